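"""Targeted validation fits: binding affinity, enzyme rates and labelling.

Dose-response data from binding assays such as microscale thermophoresis
are fitted with the 1:1 quadratic binding isotherm (the labelled target is
at a fixed, known concentration), which reduces to the familiar hyperbola
L/(Kd + L) when the target concentration is far below the Kd. Reaction
rates come from the slope of product versus time within a user-chosen
linear window, percent inhibition from the ratio of treated to control
rates, and isotope-labelling series from the product of enrichment and
total metabolite intensity with log2 ratios to the first time point.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "KdFit",
    "quadratic_isotherm",
    "hyperbolic_isotherm",
    "fit_kd",
    "affinity_fold_change",
    "reaction_rate",
    "percent_inhibition",
    "labeling_series",
    "log2_ratio_to_baseline",
    "LabelingSeries",
    "RateFit",
]


def quadratic_isotherm(
    L: np.ndarray, kd: float, f0: float, f1: float, target_conc: float
) -> np.ndarray:
    """1:1 binding isotherm at fixed labelled-target concentration Pt.

    response(L) = f0 + (f1-f0) * [(Kd+Pt+L) - sqrt((Kd+Pt+L)^2 - 4*Pt*L)] / (2*Pt)

    Exact for ligand depletion by binding; converges to the hyperbola when
    Pt << Kd.
    """
    L = np.asarray(L, dtype=float)
    s = kd + target_conc + L
    bound_frac = (s - np.sqrt(s**2 - 4 * target_conc * L)) / (2 * target_conc)
    return f0 + (f1 - f0) * bound_frac


def hyperbolic_isotherm(L: np.ndarray, kd: float, f0: float, f1: float) -> np.ndarray:
    """Non-depleting binding hyperbola: response = f0 + (f1-f0) * L/(Kd+L)."""
    L = np.asarray(L, dtype=float)
    return f0 + (f1 - f0) * L / (kd + L)


@dataclass
class KdFit:
    """Fitted dissociation constant and response asymptotes."""

    kd: float  # molar
    f0: float  # unbound response
    f1: float  # saturated response
    rss: float
    kd_stderr: float | None
    model: str  # "quadratic" | "hyperbolic"
    reliable: bool
    note: str = ""


def fit_kd(
    concentrations: Sequence[float] | np.ndarray,
    response: Sequence[float] | np.ndarray,
    target_conc: float | None = None,
    model: str = "quadratic",
) -> KdFit:
    """Fit a dissociation constant to a dose-response ladder.

    ``concentrations`` (molar, > 0) need not be sorted; replicates may be
    passed as repeated concentrations. The quadratic model (default)
    requires ``target_conc``. A fit is flagged unreliable when the optimiser
    fails, the fitted Kd exceeds the top ladder concentration, or the
    response amplitude |f1-f0| is negligible against the residual noise.
    """
    L = np.asarray(concentrations, dtype=float)
    y = np.asarray(response, dtype=float)
    if L.size != y.size:
        raise ValueError("concentrations and response differ in length")
    if (L <= 0).any():
        raise ValueError("ligand concentrations must be positive")
    if model == "quadratic":
        if target_conc is None or target_conc <= 0:
            raise ValueError("quadratic isotherm needs a positive target_conc")
        fun = lambda x, kd, f0, f1: quadratic_isotherm(x, kd, f0, f1, target_conc)
    elif model == "hyperbolic":
        fun = hyperbolic_isotherm
    else:
        raise ValueError(f"unknown model {model!r}")

    # initial guesses from the data: asymptotes from extreme doses, Kd from
    # the half-amplitude crossing
    order = np.argsort(L)
    f0_0 = float(np.mean(y[order][: max(1, L.size // 8)]))
    f1_0 = float(np.mean(y[order][-max(1, L.size // 8) :]))
    half = (f0_0 + f1_0) / 2
    crossings = L[order][np.abs(y[order] - half).argmin()]
    kd_0 = float(crossings) if crossings > 0 else float(np.median(L))

    try:
        popt, pcov = optimize.curve_fit(
            fun,
            L,
            y,
            p0=(kd_0, f0_0, f1_0),
            bounds=([1e-15, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        return KdFit(
            kd=float("nan"),
            f0=float("nan"),
            f1=float("nan"),
            rss=float("nan"),
            kd_stderr=None,
            model=model,
            reliable=False,
            note=f"fit failed: {exc}",
        )
    kd, f0, f1 = map(float, popt)
    resid = y - fun(L, *popt)
    rss = float(np.sum(resid**2))
    stderr = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else None
    noise_sd = float(np.sqrt(rss / max(L.size - 3, 1)))
    reliable = True
    note = ""
    if kd > L.max():
        reliable, note = False, "Kd beyond the highest ligand concentration"
    elif abs(f1 - f0) < 3 * noise_sd:
        reliable, note = False, "response amplitude below the signal floor"
    return KdFit(kd=kd, f0=f0, f1=f1, rss=rss, kd_stderr=stderr, model=model, reliable=reliable, note=note)


def affinity_fold_change(kd_reference: float, kd_treatment: float) -> float:
    """Affinity gain: reference Kd over treatment Kd (> 1 means tighter binding)."""
    if kd_reference <= 0 or kd_treatment <= 0:
        raise ValueError("dissociation constants must be positive")
    return kd_reference / kd_treatment


@dataclass
class RateFit:
    """Linear reaction rate within a chosen time window."""

    rate: float  # product units per minute
    intercept: float
    r_squared: float
    n_points: int


def reaction_rate(
    times: Sequence[float] | np.ndarray,
    product: Sequence[float] | np.ndarray,
    window: tuple[float, float] | None = None,
) -> RateFit:
    """Slope of product versus time within the (assumed linear) window."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(product, dtype=float)
    if t.size != y.size:
        raise ValueError("times and product differ in length")
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, y = t[mask], y[mask]
    if t.size < 3:
        raise ValueError("need at least 3 time points in the window")
    fit = stats.linregress(t, y)
    return RateFit(
        rate=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2) if not np.isnan(fit.rvalue) else 1.0,
        n_points=int(t.size),
    )


def percent_inhibition(rate_treated: float, rate_control: float) -> float:
    """Percent loss of activity relative to the untreated control."""
    if rate_control <= 0:
        raise ValueError("control rate must be positive")
    return 100.0 * (1.0 - rate_treated / rate_control)


@dataclass
class LabelingSeries:
    """Isotope-labelling time course of one metabolite."""

    times: np.ndarray  # min
    total_intensity: np.ndarray
    enrichment: np.ndarray  # fraction in [0, 1]
    fraction_intensity: np.ndarray  # enrichment x total
    enrichment_was_percent: bool


def labeling_series(
    total: Sequence[float] | np.ndarray,
    enrichment: Sequence[float] | np.ndarray,
    times: Sequence[float] | np.ndarray,
) -> LabelingSeries:
    """Labelled-fraction intensity: isotope enrichment times total intensity.

    Enrichment may be given as a fraction in [0, 1] or as percent in
    (1, 100]; percent input is detected (any value > 1), recorded, and
    converted to a fraction.
    """
    total = np.asarray(total, dtype=float)
    enr = np.asarray(enrichment, dtype=float)
    t = np.asarray(times, dtype=float)
    if not (total.size == enr.size == t.size):
        raise ValueError("total, enrichment and times differ in length")
    if (enr < 0).any() or (enr > 100).any():
        raise ValueError("enrichment must lie in [0, 1] or [0, 100]%")
    was_percent = bool((enr > 1).any())
    frac = enr / 100.0 if was_percent else enr
    return LabelingSeries(
        times=t,
        total_intensity=total,
        enrichment=frac,
        fraction_intensity=frac * total,
        enrichment_was_percent=was_percent,
    )


def log2_ratio_to_baseline(
    values: Sequence[float] | np.ndarray, t0_index: int = 0
) -> np.ndarray:
    """Log2 ratio of each time point to the baseline time point.

    The baseline must be positive; later zeros are reported as NaN (missing),
    not -inf.
    """
    v = np.asarray(values, dtype=float)
    baseline = v[t0_index]
    if baseline <= 0:
        raise ValueError("baseline value must be positive")
    with np.errstate(divide="ignore"):
        out = np.log2(v / baseline)
    out[v <= 0] = np.nan
    return out
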