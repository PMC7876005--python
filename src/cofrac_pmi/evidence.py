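"""Orthogonal target identification: thermal shifts and bead pulldowns.

Thermal proteome profiling (TPP) measures the soluble fraction of each
protein across a temperature ladder; ligand binding typically stabilises a
target, shifting its melting curve. Following the curve-level testing idea
(rather than comparing fitted melting temperatures), a nested F-test
compares one shared sigmoid fitted to both conditions against separate
per-condition sigmoids, with Benjamini-Hochberg control across proteins.

Affinity purification compares protein intensities on ligand-coupled beads
(two coupling orientations) against control beads with Welch t-tests, again
BH-adjusted. Proteins supported by at least two of the three arms (SEC
co-elution, AP, TPP) form the ligand interactome; all three is high
confidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "SigmoidFit",
    "NparcResult",
    "ApResult",
    "EvidenceSummary",
    "melting_sigmoid",
    "fit_melting_curve",
    "nparc_test",
    "nparc_screen",
    "bh_adjust",
    "ap_enrichment",
    "intersect_evidence",
    "FitError",
]


class FitError(RuntimeError):
    """Raised when a melting-curve fit fails from every start."""


def melting_sigmoid(T: np.ndarray, a: float, b: float, plateau: float) -> np.ndarray:
    """Melting-curve model f(T) = (1-p) / (1 + exp(b - a/T)) + p.

    Monotone non-increasing in T for a > 0, ~1 at low temperature, and
    decaying to the plateau p at high temperature. The midpoint (half of the
    amplitude melted) sits at T = a/b.
    """
    T = np.asarray(T, dtype=float)
    return (1 - plateau) / (1 + np.exp(b - a / T)) + plateau


@dataclass
class SigmoidFit:
    """Fitted melting-curve parameters."""

    a: float
    b: float
    plateau: float
    rss: float
    n_obs: int

    N_PARAMS = 3

    @property
    def melting_point(self) -> float:
        """Temperature at which half the meltable amplitude is lost."""
        return self.a / self.b

    def predict(self, T: np.ndarray) -> np.ndarray:
        return melting_sigmoid(T, self.a, self.b, self.plateau)


def fit_melting_curve(
    temperatures: Sequence[float] | np.ndarray,
    values: Sequence[float] | np.ndarray,
    n_starts: int = 5,
    plateau_max: float = 0.3,
    seed: int = 0,
    extra_starts: Sequence[tuple[float, float, float]] = (),
) -> SigmoidFit:
    """Least-squares sigmoid fit of one melting curve (possibly replicated).

    Multi-start optimisation: a data-driven initial guess (midpoint from the
    half-amplitude crossing) plus ``n_starts`` randomised restarts with fixed
    sub-seeds; the plateau is bounded in [0, plateau_max]. Raises
    :class:`FitError` when no start converges.
    """
    T = np.asarray(temperatures, dtype=float)
    y = np.asarray(values, dtype=float)
    if T.size != y.size:
        raise ValueError("temperatures and values differ in length")
    if np.unique(T).size < 6:
        raise ValueError("need at least 6 distinct temperatures")

    # midpoint guess: temperature where the curve crosses half amplitude
    order = np.argsort(T)
    Ts, ys = T[order], y[order]
    half = (ys.max() + ys.min()) / 2
    below = np.nonzero(ys <= half)[0]
    tm0 = float(Ts[below[0]]) if below.size else float(Ts[-1])

    rng = np.random.default_rng(seed)
    starts = [(25.0 * tm0, 25.0, 0.05), *extra_starts]
    for _ in range(n_starts):
        b0 = rng.uniform(10.0, 40.0)
        starts.append((b0 * rng.uniform(0.9 * tm0, 1.1 * tm0), b0, rng.uniform(0.0, plateau_max)))

    best: SigmoidFit | None = None
    bounds = ([1e-6, 1e-6, 0.0], [np.inf, np.inf, plateau_max])
    for a0, b0, p0 in starts:
        try:
            popt, _ = optimize.curve_fit(
                melting_sigmoid, T, y, p0=(a0, b0, p0), bounds=bounds, maxfev=5000
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((y - melting_sigmoid(T, *popt)) ** 2))
        if best is None or rss < best.rss:
            best = SigmoidFit(float(popt[0]), float(popt[1]), float(popt[2]), rss, int(T.size))
    if best is None:
        raise FitError("melting-curve fit failed from every start")
    return best


@dataclass
class NparcResult:
    """Nested-model F-test for a condition effect on the melting curve."""

    protein_id: str
    rss_null: float  # one shared curve
    rss_alt: float  # per-condition curves
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    q_value: float | None = None


def nparc_test(
    vehicle: tuple[np.ndarray, np.ndarray],
    ligand: tuple[np.ndarray, np.ndarray],
    protein_id: str = "",
    seed: int = 0,
    n_permutations: int = 0,
) -> NparcResult:
    """Test whether two conditions share one melting curve.

    ``vehicle`` and ``ligand`` are (temperatures, values) with replicate
    observations concatenated. The null model fits a single sigmoid to the
    pooled data; the alternative fits each condition separately (RSS summed).
    F = ((RSS0 - RSS1)/d1) / (RSS1/d2) with d1 the extra parameters of the
    alternative and d2 its residual degrees of freedom; the p-value comes
    from the F(d1, d2) distribution. Degrees of freedom are theoretical
    (parameter counting), which is approximate for nonlinear fits; pass
    ``n_permutations > 0`` for a robust permutation p-value instead
    (condition labels reshuffled, F recomputed each time).
    """
    Tv, yv = (np.asarray(v, dtype=float) for v in vehicle)
    Tl, yl = (np.asarray(v, dtype=float) for v in ligand)
    T_all = np.concatenate([Tv, Tl])
    y_all = np.concatenate([yv, yl])

    null_fit = fit_melting_curve(T_all, y_all, seed=seed)
    # seeding the per-condition fits with the pooled optimum guarantees the
    # nesting inequality RSS1 <= RSS0 up to optimizer tolerance
    pooled_start = (null_fit.a, null_fit.b, null_fit.plateau)
    fit_v = fit_melting_curve(Tv, yv, seed=seed + 1, extra_starts=[pooled_start])
    fit_l = fit_melting_curve(Tl, yl, seed=seed + 2, extra_starts=[pooled_start])
    rss_v = min(fit_v.rss, float(np.sum((yv - null_fit.predict(Tv)) ** 2)))
    rss_l = min(fit_l.rss, float(np.sum((yl - null_fit.predict(Tl)) ** 2)))
    rss0 = null_fit.rss
    rss1 = min(rss_v + rss_l, rss0)

    k = SigmoidFit.N_PARAMS
    d1 = k  # 2k - k extra parameters
    d2 = int(T_all.size - 2 * k)
    if d2 <= 0:
        raise ValueError(f"{protein_id}: not enough observations for the alternative model")
    # perfect pooled fit: both RSS are numerical zeros and their ratio is
    # noise, not evidence of a condition effect
    if rss0 <= 1e-10 * T_all.size:
        f_stat = 0.0
    elif rss1 <= 0:
        f_stat = np.inf if rss0 > rss1 else 0.0
    else:
        f_stat = ((rss0 - rss1) / d1) / (rss1 / d2)
    p = float(stats.f.sf(f_stat, d1, d2)) if np.isfinite(f_stat) else 0.0
    if n_permutations > 0 and np.isfinite(f_stat):
        rng = np.random.default_rng(seed + 10_000)
        n_v = Tv.size
        exceed = 0
        for _ in range(n_permutations):
            idx = rng.permutation(T_all.size)
            iv, il = idx[:n_v], idx[n_v:]
            try:
                fv = fit_melting_curve(T_all[iv], y_all[iv], n_starts=2,
                                       extra_starts=[pooled_start])
                fl = fit_melting_curve(T_all[il], y_all[il], n_starts=2,
                                       extra_starts=[pooled_start])
            except FitError:
                continue
            rss1_perm = min(fv.rss + fl.rss, rss0)
            f_perm = ((rss0 - rss1_perm) / d1) / (rss1_perm / d2) if rss1_perm > 0 else np.inf
            exceed += f_perm >= f_stat
        p = float((1 + exceed) / (1 + n_permutations))
    return NparcResult(
        protein_id=protein_id,
        rss_null=rss0,
        rss_alt=rss1,
        f_statistic=float(f_stat),
        df_num=d1,
        df_den=d2,
        p_value=p,
    )


def nparc_screen(
    tpp: pd.DataFrame,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the curve F-test per protein and BH-adjust across the tested set.

    ``tpp`` is long-form with columns protein, condition (vehicle/ligand),
    replicate, temperature, fold_change. Proteins whose fits fail in either
    condition are excluded from testing (and from the BH family) with a log
    entry. Returns a DataFrame indexed by protein with test statistics,
    q-values and a ``significant`` flag (q <= alpha).
    """
    results: list[NparcResult] = []
    for pid, group in tpp.groupby("protein", sort=True):
        veh = group[group["condition"] == "vehicle"]
        lig = group[group["condition"] == "ligand"]
        try:
            res = nparc_test(
                (veh["temperature"].to_numpy(), veh["fold_change"].to_numpy()),
                (lig["temperature"].to_numpy(), lig["fold_change"].to_numpy()),
                protein_id=str(pid),
                seed=seed,
            )
        except (FitError, ValueError) as exc:
            logger.warning("NPARC: %s excluded (%s)", pid, exc)
            continue
        results.append(res)
    if not results:
        raise ValueError("no protein could be tested")
    qs = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
    df = pd.DataFrame(
        {
            "protein": [r.protein_id for r in results],
            "rss_null": [r.rss_null for r in results],
            "rss_alt": [r.rss_alt for r in results],
            "f_statistic": [r.f_statistic for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
        }
    ).set_index("protein")
    df["significant"] = df["q_value"] <= alpha
    return df


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone-enforced)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ApResult:
    """Bait-vs-control enrichment of one protein, per coupling orientation."""

    protein_id: str
    log2fc: dict[str, float]  # coupling -> mean log2 fold-change vs control
    p_values: dict[str, float]
    q_values: dict[str, float]
    enriched: bool


def ap_enrichment(
    ap: pd.DataFrame,
    alpha: float = 0.05,
    min_log2fc: float = 1.0,
    require_both: bool = False,
) -> list[ApResult]:
    """Call bait-enriched proteins from a pulldown intensity table.

    ``ap`` holds log2 intensities with proteins as rows and a (group,
    replicate) column MultiIndex; groups are the two coupling orientations
    (``n_bait``, ``c_bait``) and ``control``. Per orientation, a Welch
    t-test of bait vs control with BH adjustment across proteins; a protein
    is enriched when q <= alpha and log2FC >= min_log2fc in at least one
    orientation (both, if ``require_both``).
    """
    groups = ap.columns.get_level_values(0).unique()
    if "control" not in groups:
        raise ValueError("AP table needs a 'control' column group")
    couplings = [g for g in groups if g != "control"]
    control = ap["control"].to_numpy(float)
    if control.shape[1] < 2:
        raise ValueError("need at least 2 control replicates")

    fcs: dict[str, np.ndarray] = {}
    qs: dict[str, np.ndarray] = {}
    ps: dict[str, np.ndarray] = {}
    for coupling in couplings:
        bait = ap[coupling].to_numpy(float)
        if bait.shape[1] < 2:
            logger.warning("AP: coupling %s skipped (<2 replicates)", coupling)
            continue
        fcs[coupling] = bait.mean(axis=1) - control.mean(axis=1)
        t = stats.ttest_ind(bait, control, axis=1, equal_var=False)
        p = np.where(np.isnan(t.pvalue), 1.0, t.pvalue)
        ps[coupling] = p
        qs[coupling] = bh_adjust(p)
    if not fcs:
        raise ValueError("no coupling orientation with enough replicates")

    results = []
    for i, pid in enumerate(ap.index):
        hits = {
            c: (qs[c][i] <= alpha and fcs[c][i] >= min_log2fc) for c in fcs
        }
        enriched = all(hits.values()) if require_both else any(hits.values())
        results.append(
            ApResult(
                protein_id=str(pid),
                log2fc={c: float(fcs[c][i]) for c in fcs},
                p_values={c: float(ps[c][i]) for c in fcs},
                q_values={c: float(qs[c][i]) for c in fcs},
                enriched=bool(enriched),
            )
        )
    return results


@dataclass
class EvidenceSummary:
    """Per-protein support across the three experimental arms."""

    protein_id: str
    sec: bool
    ap: bool
    tpp: bool
    support: int
    interactome_member: bool
    high_confidence: bool


def intersect_evidence(
    sec_targets: Iterable[str],
    ap_targets: Iterable[str],
    tpp_targets: Iterable[str],
    min_support: int = 2,
) -> list[EvidenceSummary]:
    """Tier proteins by how many independent arms support them.

    Proteins supported by at least ``min_support`` arms form the ligand
    interactome; support by all three is high confidence.
    """
    sec, ap, tpp = set(sec_targets), set(ap_targets), set(tpp_targets)
    summaries = []
    for pid in sorted(sec | ap | tpp):
        flags = (pid in sec, pid in ap, pid in tpp)
        support = sum(flags)
        summaries.append(
            EvidenceSummary(
                protein_id=pid,
                sec=flags[0],
                ap=flags[1],
                tpp=flags[2],
                support=support,
                interactome_member=support >= min_support,
                high_confidence=support == 3,
            )
        )
    return summaries
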