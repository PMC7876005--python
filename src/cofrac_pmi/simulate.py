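"""Ground-truthed synthetic datasets for every pipeline stage.

The fractionation generator emulates a size-exclusion run over 48 fractions
(the first 38 containing proteins, spanning ~5.2 MDa down to 20 kDa) with
three biological replicates: each feature elutes as one or two Gaussian
peaks in fraction coordinates, complex members share a peak placed at the
fraction their complex mass implies through the calibration line, planted
protein-metabolite interactions give the metabolite a bound peak co-located
with its partner's peak, and unbound metabolite signal elutes as a free pool
beyond the protein-containing span. Intensities carry multiplicative
lognormal noise (MS intensities are positive and heteroscedastic) and values
below a detection floor are censored to zero.

Companion generators produce thermal-proteome-profiling melting curves with
planted stability shifts and affinity-purification tables with planted
enrichments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from cofrac_pmi.profiles import (
    CalibrationCurve,
    CalibrationSet,
    FractionationDataset,
    fit_calibration,
    gaussian,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "PlantedPeak",
    "generate_calibration_refs",
    "simulate_fractionation",
    "simulate_tpp",
    "simulate_ap",
]

#: mass spanned by the protein-containing fractions (Da): ~5.2 MDa at the
#: first fraction down to 20 kDa at the last protein fraction.
DEFAULT_MASS_RANGE = (5.2e6, 2.0e4)


def generate_calibration_refs(
    n_refs: int,
    mass_range: tuple[float, float] = DEFAULT_MASS_RANGE,
    fraction_range: tuple[float, float] = (1.0, 38.0),
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> CalibrationSet:
    """Reference proteins on a log-linear mass-vs-fraction line.

    Masses are log-spaced between the endpoints of ``mass_range`` and placed
    at evenly spaced fractions, so that without noise every point satisfies
    ``log10(mass) = a * fraction + b`` exactly and masses decrease strictly
    with fraction index. Optional Gaussian noise (sd in log10 units) perturbs
    the masses.
    """
    if n_refs < 2:
        raise ValueError("need at least 2 reference proteins (line underdetermined)")
    hi, lo = mass_range
    if hi <= 0 or lo <= 0:
        raise ValueError("masses must be positive")
    if hi <= lo:
        raise ValueError("mass_range must be (high, low) in elution order")
    fractions = np.linspace(fraction_range[0], fraction_range[1], n_refs)
    log_masses = np.linspace(np.log10(hi), np.log10(lo), n_refs)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        log_masses = log_masses + rng.normal(0.0, noise_sd, n_refs)
    return CalibrationSet(fractions=fractions, masses=10.0**log_masses)


@dataclass
class PlantedPeak:
    """Ground-truth peak parameters (pre-noise)."""

    center: float  # 1-based fractional index
    width: float  # sigma, fractions
    amplitude: float


@dataclass
class SimConfig:
    """Conditions of a synthetic fractionation experiment.

    Defaults mirror the reference experiment: 48 collected fractions with
    proteins in the first 38, three biological replicates, Gaussian peaks of
    sigma 1.5 fractions, and 15% multiplicative noise.
    """

    n_proteins: int = 200
    n_metabolites: int = 30
    n_fractions: int = 48
    protein_span: tuple[int, int] = (1, 38)
    complexes: list[tuple[list[str], float]] = field(default_factory=list)
    planted_pmis: list[tuple[str, str]] = field(default_factory=list)
    n_replicates: int = 3
    noise_cv: float = 0.15
    free_pool_fraction: float = 0.4
    peak_sigma: float = 1.5
    second_peak_prob: float = 0.3
    intensity_scale: float = 1e6
    detection_floor: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.protein_span
        if not (1 <= lo < hi <= self.n_fractions):
            raise ValueError("protein_span must lie within the fraction range")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if not 0 <= self.free_pool_fraction < 1:
            raise ValueError("free_pool_fraction must be in [0, 1)")
        prot_ids = set(self.protein_ids())
        met_ids = set(self.metabolite_ids())
        for members, _ in self.complexes:
            unknown = set(members) - prot_ids
            if unknown:
                raise ValueError(f"complex members not among proteins: {sorted(unknown)}")
        for met, prot in self.planted_pmis:
            if met not in met_ids:
                raise ValueError(f"planted PMI references unknown metabolite {met!r}")
            if prot not in prot_ids:
                raise ValueError(f"planted PMI references unknown protein {prot!r}")

    def protein_ids(self) -> list[str]:
        return [f"P{i:04d}" for i in range(1, self.n_proteins + 1)]

    def metabolite_ids(self) -> list[str]:
        return [f"M{i:04d}" for i in range(1, self.n_metabolites + 1)]


@dataclass
class GroundTruth:
    """What was planted, for downstream evaluation."""

    planted_pmis: set[tuple[str, str]] = field(default_factory=set)
    planted_complexes: dict[str, int] = field(default_factory=dict)  # protein -> complex index
    planted_peaks: dict[str, list[PlantedPeak]] = field(default_factory=dict)
    planted_tm_shifts: dict[str, float] = field(default_factory=dict)  # protein -> delta Tm (degC)
    planted_enrichments: dict[str, float] = field(default_factory=dict)  # protein -> log2 FC

    def __post_init__(self) -> None:
        mets = {m for m, _ in self.planted_pmis}
        prots = {p for _, p in self.planted_pmis}
        if mets & prots:
            raise ValueError("protein and metabolite id namespaces overlap")


def _default_complexes(config: SimConfig, rng: np.random.Generator) -> list[tuple[list[str], float]]:
    """Ten 3-member complexes over the first 30 proteins, random masses."""
    prot_ids = config.protein_ids()
    n_cplx = min(10, config.n_proteins // 3)
    complexes = []
    for c in range(n_cplx):
        members = prot_ids[3 * c : 3 * c + 3]
        mass = 10 ** rng.uniform(5.3, 6.5)  # 200 kDa - 3 MDa
        complexes.append((members, mass))
    return complexes


def _default_pmis(
    config: SimConfig, rng: np.random.Generator, n_pmis: int = 20
) -> list[tuple[str, str]]:
    mets = rng.choice(config.metabolite_ids(), size=min(n_pmis, config.n_metabolites), replace=False)
    prots = rng.choice(config.protein_ids(), size=len(mets), replace=False)
    return [(str(m), str(p)) for m, p in zip(mets, prots)]


def simulate_fractionation(
    config: SimConfig,
    calibration: CalibrationSet | None = None,
) -> tuple[FractionationDataset, GroundTruth, CalibrationSet]:
    """Simulate a replicated SEC co-fractionation experiment.

    Every protein gets a main peak at the fraction its monomeric mass (or,
    for complex members, the complex mass) implies through the calibration
    line, and optionally a second peak at a multimer position. Planted PMI
    metabolites get a bound peak exactly co-located (pre-noise) with their
    partner's main peak plus a free pool beyond the protein span; unplanted
    metabolites carry only the free pool. If ``config.complexes`` or
    ``config.planted_pmis`` are empty, a default layout is drawn (ten
    3-member complexes, twenty PMIs) so the standard benchmark is a plain
    ``simulate_fractionation(SimConfig(seed=...))`` call.

    Returns the dataset, the ground truth, and the calibration references.
    """
    rng = np.random.default_rng(config.seed)
    span_lo, span_hi = config.protein_span
    if calibration is None:
        calibration = generate_calibration_refs(
            5, fraction_range=(float(span_lo), float(span_hi))
        )
    curve = fit_calibration(calibration)

    complexes = config.complexes or _default_complexes(config, rng)
    planted_pmis = config.planted_pmis or _default_pmis(config, rng)

    member_of: dict[str, tuple[int, float]] = {}
    for idx, (members, mass) in enumerate(complexes):
        lo_mass = curve.mass_at(span_hi)
        hi_mass = curve.mass_at(span_lo)
        if not (lo_mass <= mass <= hi_mass):
            raise ValueError(
                f"complex mass {mass:.3g} Da outside calibrated range "
                f"[{lo_mass:.3g}, {hi_mass:.3g}]"
            )
        for m in members:
            member_of[m] = (idx, mass)

    truth = GroundTruth(
        planted_pmis=set(planted_pmis),
        planted_complexes={p: idx for p, (idx, _) in member_of.items()},
    )

    prot_ids = config.protein_ids()
    met_ids = config.metabolite_ids()
    n_frac = config.n_fractions
    x = np.arange(1, n_frac + 1, dtype=float)

    monomeric = pd.Series(index=prot_ids, dtype=float)
    clean = pd.DataFrame(0.0, index=prot_ids + met_ids, columns=range(1, n_frac + 1))

    for pid in prot_ids:
        if pid in member_of:
            _, cplx_mass = member_of[pid]
            mono = cplx_mass / (3 * rng.uniform(0.8, 1.2))
            main_center = curve.fraction_of(cplx_mass)
        else:
            mono = 10 ** rng.uniform(4.5, 5.7)  # ~30-500 kDa monomers
            main_center = curve.fraction_of(mono)
        monomeric[pid] = mono
        amp = config.intensity_scale * 10 ** rng.uniform(-0.5, 0.5)
        peaks = [PlantedPeak(float(np.clip(main_center, span_lo + 1, span_hi - 1)), config.peak_sigma, amp)]
        if pid not in member_of and rng.random() < config.second_peak_prob:
            # a second, multimeric state at 2-4x the monomer mass
            mult_mass = mono * rng.choice([2.0, 4.0])
            center2 = float(np.clip(curve.fraction_of(mult_mass), span_lo + 1, span_hi - 1))
            if abs(center2 - peaks[0].center) >= 4:
                peaks.append(PlantedPeak(center2, config.peak_sigma, amp * rng.uniform(0.3, 1.0)))
        truth.planted_peaks[pid] = peaks
        for pk in peaks:
            clean.loc[pid] += gaussian(x, pk.amplitude, pk.center, pk.width)

    partner_main = {pid: truth.planted_peaks[pid][0] for pid in prot_ids}
    bound_partner = dict((m, p) for m, p in planted_pmis)
    for mid in met_ids:
        amp = config.intensity_scale * 10 ** rng.uniform(-0.5, 0.5)
        peaks = []
        if mid in bound_partner:
            target = partner_main[bound_partner[mid]]
            peaks.append(
                PlantedPeak(target.center, target.width, amp * (1 - config.free_pool_fraction))
            )
            free_amp = amp * config.free_pool_fraction
        else:
            free_amp = amp
        if free_amp > 0:
            free_center = float(rng.uniform(span_hi + 2, n_frac - 1))
            peaks.append(PlantedPeak(free_center, config.peak_sigma, free_amp))
        truth.planted_peaks[mid] = peaks
        for pk in peaks:
            clean.loc[mid] += gaussian(x, pk.amplitude, pk.center, pk.width)

    # multiplicative lognormal noise, mean-preserving, per replicate
    sigma_ln = float(np.sqrt(np.log1p(config.noise_cv**2)))
    intensities = {}
    for r in range(1, config.n_replicates + 1):
        mat = clean.to_numpy().copy()
        if sigma_ln > 0:
            noise = rng.lognormal(mean=-0.5 * sigma_ln**2, sigma=sigma_ln, size=mat.shape)
            mat = mat * noise
        mat[mat < config.detection_floor] = 0.0
        intensities[f"rep{r}"] = pd.DataFrame(
            mat, index=clean.index, columns=[f"F{i:02d}" for i in range(1, n_frac + 1)]
        )

    kinds = pd.Series(
        ["protein"] * len(prot_ids) + ["metabolite"] * len(met_ids),
        index=prot_ids + met_ids,
    )
    dataset = FractionationDataset(
        intensities=intensities,
        feature_kind=kinds,
        monomeric_mass=monomeric,
        protein_span=config.protein_span,
    )
    return dataset, truth, calibration


# ---------------------------------------------------------------------------
# thermal proteome profiling
# ---------------------------------------------------------------------------

DEFAULT_TPP_TEMPERATURES = tuple(np.linspace(37.0, 67.0, 10))


def simulate_tpp(
    n_proteins: int,
    n_binders: int,
    delta_tm: float,
    noise_sd: float = 0.02,
    temperatures: tuple[float, ...] = DEFAULT_TPP_TEMPERATURES,
    n_replicates: int = 2,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate vehicle/ligand melting curves with planted stability shifts.

    Per protein, a sigmoid melting curve ``(1-p)/(1+exp(b - a/T)) + p`` with a
    random midpoint around 50 degC; the first ``n_binders`` proteins have the
    ligand-condition midpoint shifted by ``delta_tm``. Fold changes are
    normalised to ~1 at the lowest temperature and carry additive Gaussian
    noise. Returns a long-form table (protein, condition, replicate,
    temperature, fold_change) and the ground truth.
    """
    if len(temperatures) < 6:
        raise ValueError("need at least 6 temperatures spanning the transition")
    if not 0 <= n_binders <= n_proteins:
        raise ValueError("n_binders must be within [0, n_proteins]")
    temps = np.asarray(temperatures, dtype=float)
    rng = np.random.default_rng(seed)
    truth = GroundTruth()
    rows = []
    for i in range(n_proteins):
        pid = f"P{i + 1:04d}"
        tm = rng.normal(50.0, 2.0)
        b = rng.uniform(20.0, 30.0)
        plateau = rng.uniform(0.02, 0.15)
        shift = delta_tm if i < n_binders else 0.0
        truth.planted_tm_shifts[pid] = shift
        if shift and not (temps.min() < tm + shift < temps.max()):
            import warnings

            warnings.warn(f"{pid}: shifted midpoint {tm + shift:.1f} outside temperature span")
        for condition, tm_c in (("vehicle", tm), ("ligand", tm + shift)):
            a = b * tm_c
            curve = (1 - plateau) / (1 + np.exp(b - a / temps)) + plateau
            for r in range(1, n_replicates + 1):
                y = curve + rng.normal(0.0, noise_sd, temps.size) if noise_sd > 0 else curve
                for t, v in zip(temps, y):
                    rows.append((pid, condition, f"rep{r}", t, max(v, 0.0)))
    df = pd.DataFrame(rows, columns=["protein", "condition", "replicate", "temperature", "fold_change"])
    return df, truth


# ---------------------------------------------------------------------------
# affinity purification
# ---------------------------------------------------------------------------

AP_GROUPS = ("n_bait", "c_bait", "control")


def simulate_ap(
    n_proteins: int,
    n_enriched: int,
    effect_log2fc: float,
    noise_sd: float = 0.3,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a bait-vs-control bead pulldown intensity table.

    Log2 intensities are Gaussian around a per-protein baseline; the first
    ``n_enriched`` proteins are offset by ``effect_log2fc`` in both bait-bead
    column groups (N- and C-coupled ligand). Columns are a MultiIndex of
    (group, replicate) with groups ``n_bait``, ``c_bait``, ``control``.
    """
    if n_enriched > n_proteins:
        raise ValueError("n_enriched must not exceed n_proteins")
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates per group")
    rng = np.random.default_rng(seed)
    ids = [f"P{i + 1:04d}" for i in range(n_proteins)]
    baseline = rng.normal(25.0, 1.5, n_proteins)
    truth = GroundTruth()
    cols = pd.MultiIndex.from_product(
        [AP_GROUPS, [f"rep{r}" for r in range(1, n_replicates + 1)]],
        names=["group", "replicate"],
    )
    data = np.empty((n_proteins, len(cols)))
    for j, (group, _) in enumerate(cols):
        mean = baseline.copy()
        if group in ("n_bait", "c_bait"):
            mean[:n_enriched] += effect_log2fc
        data[:, j] = mean + (rng.normal(0.0, noise_sd, n_proteins) if noise_sd > 0 else 0.0)
    for i, pid in enumerate(ids):
        truth.planted_enrichments[pid] = effect_log2fc if i < n_enriched else 0.0
    return pd.DataFrame(data, index=ids, columns=cols), truth
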