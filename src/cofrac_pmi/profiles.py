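"""SEC elution profiles: I/O, normalisation, deconvolution and mass calibration.

A size-exclusion run is a table of intensities, one row per feature (protein
or metabolite), one column per fraction, with biological replicates in
separate tables. Profiles are normalised to their maximum, averaged across
replicates, and split into single Gaussian peaks ("deconvolution"); each peak
is then assigned an apparent molecular mass through a log-linear calibration
fitted on reference proteins of known mass, and proteins are classified as
monomeric or multimeric from the ratio of apparent to monomeric mass.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal, stats

logger = logging.getLogger(__name__)

__all__ = [
    "FractionationDataset",
    "ElutionProfile",
    "ElutionPeak",
    "CalibrationSet",
    "CalibrationCurve",
    "OligomericCall",
    "PeakPickingParams",
    "read_fraction_table",
    "read_calibration_table",
    "normalize_profile",
    "average_replicates",
    "deconvolve",
    "deconvolve_replicates",
    "reconstruction_residual",
    "fit_calibration",
    "apparent_mass",
    "classify_oligomeric",
    "gaussian",
]

MONOMERIC_MASS_COLUMN = "monomeric_mass_da"

#: apparent/monomeric mass ratio above which a peak is called multimeric
OLIGOMERIC_RATIO_THRESHOLD = 1.5


def gaussian(x: np.ndarray, amplitude: float, center: float, width: float) -> np.ndarray:
    """Gaussian peak shape in fraction coordinates."""
    return amplitude * np.exp(-0.5 * ((x - center) / width) ** 2)


# ---------------------------------------------------------------------------
# datasets and I/O
# ---------------------------------------------------------------------------


@dataclass
class FractionationDataset:
    """Fraction x feature intensity tables for one SEC experiment.

    Parameters
    ----------
    intensities
        Mapping of replicate id to a DataFrame of raw intensities with
        feature ids as the index and fraction labels as columns, in elution
        order. All replicates share index and columns.
    feature_kind
        Series mapping feature id to ``"protein"`` or ``"metabolite"``.
    monomeric_mass
        Optional Series of monomeric masses in Da (proteins only).
    protein_span
        1-based inclusive fraction-index range that contains proteins; peaks
        and scores are restricted to this window. Later fractions hold free
        (unbound) small molecules and are excluded.
    """

    intensities: dict[str, pd.DataFrame]
    feature_kind: pd.Series
    monomeric_mass: pd.Series | None = None
    protein_span: tuple[int, int] = (1, 38)

    def __post_init__(self) -> None:
        reps = list(self.intensities)
        if not reps:
            raise ValueError("dataset needs at least one replicate")
        first = self.intensities[reps[0]]
        for rep in reps[1:]:
            df = self.intensities[rep]
            if not df.index.equals(first.index) or not df.columns.equals(first.columns):
                raise ValueError(f"replicate {rep!r} has mismatched features or fractions")
        if (first.index.duplicated()).any():
            dupes = first.index[first.index.duplicated()].tolist()
            raise ValueError(f"duplicate feature ids: {dupes}")
        for rep, df in self.intensities.items():
            if (df.to_numpy() < 0).any():
                r, c = np.argwhere(df.to_numpy() < 0)[0]
                raise ValueError(
                    f"negative intensity in replicate {rep!r} at feature "
                    f"{df.index[r]!r}, fraction {df.columns[c]!r}"
                )

    @property
    def fraction_labels(self) -> list[str]:
        return list(next(iter(self.intensities.values())).columns)

    @property
    def n_fractions(self) -> int:
        return len(self.fraction_labels)

    @property
    def replicate_ids(self) -> list[str]:
        return list(self.intensities)

    @property
    def feature_ids(self) -> list[str]:
        return list(next(iter(self.intensities.values())).index)

    def features_of_kind(self, kind: str) -> list[str]:
        return list(self.feature_kind.index[self.feature_kind == kind])

    def profiles(self, feature_id: str) -> dict[str, np.ndarray]:
        """Raw intensity vector of one feature in every replicate."""
        return {rep: df.loc[feature_id].to_numpy(float) for rep, df in self.intensities.items()}

    @staticmethod
    def concat(a: "FractionationDataset", b: "FractionationDataset") -> "FractionationDataset":
        """Stack two datasets (e.g. proteins + metabolites) sharing fractions."""
        if a.fraction_labels != b.fraction_labels or a.replicate_ids != b.replicate_ids:
            raise ValueError("datasets differ in fractions or replicates")
        overlap = set(a.feature_ids) & set(b.feature_ids)
        if overlap:
            raise ValueError(f"feature ids present in both datasets: {sorted(overlap)[:5]}")
        intensities = {
            rep: pd.concat([a.intensities[rep], b.intensities[rep]]) for rep in a.replicate_ids
        }
        masses = [m for m in (a.monomeric_mass, b.monomeric_mass) if m is not None]
        return FractionationDataset(
            intensities=intensities,
            feature_kind=pd.concat([a.feature_kind, b.feature_kind]),
            monomeric_mass=pd.concat(masses) if masses else None,
            protein_span=a.protein_span,
        )

    def write_tsv(self, directory: str | Path, prefix: str) -> list[Path]:
        """Write one TSV per replicate in the dialect `read_fraction_table` reads."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for rep, df in self.intensities.items():
            out = df.copy()
            if self.monomeric_mass is not None:
                out.insert(0, MONOMERIC_MASS_COLUMN, self.monomeric_mass.reindex(out.index))
            path = directory / f"{prefix}_{rep}.tsv"
            out.to_csv(path, sep="\t", index_label="feature_id")
            paths.append(path)
        return paths


def read_fraction_table(
    paths: str | Path | Sequence[str | Path],
    kind: str,
    protein_span: tuple[int, int] = (1, 38),
) -> FractionationDataset:
    """Read replicate fraction tables into a :class:`FractionationDataset`.

    Each TSV holds one feature per row (first column ``feature_id``), an
    optional ``monomeric_mass_da`` column, and one fraction per column in
    elution order. Pass one path per replicate, in replicate order;
    replicates get canonical ids ``rep1..repN`` so that protein and
    metabolite tables from matched files align.
    """
    if kind not in ("protein", "metabolite"):
        raise ValueError(f"kind must be 'protein' or 'metabolite', got {kind!r}")
    if isinstance(paths, (str, Path)):
        paths = [paths]
    intensities: dict[str, pd.DataFrame] = {}
    monomeric = None
    for i, path in enumerate(paths):
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.index.duplicated().any():
            raise ValueError(f"{path}: duplicate feature ids")
        if MONOMERIC_MASS_COLUMN in df.columns:
            monomeric = df.pop(MONOMERIC_MASS_COLUMN)
        if df.isna().any().any():
            row = df.index[df.isna().any(axis=1)][0]
            raise ValueError(f"{path}: ragged or missing values at feature {row!r}")
        neg = df.to_numpy() < 0
        if neg.any():
            r, c = np.argwhere(neg)[0]
            raise ValueError(
                f"{path}: negative intensity at feature {df.index[r]!r}, "
                f"fraction {df.columns[c]!r}"
            )
        intensities[f"rep{i + 1}"] = df.astype(float)
    kinds = pd.Series(kind, index=next(iter(intensities.values())).index)
    return FractionationDataset(
        intensities=intensities,
        feature_kind=kinds,
        monomeric_mass=monomeric,
        protein_span=protein_span,
    )


# ---------------------------------------------------------------------------
# normalisation and replicate handling
# ---------------------------------------------------------------------------


@dataclass
class ElutionProfile:
    """A single feature's elution profile, normalised to its maximum."""

    feature_id: str
    kind: str
    intensities: np.ndarray  # in [0, 1]
    all_zero: bool = False

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.intensities))


def normalize_profile(
    intensities: np.ndarray | Sequence[float],
    feature_id: str = "",
    kind: str = "protein",
) -> ElutionProfile:
    """Scale an intensity vector to its maximum (max becomes 1).

    An all-zero vector is returned unchanged with ``all_zero=True``.
    """
    vec = np.asarray(intensities, dtype=float)
    if (vec < 0).any():
        raise ValueError("negative intensities")
    peak = vec.max() if vec.size else 0.0
    if peak == 0:
        return ElutionProfile(feature_id, kind, vec.copy(), all_zero=True)
    return ElutionProfile(feature_id, kind, vec / peak)


def average_replicates(
    profiles: Sequence[ElutionProfile],
) -> tuple[ElutionProfile, float | None]:
    """Average normalised replicate profiles and report reproducibility.

    Returns the re-normalised element-wise mean and the mean pairwise Pearson
    correlation across replicates (``None`` with a single replicate).
    """
    if not profiles:
        raise ValueError("no replicates")
    lengths = {len(p.intensities) for p in profiles}
    if len(lengths) != 1:
        raise ValueError(f"replicate length mismatch: {sorted(lengths)}")
    mat = np.vstack([p.intensities for p in profiles])
    mean = normalize_profile(mat.mean(axis=0), profiles[0].feature_id, profiles[0].kind)
    if len(profiles) < 2:
        return mean, None
    rs = []
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            a, b = mat[i], mat[j]
            if a.std() == 0 or b.std() == 0:
                continue
            rs.append(stats.pearsonr(a, b).statistic)
    return mean, (float(np.mean(rs)) if rs else None)


# ---------------------------------------------------------------------------
# deconvolution
# ---------------------------------------------------------------------------


@dataclass
class PeakPickingParams:
    """Settings for peak picking and Gaussian fitting.

    Defaults follow standard chromatographic practice: light moving-average
    smoothing, prominence-filtered local maxima, region boundaries at the
    minima between adjacent apexes, and a least-squares Gaussian per region.
    """

    smooth_window: int = 3  # moving-average width (fractions)
    min_prominence_frac: float = 0.05  # of the profile maximum
    min_apex_separation: int = 2  # fractions
    min_support: int = 3  # fractions in a peak region
    min_width: float = 0.5  # fractions; narrower fits discarded
    max_width: float = 10.0
    replicate_apex_tolerance: int = 1  # fractions, for cross-replicate support
    min_replicate_support: int = 2


@dataclass
class ElutionPeak:
    """One deconvolved Gaussian component of an elution profile."""

    feature_id: str
    kind: str
    ordinal: int
    amplitude: float
    center: float  # fractional 1-based index (mu)
    width: float  # sigma, fractions
    support: tuple[int, int]  # closed 1-based fraction interval
    single_peak_profile: np.ndarray  # fitted Gaussian inside support, 0 outside
    detected_apex: int | None = None  # observed local maximum (1-based fraction)
    apparent_mass: float | None = None
    mass_extrapolated: bool = False

    @property
    def apex_fraction(self) -> int:
        """Observed apex if recorded, else the nearest fraction to the centre."""
        return self.detected_apex if self.detected_apex is not None else int(round(self.center))


def _smooth(vec: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return vec
    kernel = np.ones(window) / window
    return np.convolve(vec, kernel, mode="same")


def _find_apexes(vec: np.ndarray, params: PeakPickingParams) -> np.ndarray:
    """0-based apex indices of the smoothed profile."""
    if vec.max() <= 0:
        return np.array([], dtype=int)
    smoothed = _smooth(vec, params.smooth_window)
    apexes, _ = signal.find_peaks(
        smoothed,
        prominence=params.min_prominence_frac * smoothed.max(),
        distance=params.min_apex_separation,
    )
    # find_peaks misses maxima at array edges; recover a dominant edge apex
    if smoothed[0] > smoothed[1] and smoothed[0] >= params.min_prominence_frac * smoothed.max():
        apexes = np.concatenate(([0], apexes))
    if smoothed[-1] > smoothed[-2] and smoothed[-1] >= params.min_prominence_frac * smoothed.max():
        apexes = np.concatenate((apexes, [len(vec) - 1]))
    return np.unique(apexes)


def _regions(vec: np.ndarray, apexes: np.ndarray) -> list[tuple[int, int]]:
    """Closed 0-based regions split at the minima between adjacent apexes."""
    bounds = [0]
    for left, right in zip(apexes[:-1], apexes[1:]):
        bounds.append(left + int(np.argmin(vec[left : right + 1])))
    bounds.append(len(vec) - 1)
    return [(bounds[i], bounds[i + 1]) for i in range(len(apexes))]


def deconvolve(
    profile: ElutionProfile,
    params: PeakPickingParams | None = None,
) -> list[ElutionPeak]:
    """Split a normalised elution profile into single Gaussian peaks.

    Local maxima of the lightly smoothed profile seed one region each,
    bounded by the minima between adjacent apexes; a Gaussian is fitted by
    least squares within each region. Candidates whose fit fails, whose
    support is shorter than ``min_support`` fractions, or whose width falls
    outside ``[min_width, max_width]`` are dropped with a warning.
    """
    params = params or PeakPickingParams()
    vec = profile.intensities
    n = len(vec)
    if n < params.min_support or vec.max() <= 0:
        return []
    apexes = _find_apexes(vec, params)
    if apexes.size == 0:
        return []
    x = np.arange(1, n + 1, dtype=float)  # 1-based fraction coordinates
    peaks: list[ElutionPeak] = []
    for lo, hi in _regions(vec, apexes):
        if hi - lo + 1 < params.min_support:
            continue
        xs, ys = x[lo : hi + 1], vec[lo : hi + 1]
        apex_rel = int(np.argmax(ys))
        p0 = (ys[apex_rel], xs[apex_rel], 1.5)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, _ = optimize.curve_fit(
                    gaussian,
                    xs,
                    ys,
                    p0=p0,
                    bounds=([0.0, xs[0] - 1, 0.1], [2.0, xs[-1] + 1, params.max_width * 2]),
                    maxfev=2000,
                )
        except (RuntimeError, ValueError):
            logger.warning("%s: Gaussian fit failed in region %s-%s", profile.feature_id, lo, hi)
            continue
        amplitude, center, width = map(float, popt)
        if width < params.min_width or width > params.max_width:
            logger.warning(
                "%s: peak at %.1f dropped (sigma=%.2f outside bounds)",
                profile.feature_id,
                center,
                width,
            )
            continue
        single = np.zeros(n)
        single[lo : hi + 1] = gaussian(xs, amplitude, center, width)
        peaks.append(
            ElutionPeak(
                feature_id=profile.feature_id,
                kind=profile.kind,
                ordinal=len(peaks) + 1,
                amplitude=amplitude,
                center=center,
                width=width,
                support=(lo + 1, hi + 1),
                single_peak_profile=single,
                detected_apex=int(xs[apex_rel]),
            )
        )
    return peaks


def reconstruction_residual(profile: ElutionProfile, peaks: Sequence[ElutionPeak]) -> float:
    """Relative L2 residual of the summed single peaks against the profile."""
    denom = np.linalg.norm(profile.intensities)
    if denom == 0:
        return 0.0
    total = np.sum([p.single_peak_profile for p in peaks], axis=0) if peaks else 0.0
    return float(np.linalg.norm(profile.intensities - total) / denom)


def deconvolve_replicates(
    replicate_profiles: Sequence[np.ndarray],
    feature_id: str = "",
    kind: str = "protein",
    params: PeakPickingParams | None = None,
) -> tuple[list[ElutionPeak], ElutionProfile, float | None]:
    """Normalise, merge and deconvolve replicate profiles of one feature.

    Each replicate is max-normalised, the mean profile is deconvolved, and a
    peak is kept only when its apex is reproduced (a local maximum within
    ``replicate_apex_tolerance`` fractions) in at least
    ``min_replicate_support`` replicates. With a single replicate every peak
    of that replicate is kept.
    """
    params = params or PeakPickingParams()
    normed = [normalize_profile(v, feature_id, kind) for v in replicate_profiles]
    mean, reproducibility = average_replicates(normed)
    peaks = deconvolve(mean, params)
    if len(normed) >= 2:
        rep_apexes = [_find_apexes(p.intensities, params) + 1 for p in normed]  # 1-based
        kept = []
        for peak in peaks:
            # compare against the observed apex: for merged regions the
            # least-squares centre sits between components
            support = sum(
                bool(ap.size)
                and np.min(np.abs(ap - peak.apex_fraction)) <= params.replicate_apex_tolerance
                for ap in rep_apexes
            )
            if support >= min(params.min_replicate_support, len(normed)):
                kept.append(peak)
        peaks = [replace(p, ordinal=i + 1) for i, p in enumerate(kept)]
    return peaks, mean, reproducibility


# ---------------------------------------------------------------------------
# calibration and oligomeric state
# ---------------------------------------------------------------------------


@dataclass
class CalibrationSet:
    """Reference proteins of known mass with their elution positions."""

    fractions: np.ndarray  # fraction index (or elution volume), ascending
    masses: np.ndarray  # Da

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.fractions.size != self.masses.size:
            raise ValueError("fractions and masses differ in length")
        if (self.masses <= 0).any():
            raise ValueError("masses must be positive")


def read_calibration_table(path: str | Path) -> CalibrationSet:
    """Read a reference table with columns ``fraction`` and ``mass_da``."""
    df = pd.read_csv(path, sep="\t")
    missing = {"fraction", "mass_da"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return CalibrationSet(df["fraction"].to_numpy(), df["mass_da"].to_numpy())


@dataclass
class CalibrationCurve:
    """Log-linear mass calibration: log10(mass) = slope * fraction + intercept."""

    slope: float
    intercept: float
    r_squared: float
    fraction_range: tuple[float, float]

    def mass_at(self, fraction: float) -> float:
        return float(10 ** (self.slope * fraction + self.intercept))

    def fraction_of(self, mass: float) -> float:
        if mass <= 0:
            raise ValueError("mass must be positive")
        return float((np.log10(mass) - self.intercept) / self.slope)

    def in_range(self, fraction: float) -> bool:
        lo, hi = self.fraction_range
        return lo <= fraction <= hi


def fit_calibration(refs: CalibrationSet) -> CalibrationCurve:
    """Least-squares line of log10(mass) against elution position.

    Mass must decrease along the gradient, so the fitted slope is required to
    be negative.
    """
    if refs.fractions.size < 2:
        raise ValueError("calibration needs at least 2 reference points")
    if np.unique(refs.fractions).size < 2:
        raise ValueError("calibration references all at one fraction")
    fit = stats.linregress(refs.fractions, np.log10(refs.masses))
    if fit.slope >= 0:
        raise ValueError("calibration slope must be negative (mass decreases along elution)")
    r2 = float(fit.rvalue**2)
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        fraction_range=(float(refs.fractions.min()), float(refs.fractions.max())),
    )


def apparent_mass(peak: ElutionPeak, cal: CalibrationCurve) -> ElutionPeak:
    """Assign the calibrated apparent mass of a peak from its fitted centre.

    Returns a copy of the peak with ``apparent_mass`` set; positions outside
    the calibrated span are extrapolated and flagged.
    """
    mass = cal.mass_at(peak.center)
    return replace(peak, apparent_mass=mass, mass_extrapolated=not cal.in_range(peak.center))


@dataclass
class OligomericCall:
    """Multimeric-state classification of one protein peak."""

    protein_id: str
    peak_ordinal: int
    monomeric_mass: float
    apparent_mass: float
    ratio: float
    multimeric: bool


def classify_oligomeric(
    protein_id: str,
    peak: ElutionPeak,
    monomeric_mass: float,
    ratio_threshold: float = OLIGOMERIC_RATIO_THRESHOLD,
) -> OligomericCall:
    """Call a peak multimeric when apparent/monomeric mass exceeds the threshold.

    A ratio above 1.5 (default) indicates the protein elutes as part of a
    larger assembly than its monomer.
    """
    if monomeric_mass is None or not monomeric_mass > 0:
        raise ValueError(f"{protein_id}: monomeric mass must be positive")
    if peak.apparent_mass is None:
        raise ValueError(f"{protein_id}: peak has no apparent mass; calibrate first")
    ratio = peak.apparent_mass / monomeric_mass
    return OligomericCall(
        protein_id=protein_id,
        peak_ordinal=peak.ordinal,
        monomeric_mass=float(monomeric_mass),
        apparent_mass=float(peak.apparent_mass),
        ratio=float(ratio),
        multimeric=bool(ratio > ratio_threshold),
    )
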