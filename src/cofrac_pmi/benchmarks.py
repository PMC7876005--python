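"""Self-validation benchmarks: recovery rates on ground-truthed simulations.

Each function generates a synthetic dataset with known truth, runs the
corresponding pipeline stage from scratch, and returns the measured
performance. Problem sizes are chosen to give stable estimates within a
couple of minutes on one CPU; seeds make every run reproducible.
"""

from __future__ import annotations

import numpy as np

import cofrac_pmi as cp
from cofrac_pmi.profiles import gaussian

__all__ = [
    "two_peak_recovery",
    "calibration_accuracy",
    "oligomeric_accuracy",
    "nparc_null_rejection",
    "nparc_power",
    "kd_recovery",
    "pcc_formula_agreement",
    "bh_stepup_agreement",
]


def two_peak_recovery(
    n_profiles: int = 500,
    cv: float = 0.10,
    min_separation: float = 6.0,
    sigma: float = 1.5,
    seed: int = 0,
) -> float:
    """Fraction of planted two-peak profiles deconvolved into exactly two
    peaks with both apexes within one fraction of truth."""
    rng = np.random.default_rng(seed)
    x = np.arange(1, 49, dtype=float)
    s = np.sqrt(np.log1p(cv**2))
    n_ok = 0
    for _ in range(n_profiles):
        c1 = rng.uniform(4.0, 34.0 - min_separation)
        c2 = c1 + rng.uniform(min_separation, 12.0)
        clean = gaussian(x, 1.0, c1, sigma) + gaussian(x, rng.uniform(0.4, 1.0), c2, sigma)
        noisy = clean * rng.lognormal(-0.5 * s * s, s, x.size) if cv > 0 else clean
        peaks = cp.deconvolve(cp.normalize_profile(noisy))
        if len(peaks) == 2:
            got = sorted(p.center for p in peaks)
            n_ok += abs(got[0] - c1) <= 1 and abs(got[1] - c2) <= 1
    return n_ok / n_profiles


def calibration_accuracy(n_refs: int = 6, n_queries: int = 50, seed: int = 0) -> float:
    """Worst relative error of predicted mass for points on a noiseless
    log-linear reference line (leave-one-out plus dense interpolation)."""
    refs = cp.generate_calibration_refs(n_refs)
    rng = np.random.default_rng(seed)
    worst = 0.0
    for i in range(n_refs):
        keep = [j for j in range(n_refs) if j != i]
        curve = cp.fit_calibration(
            cp.CalibrationSet(refs.fractions[keep], refs.masses[keep])
        )
        err = abs(curve.mass_at(refs.fractions[i]) - refs.masses[i]) / refs.masses[i]
        worst = max(worst, err)
    curve = cp.fit_calibration(refs)
    full_slope, full_icpt = curve.slope, curve.intercept
    for f in rng.uniform(1, 38, n_queries):
        truth = 10 ** (full_slope * f + full_icpt)
        worst = max(worst, abs(curve.mass_at(f) - truth) / truth)
    return worst


def oligomeric_accuracy(
    cv: float, n_proteins: int = 200, n_replicates: int = 3, seed: int = 0
) -> float:
    """Monomer vs dimer/tetramer classification accuracy on simulated elutions.

    Each protein elutes as a single peak at the fraction its oligomer mass
    (1x, 2x or 4x the monomer) implies through the calibration line; the
    pipeline deconvolves the noisy replicates, calibrates the apparent mass
    and applies the 1.5 oligomeric-ratio rule.
    """
    rng = np.random.default_rng(seed)
    refs = cp.generate_calibration_refs(5)
    curve = cp.fit_calibration(refs)
    x = np.arange(1, 49, dtype=float)
    s = np.sqrt(np.log1p(cv**2))
    n_correct = 0
    for _ in range(n_proteins):
        mono = 10 ** rng.uniform(4.5, 5.5)
        k = rng.choice([1, 2, 4])
        center = float(np.clip(curve.fraction_of(k * mono), 2.0, 37.0))
        clean = gaussian(x, 1.0, center, 1.5)
        reps = [
            clean * rng.lognormal(-0.5 * s * s, s, x.size) if cv > 0 else clean
            for _ in range(n_replicates)
        ]
        peaks, _, _ = cp.deconvolve_replicates(reps, "P", "protein")
        if not peaks:
            continue
        peak = max(peaks, key=lambda p: p.amplitude)
        call = cp.classify_oligomeric("P", cp.apparent_mass(peak, curve), mono)
        n_correct += call.multimeric == (k > 1)
    return n_correct / n_proteins


def nparc_null_rejection(
    n_proteins: int = 300, noise_sd: float = 0.02, alpha: float = 0.05, seed: int = 0
) -> float:
    """Type-I error of the melting-curve F-test on shift-free simulations."""
    tpp, _ = cp.simulate_tpp(
        n_proteins=n_proteins, n_binders=0, delta_tm=0.0, noise_sd=noise_sd, seed=seed
    )
    res = cp.nparc_screen(tpp)
    return float((res["p_value"] <= alpha).mean())


def nparc_power(
    delta_tm: float,
    n_proteins: int = 50,
    noise_sd: float = 0.02,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Detection rate for a planted melting-point shift of ``delta_tm`` degC."""
    tpp, _ = cp.simulate_tpp(
        n_proteins=n_proteins,
        n_binders=n_proteins,
        delta_tm=delta_tm,
        noise_sd=noise_sd,
        seed=seed,
    )
    res = cp.nparc_screen(tpp)
    return float((res["p_value"] <= alpha).mean())


def kd_recovery(
    n_ladders: int = 100,
    kd_true: float = 416e-6,
    target_conc: float = 50e-9,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> tuple[float, float]:
    """(relative bias, relative RMSE) of Kd estimates on simulated
    16-point 2x dilution ladders with additive response noise."""
    rng = np.random.default_rng(seed)
    ladder = 10e-3 / 2 ** np.arange(16)
    estimates = []
    for _ in range(n_ladders):
        y = cp.quadratic_isotherm(ladder, kd_true, 0.0, 1.0, target_conc)
        y = y + rng.normal(0.0, noise_sd, y.size)
        fit = cp.fit_kd(ladder, y, target_conc=target_conc)
        if np.isfinite(fit.kd):
            estimates.append(fit.kd)
    est = np.array(estimates)
    bias = abs(est.mean() - kd_true) / kd_true
    rmse = float(np.sqrt(((est - kd_true) ** 2).mean())) / kd_true
    return float(bias), rmse


def pcc_formula_agreement(n_pairs: int = 1000, length: int = 12, seed: int = 0) -> float:
    """Worst absolute deviation of pcc() from the product-moment formula."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_pairs):
        x, y = rng.normal(size=(2, length)) + 1.0
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        worst = max(worst, abs(cp.pcc(x, y) - num / den))
    return worst


def bh_stepup_agreement(n_vectors: int = 200, max_len: int = 50, seed: int = 0) -> float:
    """Worst absolute deviation of bh_adjust() from the step-up definition."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_vectors):
        p = rng.uniform(0, 1, rng.integers(1, max_len + 1))
        m = p.size
        order = np.argsort(p, kind="mergesort")
        q_sorted = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        q = np.empty(m)
        q[order] = np.minimum(q_sorted, 1.0)
        worst = max(worst, float(np.max(np.abs(cp.bh_adjust(p) - q))))
    return worst
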