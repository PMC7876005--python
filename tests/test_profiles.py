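"""Profile normalisation, deconvolution, calibration and oligomeric calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cofrac_pmi as cp
from cofrac_pmi.profiles import (
    CalibrationSet,
    PeakPickingParams,
    gaussian,
    reconstruction_residual,
)


class TestIO:
    def test_round_trip_via_tsv(self, tmp_path, small_sim):
        _, dataset, _, _ = small_sim
        prot_ids = dataset.features_of_kind("protein")
        sub = cp.FractionationDataset(
            intensities={r: df.loc[prot_ids] for r, df in dataset.intensities.items()},
            feature_kind=dataset.feature_kind[prot_ids],
            monomeric_mass=dataset.monomeric_mass[prot_ids],
        )
        paths = sub.write_tsv(tmp_path, "proteins")
        back = cp.read_fraction_table(paths, "protein")
        for rep_w, rep_r in zip(sub.replicate_ids, back.replicate_ids):
            np.testing.assert_allclose(
                back.intensities[rep_r].to_numpy(), sub.intensities[rep_w].to_numpy()
            )
        np.testing.assert_allclose(
            back.monomeric_mass.to_numpy(), sub.monomeric_mass.to_numpy()
        )

    def test_small_table_reads(self, tmp_path):
        path = tmp_path / "toy.tsv"
        path.write_text("feature_id\tF1\tF2\tF3\tF4\nA\t1\t2\t3\t4\nB\t0\t1\t0\t1\n")
        ds = cp.read_fraction_table(path, "metabolite")
        assert ds.n_fractions == 4 and len(ds.feature_ids) == 2

    def test_negative_intensity_names_location(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("feature_id\tF1\tF2\nA\t1\t2\nB\t3\t-4\n")
        with pytest.raises(ValueError, match="'B'.*'F2'"):
            cp.read_fraction_table(path, "protein")

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("feature_id\tF1\tF2\nA\t1\t2\nA\t3\t4\n")
        with pytest.raises(ValueError, match="duplicate"):
            cp.read_fraction_table(path, "protein")


class TestNormalize:
    def test_divides_by_maximum(self):
        prof = cp.normalize_profile([2, 4, 8, 4])
        np.testing.assert_allclose(prof.intensities, [0.25, 0.5, 1.0, 0.5])
        assert not prof.all_zero

    def test_all_zero_flagged(self):
        prof = cp.normalize_profile([0, 0, 0])
        assert prof.all_zero and prof.intensities.max() == 0

    @given(st.lists(st.floats(0, 1e9), min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_max_is_one_or_flagged(self, values):
        prof = cp.normalize_profile(values)
        assert prof.all_zero or prof.intensities.max() == pytest.approx(1.0)


class TestAverageReplicates:
    def test_identical_replicates(self):
        p = cp.normalize_profile([1, 3, 2, 1])
        mean, repro = cp.average_replicates([p, p, p])
        np.testing.assert_allclose(mean.intensities, p.intensities)
        assert repro == pytest.approx(1.0)

    def test_single_replicate_has_no_reproducibility(self):
        p = cp.normalize_profile([1, 3, 2, 1])
        mean, repro = cp.average_replicates([p])
        assert repro is None

    def test_reproducibility_matches_brute_force(self):
        rng = np.random.default_rng(0)
        base = gaussian(np.arange(20.0), 1.0, 9.0, 2.0)
        reps = [cp.normalize_profile(base * rng.lognormal(0, 0.1, 20)) for _ in range(3)]
        _, repro = cp.average_replicates(reps)
        expected = np.mean(
            [
                np.corrcoef(reps[i].intensities, reps[j].intensities)[0, 1]
                for i in range(3)
                for j in range(i + 1, 3)
            ]
        )
        assert repro == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_fails(self):
        with pytest.raises(ValueError, match="length"):
            cp.average_replicates(
                [cp.normalize_profile([1, 2]), cp.normalize_profile([1, 2, 3])]
            )


class TestDeconvolve:
    x = np.arange(1, 49, dtype=float)

    def test_single_gaussian_center_recovered(self):
        prof = cp.normalize_profile(gaussian(self.x, 1.0, 15.0, 1.5))
        peaks = cp.deconvolve(prof)
        assert len(peaks) == 1
        assert abs(peaks[0].center - 15.0) <= 0.1

    def test_two_gaussians_resolved(self):
        mix = gaussian(self.x, 1.0, 10.0, 1.5) + gaussian(self.x, 1.0, 20.0, 1.5)
        peaks = cp.deconvolve(cp.normalize_profile(mix))
        assert len(peaks) == 2
        centers = sorted(p.center for p in peaks)
        assert abs(centers[0] - 10) <= 1 and abs(centers[1] - 20) <= 1

    def test_flat_profile_yields_nothing(self):
        assert cp.deconvolve(cp.normalize_profile(np.zeros(48))) == []

    def test_reconstruction_residual_small(self):
        mix = gaussian(self.x, 1.0, 12.0, 1.5) + gaussian(self.x, 0.6, 25.0, 2.0)
        prof = cp.normalize_profile(mix)
        peaks = cp.deconvolve(prof)
        assert reconstruction_residual(prof, peaks) < 0.05

    def test_replicate_support_filter_drops_unreproduced_apex(self):
        base = gaussian(self.x, 1.0, 12.0, 1.5)
        ghost = gaussian(self.x, 0.5, 30.0, 1.5)
        reps = [base + ghost, base, base]  # ghost peak in 1 of 3 replicates
        peaks, _, _ = cp.deconvolve_replicates(reps)
        assert [round(p.center) for p in peaks] == [12]

    def test_planted_k_peak_recovery_rate(self):
        # two planted peaks, >= 4 sigma apart, 10% CV: both recovered +-1
        rng = np.random.default_rng(1)
        ok = 0
        n = 100
        for _ in range(n):
            c1 = rng.uniform(5, 25)
            c2 = c1 + rng.uniform(6, 12)
            clean = gaussian(self.x, 1.0, c1, 1.5) + gaussian(self.x, rng.uniform(0.4, 1), c2, 1.5)
            s = np.sqrt(np.log1p(0.1**2))
            noisy = clean * rng.lognormal(-s * s / 2, s, 48)
            peaks = cp.deconvolve(cp.normalize_profile(noisy))
            if len(peaks) == 2:
                got = sorted(p.center for p in peaks)
                ok += abs(got[0] - c1) <= 1 and abs(got[1] - c2) <= 1
        assert ok / n >= 0.95


class TestCalibration:
    def test_exact_line_r2_one(self):
        refs = cp.generate_calibration_refs(5)
        curve = cp.fit_calibration(refs)
        assert curve.r_squared == pytest.approx(1.0)
        for f, m in zip(refs.fractions, refs.masses):
            assert curve.mass_at(f) == pytest.approx(m, rel=1e-9)

    def test_two_points_interpolate_exactly(self):
        refs = CalibrationSet(fractions=[5, 30], masses=[1e6, 5e4])
        curve = cp.fit_calibration(refs)
        assert curve.mass_at(5) == pytest.approx(1e6, rel=1e-9)
        assert curve.mass_at(30) == pytest.approx(5e4, rel=1e-9)

    def test_held_out_prediction_under_one_percent(self):
        refs = cp.generate_calibration_refs(6)
        train = CalibrationSet(refs.fractions[:5], refs.masses[:5])
        curve = cp.fit_calibration(train)
        pred = curve.mass_at(refs.fractions[5])
        assert abs(pred - refs.masses[5]) / refs.masses[5] < 0.01

    def test_monotone_decreasing(self):
        curve = cp.fit_calibration(cp.generate_calibration_refs(5))
        fr = np.linspace(1, 38, 100)
        masses = [curve.mass_at(f) for f in fr]
        assert all(a > b for a, b in zip(masses, masses[1:]))

    def test_degenerate_refs_fail(self):
        with pytest.raises(ValueError):
            cp.fit_calibration(CalibrationSet([5.0], [1e6]))
        with pytest.raises(ValueError):
            cp.fit_calibration(CalibrationSet([5.0, 5.0], [1e6, 2e5]))
        with pytest.raises(ValueError, match="slope"):
            cp.fit_calibration(CalibrationSet([5.0, 10.0], [1e5, 1e6]))


class TestApparentMass:
    def _peak(self, center):
        return cp.ElutionPeak(
            feature_id="P", kind="protein", ordinal=1, amplitude=1.0,
            center=center, width=1.5, support=(1, 10), single_peak_profile=np.zeros(48),
        )

    def test_reference_fraction_returns_reference_mass(self):
        refs = cp.generate_calibration_refs(5)
        curve = cp.fit_calibration(refs)
        peak = cp.apparent_mass(self._peak(refs.fractions[2]), curve)
        assert peak.apparent_mass == pytest.approx(refs.masses[2], rel=1e-9)
        assert not peak.mass_extrapolated

    def test_midpoint_is_geometric_mean(self):
        refs = CalibrationSet(fractions=[10, 20], masses=[1e6, 1e4])
        curve = cp.fit_calibration(refs)
        peak = cp.apparent_mass(self._peak(15.0), curve)
        assert peak.apparent_mass == pytest.approx(np.sqrt(1e6 * 1e4), rel=1e-9)

    def test_outside_span_flagged(self):
        curve = cp.fit_calibration(cp.generate_calibration_refs(3))
        peak = cp.apparent_mass(self._peak(45.0), curve)
        assert peak.mass_extrapolated and peak.apparent_mass > 0


class TestOligomeric:
    def _peak_with_mass(self, mass):
        p = TestApparentMass()._peak(10.0)
        p.apparent_mass = mass
        return p

    @pytest.mark.parametrize(
        "apparent, mono, ratio, multimeric",
        [
            (138e3, 33e3, 4.18, True),
            (88e3, 33e3, 2.67, True),
            (33e3, 33e3, 1.0, False),
        ],
    )
    def test_ratio_and_call(self, apparent, mono, ratio, multimeric):
        call = cp.classify_oligomeric("Pnp1", self._peak_with_mass(apparent), mono)
        assert call.ratio == pytest.approx(ratio, abs=0.01)
        assert call.multimeric is multimeric

    @given(st.floats(0.01, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, scale):
        a = cp.classify_oligomeric("P", self._peak_with_mass(1.0e5), 4.0e4)
        b = cp.classify_oligomeric("P", self._peak_with_mass(1.0e5 * scale), 4.0e4 * scale)
        assert a.multimeric == b.multimeric
        assert a.ratio == pytest.approx(b.ratio, rel=1e-9)

    def test_missing_mass_refused(self):
        with pytest.raises(ValueError, match="monomeric mass"):
            cp.classify_oligomeric("P", self._peak_with_mass(1e5), 0.0)
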