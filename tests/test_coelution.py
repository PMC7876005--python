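"""Co-elution scoring, null model, ROC/FDR and network calling."""

import numpy as np
import pandas as pd
import pytest

import cofrac_pmi as cp
from cofrac_pmi.coelution import (
    InteractionCandidate,
    KnownInteractionSet,
    NullDistribution,
)
from cofrac_pmi.profiles import gaussian


def _peak(fid, kind, ordinal, center, width=1.5, n=48):
    x = np.arange(1, n + 1, dtype=float)
    prof = gaussian(x, 1.0, center, width)
    prof[prof < 1e-6] = 0.0
    return cp.ElutionPeak(
        feature_id=fid, kind=kind, ordinal=ordinal, amplitude=1.0,
        center=center, width=width, support=(1, n), single_peak_profile=prof,
    )


class TestPcc:
    def test_identity_and_inversion(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        assert cp.pcc(x, x) == pytest.approx(1.0)
        assert cp.pcc(x, 10 - x) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        assert cp.pcc([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_zero_variance_is_undefined(self):
        with pytest.raises(ValueError, match="variance"):
            cp.pcc([1, 1, 1, 1], [1, 2, 3, 4])

    def test_matches_product_moment_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            x, y = rng.normal(size=(2, 12)) + 1.0
            num = np.sum((x - x.mean()) * (y - y.mean()))
            den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
            assert abs(cp.pcc(x, y) - num / den) < 1e-12


class TestScorePairs:
    def test_colocated_peaks_score_one(self):
        cands = cp.score_pairs([_peak("M1", "metabolite", 1, 15.0)], [_peak("P1", "protein", 1, 15.0)])
        assert len(cands) == 1
        assert cands[0].r == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_supports_score_nonpositive(self):
        cands = cp.score_pairs([_peak("M1", "metabolite", 1, 8.0)], [_peak("P1", "protein", 1, 30.0)])
        assert cands and cands[0].r <= 0

    def test_all_combinations_scored(self):
        mets = [_peak("M1", "metabolite", i, 10.0 + 5 * i) for i in range(1, 4)]
        prots = [_peak(f"P{j}", "protein", 1, 12.0 + 4 * j) for j in range(1, 3)]
        assert len(cp.score_pairs(mets, prots)) == 6


class TestPairScore:
    def _cands(self, rs):
        return [
            InteractionCandidate("M1", i + 1, "P1", 1, r) for i, r in enumerate(rs)
        ]

    def test_max_over_combinations(self):
        assert cp.pair_score("M1", "P1", self._cands([0.2, 0.8])) == 0.8
        assert cp.pair_score("M1", "P1", self._cands([0.9])) == 0.9

    def test_missing_pair_raises(self):
        with pytest.raises(KeyError):
            cp.pair_score("M2", "P1", self._cands([0.5]))

    def test_table_matches_exhaustive_max(self):
        rng = np.random.default_rng(2)
        cands = [
            InteractionCandidate(f"M{rng.integers(3)}", int(rng.integers(1, 3)),
                                 f"P{rng.integers(4)}", int(rng.integers(1, 3)),
                                 float(rng.uniform(-1, 1)))
            for _ in range(200)
        ]
        table = cp.pair_score_table(cands)
        for (m, p), score in table.items():
            brute = max(c.r for c in cands if c.metabolite_id == m and c.protein_id == p)
            assert score == brute


class TestTrueSet:
    def test_restricts_to_detected(self):
        known = pd.DataFrame(
            {"chemical_id": ["M1", "M2", "M3", "M4", "M5"],
             "protein_id": ["P1", "P2", "P3", "P4", "P5"]}
        )
        ts = cp.build_true_set(known, ["M1", "M2", "M3"], ["P1", "P2", "P3"])
        assert ts.pairs == {("M1", "P1"), ("M2", "P2"), ("M3", "P3")}

    def test_duplicates_collapse(self):
        known = pd.DataFrame({"chemical_id": ["M1", "M1"], "protein_id": ["P1", "P1"]})
        assert cp.build_true_set(known, ["M1"], ["P1"]).n_pairs == 1

    def test_empty_intersection_fails(self):
        known = pd.DataFrame({"chemical_id": ["M9"], "protein_id": ["P9"]})
        with pytest.raises(ValueError, match="no known interaction"):
            cp.build_true_set(known, ["M1"], ["P1"])


class TestNull:
    scores = {("M1", "P1"): 0.9, ("M1", "P2"): 0.1, ("M2", "P1"): 0.3}
    true_set = KnownInteractionSet({("M1", "P1")})

    def test_shape_and_determinism(self):
        a = cp.sample_null(["M1", "M2"], ["P1", "P2"], self.scores, self.true_set,
                           n_pairs=2, n_iterations=10, seed=3)
        b = cp.sample_null(["M1", "M2"], ["P1", "P2"], self.scores, self.true_set,
                           n_pairs=2, n_iterations=10, seed=3)
        assert a.scores.shape == (10, 2)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_true_pairs_excluded(self):
        null = cp.sample_null(["M1", "M2"], ["P1", "P2"], self.scores, self.true_set,
                              n_pairs=3, n_iterations=50, seed=0)
        assert not (null.scores == 0.9).any()  # the known pair's score never drawn

    def test_unscored_pairs_get_floor(self):
        null = cp.sample_null(["M1", "M2"], ["P1", "P2"], self.scores, self.true_set,
                              n_pairs=3, n_iterations=5, seed=0)
        assert (null.scores == -1.0).any()  # ("M2","P2") was never co-scored

    def test_too_few_eligible_fails(self):
        with pytest.raises(ValueError, match="eligible"):
            cp.sample_null(["M1"], ["P1"], self.scores, self.true_set, n_pairs=1, seed=0)

    def test_null_mean_tracks_exhaustive_mean_without_planting(self):
        rng = np.random.default_rng(7)
        mets = [f"M{i}" for i in range(12)]
        prots = [f"P{i}" for i in range(20)]
        scores = {(m, p): float(rng.uniform(-1, 1)) for m in mets for p in prots}
        # one token "true" pair so the exclusion machinery is exercised
        ts = KnownInteractionSet({(mets[0], prots[0])})
        null = cp.sample_null(mets, prots, scores, ts, n_pairs=30, n_iterations=200, seed=1)
        eligible_mean = np.mean([v for k, v in scores.items() if k not in ts.pairs])
        assert null.scores.mean() == pytest.approx(eligible_mean, abs=0.02)


class TestRocFdr:
    def _setup(self, true_scores, null_scores):
        ts = KnownInteractionSet({(f"M{i}", f"P{i}") for i in range(len(true_scores))})
        scores = {(f"M{i}", f"P{i}"): s for i, s in enumerate(true_scores)}
        null = NullDistribution(np.asarray(null_scores, dtype=float), seed=0)
        return ts, null, scores

    def test_perfect_separation_auc_one(self):
        ts, null, scores = self._setup([0.95] * 10, [[0.05] * 10] * 5)
        roc = cp.roc_analysis(ts, null, scores)
        assert roc.auc == pytest.approx(1.0)

    def test_same_distribution_auc_half(self):
        rng = np.random.default_rng(5)
        draws = rng.uniform(-1, 1, 400)
        ts, null, scores = self._setup(draws[:200], draws[200:].reshape(1, 200))
        roc = cp.roc_analysis(ts, null, scores)
        assert roc.auc == pytest.approx(0.5, abs=0.08)

    def test_boundary_rates_are_one(self):
        ts, null, scores = self._setup([0.5, 0.9], [[0.1, 0.2]])
        roc = cp.roc_analysis(ts, null, scores)
        assert roc.tpr[0] == 1.0 and roc.fpr[0] == 1.0

    def test_rates_monotone_in_threshold(self):
        rng = np.random.default_rng(6)
        ts, null, scores = self._setup(rng.uniform(-1, 1, 50), rng.uniform(-1, 1, (10, 50)))
        roc = cp.roc_analysis(ts, null, scores)
        assert (np.diff(roc.tpr) <= 1e-12).all()
        assert (np.diff(roc.fpr) <= 1e-12).all()

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(8)
        true_s = rng.uniform(0, 1, 40)
        null_s = rng.uniform(0, 1, (5, 40))
        ts, null, scores = self._setup(true_s, null_s)
        roc1 = cp.roc_analysis(ts, null, scores)
        f = lambda s: s**3  # strictly monotone on [0, 1]
        ts2, null2, scores2 = self._setup(f(true_s), f(null_s))
        roc2 = cp.roc_analysis(
            ts2, null2, scores2, thresholds=f(np.linspace(0, 1, 201))
        )
        assert roc2.auc == pytest.approx(roc1.auc, abs=0.02)

    def test_fdr_operating_points(self):
        # mean null positives 3 vs 14 true positives -> 3/17 ~ 17.6%
        ts, null, scores = self._setup([0.9] * 14, [[0.9] * 3 + [0.1] * 11])
        assert cp.fdr_at_threshold(ts, null, scores, 0.7) == pytest.approx(0.176, abs=0.001)
        # no null positives -> 0
        ts, null, scores = self._setup([0.9] * 14, [[0.1] * 14])
        assert cp.fdr_at_threshold(ts, null, scores, 0.7) == 0.0
        # no true positives -> 1
        ts, null, scores = self._setup([0.1] * 5, [[0.9] * 5])
        assert cp.fdr_at_threshold(ts, null, scores, 0.7) == 1.0
        # nothing passes -> undefined
        ts, null, scores = self._setup([0.1], [[0.1]])
        assert cp.fdr_at_threshold(ts, null, scores, 0.7) is None

    def test_enrichment_over_chance(self):
        ts, null, scores = self._setup(
            [0.9] * 14, [[0.9, 0.9, 0.9, 0.9, 0.1] + [0.1] * 9,
                         [0.9, 0.9, 0.1, 0.1, 0.1] + [0.1] * 9]
        )
        m_null = ((null.scores >= 0.7).sum(axis=1)).mean()  # (4+2)/2 = 3
        fold = cp.enrichment_over_chance(ts, null, scores, 0.7)
        assert fold == pytest.approx(14 / m_null)
        ts, null, scores = self._setup([0.9] * 5, [[0.1] * 5])
        assert cp.enrichment_over_chance(ts, null, scores, 0.7) == float("inf")


class TestNetwork:
    def _candidates(self):
        rng = np.random.default_rng(9)
        return [
            InteractionCandidate(f"M{m}", k, f"P{p}", 1, float(rng.uniform(-1, 1)))
            for m in range(5) for p in range(8) for k in (1, 2)
        ]

    def test_impossible_threshold_empty(self):
        assert cp.call_interactions(self._candidates(), threshold=1.01).n_edges == 0

    def test_lowering_threshold_only_adds_edges(self):
        cands = self._candidates()
        high = cp.call_interactions(cands, threshold=0.8).pairs()
        low = cp.call_interactions(cands, threshold=0.3).pairs()
        assert high <= low

    def test_edges_match_brute_force(self):
        cands = self._candidates()
        net = cp.call_interactions(cands, threshold=0.5)
        table = cp.pair_score_table(cands)
        expected = {k for k, v in table.items() if v >= 0.5}
        assert net.pairs() == expected
        assert all(e.score >= 0.5 for e in net.edges)


class TestValidatePredicted:
    def test_empty_list(self):
        net = cp.call_interactions([InteractionCandidate("M1", 1, "P1", 1, 0.9)], 0.7)
        edges, n_int, n_met = cp.validate_predicted(net, pd.DataFrame())
        assert (edges, n_int, n_met) == ([], 0, 0)

    def test_counts_equal_set_intersection(self):
        rng = np.random.default_rng(10)
        cands = [
            InteractionCandidate(f"M{m}", 1, f"P{p}", 1, float(rng.uniform(0, 1)))
            for m in range(6) for p in range(6)
        ]
        net = cp.call_interactions(cands, threshold=0.5)
        predicted = pd.DataFrame(
            {
                "chemical_id": [f"M{rng.integers(6)}" for _ in range(12)],
                "protein_id": [f"P{rng.integers(6)}" for _ in range(12)],
                "score": rng.uniform(0, 1, 12),
            }
        )
        edges, n_int, n_met = cp.validate_predicted(net, predicted, min_score=0.4)
        keep = predicted[predicted.score >= 0.4]
        expected = net.pairs() & set(zip(keep.chemical_id, keep.protein_id))
        assert {(e.metabolite_id, e.protein_id) for e in edges} == expected
        assert n_int == len(expected)
        assert n_met == len({m for m, _ in expected})

    def test_score_filter_applied(self):
        net = cp.call_interactions([InteractionCandidate("M1", 1, "P1", 1, 0.9)], 0.7)
        predicted = pd.DataFrame(
            {"chemical_id": ["M1"], "protein_id": ["P1"], "score": [0.2]}
        )
        _, n_int, _ = cp.validate_predicted(net, predicted, min_score=0.4)
        assert n_int == 0
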