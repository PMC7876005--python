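"""Co-elution scoring, ROC threshold selection, FDR and the PMI network.

Candidate interactions are scored by the Pearson correlation coefficient
(PCC) between deconvolved single-peak profiles of metabolites and proteins
over the protein-containing fraction window. A feature pair's score is the
maximum over its peak-pair combinations: co-elution of any single peak is
the evidence of interest, and PCC magnitude is not used to rank called
edges. The PCC threshold is chosen from a ROC curve comparing scores of
known interactions against repeated random protein-metabolite pairings
(default 100 iterations), from which the false discovery rate and the fold
enrichment over chance at the operating point are estimated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from cofrac_pmi.profiles import ElutionPeak

__all__ = [
    "InteractionCandidate",
    "KnownInteractionSet",
    "NullDistribution",
    "RocResult",
    "PmiNetwork",
    "pcc",
    "score_pairs",
    "pair_score",
    "pair_score_table",
    "build_true_set",
    "sample_null",
    "roc_analysis",
    "fdr_at_threshold",
    "enrichment_over_chance",
    "call_interactions",
    "validate_predicted",
]

#: score assigned to pairs that were never co-scored (below any real PCC)
SCORE_FLOOR = -1.0

#: default PCC threshold for calling interactions
DEFAULT_THRESHOLD = 0.7


@dataclass(frozen=True)
class InteractionCandidate:
    """A scored metabolite-peak x protein-peak combination."""

    metabolite_id: str
    metabolite_peak: int
    protein_id: str
    protein_peak: int
    r: float


def pcc(x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray) -> float:
    """Pearson product-moment correlation of two elution vectors.

    Requires equal length >= 3, at least 3 nonzero entries in each vector and
    nonzero variance; otherwise the correlation is undefined and a
    ``ValueError`` is raised (callers exclude the pair rather than scoring 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be 1-D and equal length")
    if x.size < 3:
        raise ValueError("need at least 3 fractions")
    if np.count_nonzero(x) < 3 or np.count_nonzero(y) < 3:
        raise ValueError("need at least 3 nonzero entries per vector")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def score_pairs(
    metabolite_peaks: Sequence[ElutionPeak],
    protein_peaks: Sequence[ElutionPeak],
    window: tuple[int, int] = (1, 38),
) -> list[InteractionCandidate]:
    """PCC for every metabolite-peak x protein-peak combination.

    Scores are computed on the fitted single-peak profiles restricted to the
    1-based closed fraction ``window`` (by default the protein-containing
    span; metabolite signal beyond it is free pool and never scored).
    Combinations whose windowed vectors fail the PCC preconditions are
    excluded, not scored zero.
    """
    lo, hi = window
    sl = slice(lo - 1, hi)
    candidates = []
    for mp in metabolite_peaks:
        mx = mp.single_peak_profile[sl]
        for pp in protein_peaks:
            px = pp.single_peak_profile[sl]
            try:
                r = pcc(mx, px)
            except ValueError:
                continue
            candidates.append(
                InteractionCandidate(mp.feature_id, mp.ordinal, pp.feature_id, pp.ordinal, r)
            )
    return candidates


def pair_score(
    metabolite_id: str, protein_id: str, candidates: Iterable[InteractionCandidate]
) -> float:
    """Feature-level score: the maximum r over all peak-pair combinations.

    Raises ``KeyError`` when the pair has no scored candidate (the pair is
    absent from scoring, not scored 0).
    """
    rs = [
        c.r
        for c in candidates
        if c.metabolite_id == metabolite_id and c.protein_id == protein_id
    ]
    if not rs:
        raise KeyError(f"no scored candidate for pair ({metabolite_id}, {protein_id})")
    return max(rs)


def pair_score_table(candidates: Iterable[InteractionCandidate]) -> dict[tuple[str, str], float]:
    """Max-over-peaks score for every feature pair with at least one candidate."""
    table: dict[tuple[str, str], float] = {}
    for c in candidates:
        key = (c.metabolite_id, c.protein_id)
        if key not in table or c.r > table[key]:
            table[key] = c.r
    return table


@dataclass
class KnownInteractionSet:
    """Known (reference) interactions restricted to detected features."""

    pairs: set[tuple[str, str]]  # (metabolite_id, protein_id)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def build_true_set(
    known: pd.DataFrame | str | Path,
    detected_metabolites: Iterable[str],
    detected_proteins: Iterable[str],
) -> KnownInteractionSet:
    """Restrict a known-interaction list to features detected in the dataset.

    ``known`` is a DataFrame or TSV path with columns ``chemical_id`` and
    ``protein_id`` (STITCH-export-like); duplicate rows collapse to one pair.
    """
    if not isinstance(known, pd.DataFrame):
        known = pd.read_csv(known, sep="\t")
    missing = {"chemical_id", "protein_id"} - set(known.columns)
    if missing:
        raise ValueError(f"known-interaction list missing columns {sorted(missing)}")
    mets = set(detected_metabolites)
    prots = set(detected_proteins)
    pairs = {
        (str(m), str(p))
        for m, p in zip(known["chemical_id"], known["protein_id"])
        if m in mets and p in prots
    }
    if not pairs:
        raise ValueError(
            "no known interaction has both partners detected in the dataset "
            f"({len(known)} listed; {len(mets)} metabolites / {len(prots)} proteins detected)"
        )
    return KnownInteractionSet(pairs=pairs)


@dataclass
class NullDistribution:
    """Random-pair score samples: n_iterations x n_pairs."""

    scores: np.ndarray  # shape (n_iterations, n_pairs)
    seed: int

    @property
    def n_iterations(self) -> int:
        return self.scores.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.scores.shape[1]


def sample_null(
    metabolite_ids: Sequence[str],
    protein_ids: Sequence[str],
    scores: Mapping[tuple[str, str], float],
    true_set: KnownInteractionSet,
    n_pairs: int | None = None,
    n_iterations: int = 100,
    seed: int = 0,
) -> NullDistribution:
    """Sample random protein-metabolite pairings as the false-positive model.

    Each iteration draws ``n_pairs`` pairs (default: the size of the true
    set) uniformly without replacement from the detected metabolite x protein
    product, excluding the known-true pairs. A sampled pair never co-scored
    gets the scoring floor (-1).
    """
    if n_pairs is None:
        n_pairs = true_set.n_pairs
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    eligible = [
        (m, p)
        for m in metabolite_ids
        for p in protein_ids
        if (m, p) not in true_set.pairs
    ]
    if len(eligible) < n_pairs:
        raise ValueError(
            f"only {len(eligible)} eligible random pairs; cannot draw {n_pairs}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty((n_iterations, n_pairs))
    for it in range(n_iterations):
        idx = rng.choice(len(eligible), size=n_pairs, replace=False)
        out[it] = [scores.get(eligible[i], SCORE_FLOOR) for i in idx]
    return NullDistribution(scores=out, seed=seed)


@dataclass
class RocResult:
    """Threshold trade-off between recovered true and random-pair positives."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    chosen_threshold: float
    fdr_at_chosen: float | None
    fold_enrichment_at_chosen: float
    n_true_positive_at_chosen: int


def _true_scores(
    true_set: KnownInteractionSet, scores: Mapping[tuple[str, str], float]
) -> np.ndarray:
    return np.array([scores.get(pair, SCORE_FLOOR) for pair in sorted(true_set.pairs)])


def roc_analysis(
    true_set: KnownInteractionSet,
    null: NullDistribution,
    scores: Mapping[tuple[str, str], float],
    thresholds: np.ndarray | None = None,
    chosen_threshold: float = DEFAULT_THRESHOLD,
) -> RocResult:
    """ROC of known-interaction scores against the random-pair null.

    TPR(t) is the fraction of known pairs scoring >= t; FPR(t) is the mean
    over null iterations of the fraction of random pairs scoring >= t. The
    AUC is the trapezoid over (FPR, TPR). Known pairs never co-scored carry
    the scoring floor, so both rates are 1 at t = -1.
    """
    if true_set.n_pairs == 0:
        raise ValueError("true set is empty")
    if thresholds is None:
        thresholds = np.linspace(SCORE_FLOOR, 1.0, 201)
    ts = _true_scores(true_set, scores)
    tpr = np.array([(ts >= t).mean() for t in thresholds])
    fpr = np.array([(null.scores >= t).mean() for t in thresholds])
    order = np.argsort(fpr)
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    return RocResult(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        auc=auc,
        chosen_threshold=chosen_threshold,
        fdr_at_chosen=fdr_at_threshold(true_set, null, scores, chosen_threshold),
        fold_enrichment_at_chosen=enrichment_over_chance(
            true_set, null, scores, chosen_threshold
        ),
        n_true_positive_at_chosen=int((ts >= chosen_threshold).sum()),
    )


def fdr_at_threshold(
    true_set: KnownInteractionSet,
    null: NullDistribution,
    scores: Mapping[tuple[str, str], float],
    threshold: float,
) -> float | None:
    """Estimated false discovery rate at a PCC threshold.

    FDR(t) = m_null / (m_null + m_true), where m_null is the mean
    per-iteration count of random pairs scoring >= t and m_true the count of
    known pairs scoring >= t. Returns ``None`` when both counts are zero.
    """
    m_true = int((_true_scores(true_set, scores) >= threshold).sum())
    m_null = float((null.scores >= threshold).sum(axis=1).mean())
    if m_true == 0 and m_null == 0:
        return None
    return m_null / (m_null + m_true)


def enrichment_over_chance(
    true_set: KnownInteractionSet,
    null: NullDistribution,
    scores: Mapping[tuple[str, str], float],
    threshold: float,
) -> float:
    """Recovered known interactions relative to the number expected by chance.

    fold = m_true / m_null; infinite (``inf``) when no random pair passes.
    """
    m_true = int((_true_scores(true_set, scores) >= threshold).sum())
    m_null = float((null.scores >= threshold).sum(axis=1).mean())
    if m_null == 0:
        return float("inf")
    return m_true / m_null


@dataclass
class PmiEdge:
    """One called protein-metabolite interaction."""

    metabolite_id: str
    protein_id: str
    score: float  # max pair score; qualitative evidence, not a ranking
    peak_pairs: list[tuple[int, int]]  # contributing (metabolite peak, protein peak)
    provenance: str = "novel"  # novel | known | predicted


@dataclass
class PmiNetwork:
    """The thresholded protein-metabolite interaction network."""

    edges: list[PmiEdge]
    threshold: float

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def pairs(self) -> set[tuple[str, str]]:
        return {(e.metabolite_id, e.protein_id) for e in self.edges}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "metabolite_id": e.metabolite_id,
                    "protein_id": e.protein_id,
                    "score": e.score,
                    "n_peak_pairs": len(e.peak_pairs),
                    "provenance": e.provenance,
                }
                for e in self.edges
            ],
            columns=["metabolite_id", "protein_id", "score", "n_peak_pairs", "provenance"],
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for e in self.edges:
            g.add_node(e.metabolite_id, kind="metabolite")
            g.add_node(e.protein_id, kind="protein")
            g.add_edge(
                e.metabolite_id, e.protein_id, score=e.score, provenance=e.provenance
            )
        return g


def call_interactions(
    candidates: Iterable[InteractionCandidate],
    threshold: float = DEFAULT_THRESHOLD,
    known: KnownInteractionSet | None = None,
) -> PmiNetwork:
    """Call edges for every feature pair whose max peak-pair score >= threshold.

    Edge scores are retained as qualitative evidence of co-elution; they are
    deliberately not a ranking of interaction strength.
    """
    candidates = list(candidates)
    by_pair: dict[tuple[str, str], list[InteractionCandidate]] = {}
    for c in candidates:
        by_pair.setdefault((c.metabolite_id, c.protein_id), []).append(c)
    edges = []
    for (mid, pid), group in sorted(by_pair.items()):
        best = max(c.r for c in group)
        if best >= threshold:
            contributing = [
                (c.metabolite_peak, c.protein_peak) for c in group if c.r >= threshold
            ]
            provenance = "known" if known and (mid, pid) in known.pairs else "novel"
            edges.append(PmiEdge(mid, pid, best, contributing, provenance))
    return PmiNetwork(edges=edges, threshold=threshold)


def validate_predicted(
    network: PmiNetwork,
    predicted: pd.DataFrame | str | Path,
    min_score: float = 0.4,
) -> tuple[list[PmiEdge], int, int]:
    """Intersect called edges with a predicted-interaction list.

    ``predicted`` has columns ``chemical_id``, ``protein_id`` and optionally
    ``score`` (predictions below ``min_score`` are ignored). Returns the
    validated edges (marked ``provenance='predicted'`` unless already known),
    the number of validated interactions and the number of unique metabolites
    they engage.
    """
    if not isinstance(predicted, pd.DataFrame):
        predicted = pd.read_csv(predicted, sep="\t")
    if predicted.empty:
        return [], 0, 0
    missing = {"chemical_id", "protein_id"} - set(predicted.columns)
    if missing:
        raise ValueError(f"predicted list missing columns {sorted(missing)}")
    if "score" in predicted.columns:
        predicted = predicted[predicted["score"] >= min_score]
    wanted = {
        (str(m), str(p)) for m, p in zip(predicted["chemical_id"], predicted["protein_id"])
    }
    validated = []
    for edge in network.edges:
        if (edge.metabolite_id, edge.protein_id) in wanted:
            if edge.provenance == "novel":
                edge.provenance = "predicted"
            validated.append(edge)
    n_mets = len({e.metabolite_id for e in validated})
    return validated, len(validated), n_mets
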