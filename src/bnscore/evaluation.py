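"""Benchmarking of score tables against gold-standard gene sets.

ROC-AUC is the Mann-Whitney probability (ties count 1/2); PR-AUC uses step
interpolation (average precision — no linear interpolation between recall
points).  Paired AUCs are compared with DeLong's test (one-sided, first
score vector larger).  Top-K enrichment is a Fisher's exact test on the
(top-K vs rest) x (benchmark vs not) table over the evaluated genes, with
training (seed/background) genes depleted before evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score
from statsmodels.stats.multitest import multipletests

from .data_io import GeneSet, GeneUniverse

__all__ = [
    "BenchmarkLabeling",
    "EnrichmentResult",
    "make_labeling",
    "roc_auc",
    "pr_auc",
    "delong_one_sided",
    "topk_enrichment",
    "bh_adjust",
]


@dataclass
class BenchmarkLabeling:
    """Evaluated genes (training depleted) with 0/1 benchmark labels."""

    genes: tuple[str, ...]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if set(np.unique(self.labels)) - {0, 1}:
            raise ValueError("labels must be 0/1")


@dataclass
class EnrichmentResult:
    k: int
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    bh_adjusted_p: float | None = None
    zero_cell_corrected: bool = False


def make_labeling(
    genes: Sequence[str],
    benchmark: GeneSet,
    training: Sequence[GeneSet] = (),
) -> BenchmarkLabeling:
    """Label genes by benchmark membership after removing training genes."""
    drop: set[str] = set()
    for gs in training:
        drop |= gs.members
    kept = tuple(g for g in genes if g not in drop)
    labels = np.fromiter((1 if g in benchmark.members else 0 for g in kept),
                         dtype=int, count=len(kept))
    return BenchmarkLabeling(kept, labels)


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, scores))


def pr_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.sum() == 0:
        raise ValueError("no positive labels")
    return float(average_precision_score(labels, scores))


# ---------------------------------------------------------------------------
# DeLong's test


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_structural(scores: np.ndarray, labels: np.ndarray):
    """AUC and structural components V10 (positives), V01 (negatives)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return auc, v10, v01


def delong_one_sided(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
) -> float:
    """One-sided DeLong p-value for AUC(scores_a) > AUC(scores_b).

    Both score vectors are evaluated on the same labels; the covariance of
    the paired AUCs is estimated from the structural components.  A
    degenerate (zero) variance returns p = 0.5 with a warning.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if a.shape != b.shape or a.shape != labels.shape:
        raise ValueError("score vectors and labels must have equal length")
    _check_two_classes(labels)
    auc_a, v10_a, v01_a = _delong_structural(a, labels)
    auc_b, v10_b, v01_b = _delong_structural(b, labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]))
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    var = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    if var <= 0:
        # zero variance: identical AUCs are a tie; otherwise the z statistic
        # diverges and the p-value is the sign-based limit
        if auc_a == auc_b:
            return 0.5
        warnings.warn("degenerate DeLong variance with unequal AUCs",
                      stacklevel=2)
        return 0.0 if auc_a > auc_b else 1.0
    z = (auc_a - auc_b) / np.sqrt(var)
    return float(stats.norm.sf(z))


# ---------------------------------------------------------------------------
# top-K enrichment


def topk_enrichment(
    table: pd.DataFrame,
    benchmark: GeneSet,
    universe: GeneUniverse | Sequence[str] | None,
    k: int,
    training: Sequence[GeneSet] = (),
    alternative: str = "two-sided",
) -> EnrichmentResult:
    """Fisher's exact enrichment of the top-K ranked genes in a benchmark set.

    ``table`` is a ranked score table (index = gene, ``rank`` column) whose
    rows are the evaluated genes; training gene sets are depleted from both
    margins first.  The rest of the evaluated genes serve as background.
    The odds ratio gets a Haldane-Anscombe 0.5 correction only when a zero
    cell occurs (flagged in the result).
    """
    drop: set[str] = set()
    for gs in training:
        drop |= gs.members
    if "rank" in table.columns:
        ordered = table.sort_values("rank")
    else:
        ordered = table
    evaluated = [g for g in ordered.index if g not in drop]
    if k > len(evaluated):
        raise ValueError(f"K = {k} exceeds the {len(evaluated)} evaluated genes")
    if universe is not None:
        uni = set(universe.genes if isinstance(universe, GeneUniverse) else universe)
        if not (benchmark.members & uni):
            raise ValueError("benchmark set is disjoint from the universe")
    top = set(evaluated[:k])
    bench = benchmark.members
    a = sum(1 for g in top if g in bench)
    b = k - a
    c = sum(1 for g in evaluated[k:] if g in bench)
    d = len(evaluated) - k - c
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative).pvalue)
    corrected = 0 in (a, b, c, d)
    if corrected:
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
    else:
        aa, bb, cc, dd = a, b, c, d
    odds = (aa * dd) / (bb * cc)
    return EnrichmentResult(
        k=k, table=((a, b), (c, d)), odds_ratio=float(odds), p_value=p,
        zero_cell_corrected=corrected,
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
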