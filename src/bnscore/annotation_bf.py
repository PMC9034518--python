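"""Per-annotation Bayes factors under conjugate risk (M1) / non-risk (M0) models.

Binary annotations use a Beta-Bernoulli model: the annotation rate theta_j
under model j carries a Beta(alpha_j, beta_j) prior, and the marginal
likelihood of observing k successes in n genes is

    p(D | alpha, beta) = B(alpha + k, n - k + beta) / B(alpha, beta).

Continuous annotations use a Normal-Inverse-Gamma model: mean mu | theta ~
N(mu0, theta/kappa), variance theta ~ IG(nu/2, nu*sigma2/2); the marginal of
a single observation is the non-standardized Student t

    t_nu(mu0, sigma2 * (1 + kappa) / kappa).

Hyperparameters are fitted by empirical Bayes from the seed genes (M1) and
background genes (M0); each candidate gene's Bayes factor is the ratio of its
single-observation marginals.  Annotations are pre-selected by a one-sided
Fisher's exact test (binary, enrichment in seeds) or a two-sided Welch t-test
(continuous).  All Bayes factors are accumulated in log space; a missing
annotation value contributes log BF = 0 (evidence-neutral).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import betaln

from .data_io import (
    BinaryAnnotationMatrix,
    ContinuousAnnotationMatrix,
    GeneSet,
)

__all__ = [
    "BetaHyperparams",
    "NIGHyperparams",
    "AnnotationSelection",
    "select_binary_annotations",
    "select_continuous_annotations",
    "fit_beta_hyperparams",
    "binary_log_marginal",
    "binary_marginal",
    "binary_log_bf",
    "fit_nig_hyperparams",
    "nig_marginal_logpdf",
    "continuous_log_bf",
    "gene_bayes_factor",
    "bayes_factor_table",
]

LN10 = np.log(10.0)


@dataclass(frozen=True)
class BetaHyperparams:
    """Beta prior hyperparameters for one binary annotation under one model."""

    annotation: str
    model: int
    alpha: float
    beta: float
    n_fit: int = 0
    k_fit: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if not (0 <= self.k_fit <= self.n_fit):
            raise ValueError("need 0 <= k_fit <= n_fit")


@dataclass(frozen=True)
class NIGHyperparams:
    """Normal-Inverse-Gamma hyperparameters (mu0, kappa, nu, sigma2)."""

    annotation: str
    model: int
    mu0: float
    kappa: float
    nu: float
    sigma2: float

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.nu <= 0 or self.sigma2 <= 0:
            raise ValueError("kappa, nu and sigma2 must be positive")

    @property
    def marginal_scale2(self) -> float:
        """Squared scale of the implied non-standardized t marginal."""
        return self.sigma2 * (1.0 + self.kappa) / self.kappa


@dataclass(frozen=True)
class AnnotationSelection:
    annotation: str
    kind: Literal["binary", "continuous"]
    statistic: float
    p_value: float
    selected: bool
    flag: str | None = None


# ---------------------------------------------------------------------------
# annotation pre-selection


def _group_values(matrix, annotation: str, group: GeneSet) -> np.ndarray:
    col = matrix.column(annotation)
    members = [g for g in col.index if g in group.members]
    vals = col.loc[members].to_numpy(dtype=float)
    return vals[~np.isnan(vals)]


def select_binary_annotations(
    B: BinaryAnnotationMatrix,
    seeds: GeneSet,
    background: GeneSet,
    alpha_level: float = 0.05,
) -> list[AnnotationSelection]:
    """One-sided Fisher's exact test for seed enrichment, per annotation."""
    out = []
    for ann in B.annotations:
        s = _group_values(B, ann, seeds)
        b = _group_values(B, ann, background)
        if len(s) == 0 or len(b) == 0:
            out.append(
                AnnotationSelection(ann, "binary", float("nan"), float("nan"),
                                    False, flag="all_missing_in_group")
            )
            continue
        table = [
            [int(s.sum()), int(len(s) - s.sum())],
            [int(b.sum()), int(len(b) - b.sum())],
        ]
        res = stats.fisher_exact(table, alternative="greater")
        out.append(
            AnnotationSelection(
                ann, "binary", float(res.statistic), float(res.pvalue),
                bool(res.pvalue < alpha_level),
            )
        )
    return out


def select_continuous_annotations(
    C: ContinuousAnnotationMatrix,
    seeds: GeneSet,
    background: GeneSet,
    alpha_level: float = 0.05,
) -> list[AnnotationSelection]:
    """Two-sided Welch t-test between seed and background values."""
    out = []
    for ann in C.annotations:
        s = _group_values(C, ann, seeds)
        b = _group_values(C, ann, background)
        if len(s) < 2 or len(b) < 2:
            out.append(
                AnnotationSelection(ann, "continuous", float("nan"),
                                    float("nan"), False, flag="too_few_values")
            )
            continue
        if s.var(ddof=1) == 0 and b.var(ddof=1) == 0 and s.mean() == b.mean():
            out.append(
                AnnotationSelection(ann, "continuous", 0.0, 1.0, False,
                                    flag="degenerate")
            )
            continue
        res = stats.ttest_ind(s, b, equal_var=False)
        out.append(
            AnnotationSelection(
                ann, "continuous", float(res.statistic), float(res.pvalue),
                bool(res.pvalue < alpha_level),
            )
        )
    return out


def selection_frame(selections: Iterable[AnnotationSelection]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "annotation": s.annotation,
                "kind": s.kind,
                "statistic": s.statistic,
                "p_value": s.p_value,
                "selected": s.selected,
                "flag": s.flag or "",
            }
            for s in selections
        ]
    )


# ---------------------------------------------------------------------------
# binary annotations: Beta-Bernoulli


def fit_beta_hyperparams(
    B: BinaryAnnotationMatrix,
    annotation: str,
    group: GeneSet,
    model: int,
) -> BetaHyperparams:
    """Laplace-smoothed conjugate fit: alpha = k + 1, beta = n - k + 1.

    The implied prior mean (k+1)/(n+2) tracks the group frequency and is
    never exactly 0 or 1, so degenerate groups (k = 0 or k = n) stay usable.
    """
    vals = _group_values(B, annotation, group)
    n = len(vals)
    if n < 1:
        raise ValueError(
            f"no non-missing values for {annotation!r} in group {group.name!r}"
        )
    k = int(vals.sum())
    return BetaHyperparams(annotation, model, alpha=k + 1.0, beta=n - k + 1.0,
                           n_fit=n, k_fit=k)


def binary_log_marginal(k: int, n: int, hp: BetaHyperparams) -> float:
    """Log Beta-Bernoulli marginal likelihood of k successes in n draws."""
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    return float(betaln(hp.alpha + k, n - k + hp.beta) - betaln(hp.alpha, hp.beta))


def binary_marginal(k: int, n: int, hp: BetaHyperparams) -> float:
    return float(np.exp(binary_log_marginal(k, n, hp)))


def binary_log_bf(d: float, hp1: BetaHyperparams, hp0: BetaHyperparams) -> float:
    """Log Bayes factor of one binary observation; missing -> 0 (neutral)."""
    if d is None or (isinstance(d, float) and np.isnan(d)):
        return 0.0
    d = int(d)
    if d not in (0, 1):
        raise ValueError(f"binary observation must be 0 or 1, got {d}")
    return binary_log_marginal(d, 1, hp1) - binary_log_marginal(d, 1, hp0)


# ---------------------------------------------------------------------------
# continuous annotations: Normal-Inverse-Gamma


def fit_nig_hyperparams(
    C: ContinuousAnnotationMatrix,
    annotation: str,
    group: GeneSet,
    model: int,
) -> NIGHyperparams:
    """Moment-matching fit of the NIG hyperparameters from group values.

    mu0 = sample mean, kappa = n, nu = n - 1 and
    sigma2 = v * (nu - 2)/nu * kappa/(1 + kappa)
    so the implied t marginal reproduces the group mean and variance v
    exactly.  Requires n >= 4 (so nu > 2 and the marginal variance exists)
    and positive sample variance.
    """
    vals = _group_values(C, annotation, group)
    n = len(vals)
    if n < 4:
        raise ValueError(
            f"need >= 4 non-missing values to fit {annotation!r} "
            f"in group {group.name!r} (got {n})"
        )
    v = float(vals.var(ddof=1))
    if v <= 0:
        raise ValueError(
            f"zero sample variance for {annotation!r} in group {group.name!r}"
        )
    kappa = float(n)
    nu = float(n - 1)
    sigma2 = v * (nu - 2.0) / nu * kappa / (1.0 + kappa)
    return NIGHyperparams(annotation, model, mu0=float(vals.mean()),
                          kappa=kappa, nu=nu, sigma2=sigma2)


def nig_marginal_logpdf(d, hp: NIGHyperparams):
    """Log density of the NIG single-observation marginal (non-standardized t)."""
    scale = np.sqrt(hp.marginal_scale2)
    return stats.t.logpdf(d, df=hp.nu, loc=hp.mu0, scale=scale)


def continuous_log_bf(d: float, hp1: NIGHyperparams, hp0: NIGHyperparams) -> float:
    """Log Bayes factor of one continuous observation; missing -> 0."""
    if d is None or (isinstance(d, float) and np.isnan(d)):
        return 0.0
    return float(nig_marginal_logpdf(d, hp1) - nig_marginal_logpdf(d, hp0))


# ---------------------------------------------------------------------------
# gene-level combination


def gene_bayes_factor(
    gene: str,
    binary: BinaryAnnotationMatrix | None,
    continuous: ContinuousAnnotationMatrix | None,
    selections: Sequence[AnnotationSelection],
    hyperparams: dict[tuple[str, int], BetaHyperparams | NIGHyperparams],
) -> tuple[float, dict[str, float]]:
    """Total log BF for one gene: sum of selected per-annotation log BFs.

    ``hyperparams`` maps (annotation, model) to the fitted hyperparameters.
    Returns (total natural-log BF, per-annotation natural-log BFs).
    """
    per_ann: dict[str, float] = {}
    for sel in selections:
        if not sel.selected:
            continue
        hp1 = hyperparams[(sel.annotation, 1)]
        hp0 = hyperparams[(sel.annotation, 0)]
        if sel.kind == "binary":
            d = binary.column(sel.annotation).get(gene, np.nan)
            per_ann[sel.annotation] = binary_log_bf(d, hp1, hp0)
        else:
            d = continuous.column(sel.annotation).get(gene, np.nan)
            per_ann[sel.annotation] = continuous_log_bf(d, hp1, hp0)
    return sum(per_ann.values()), per_ann


def fit_hyperparams(
    binary: BinaryAnnotationMatrix | None,
    continuous: ContinuousAnnotationMatrix | None,
    selections: Sequence[AnnotationSelection],
    seeds: GeneSet,
    background: GeneSet,
) -> dict[tuple[str, int], BetaHyperparams | NIGHyperparams]:
    """Fit M1 (seed) and M0 (background) hyperparameters per selected annotation."""
    out: dict[tuple[str, int], BetaHyperparams | NIGHyperparams] = {}
    for sel in selections:
        if not sel.selected:
            continue
        for model, group in ((1, seeds), (0, background)):
            if sel.kind == "binary":
                out[(sel.annotation, model)] = fit_beta_hyperparams(
                    binary, sel.annotation, group, model
                )
            else:
                out[(sel.annotation, model)] = fit_nig_hyperparams(
                    continuous, sel.annotation, group, model
                )
    return out


def bayes_factor_table(
    binary: BinaryAnnotationMatrix | None,
    continuous: ContinuousAnnotationMatrix | None,
    selections: Sequence[AnnotationSelection],
    hyperparams: dict[tuple[str, int], BetaHyperparams | NIGHyperparams],
    genes: Sequence[str],
) -> pd.DataFrame:
    """Vectorized per-gene log10 Bayes factors for the selected annotations.

    Returns a DataFrame indexed by gene with one ``log10_bf:<annotation>``
    column per selected annotation and a ``log10_bf_total`` column.
    Missing values contribute 0.
    """
    genes = list(genes)
    cols: dict[str, np.ndarray] = {}
    for sel in selections:
        if not sel.selected:
            continue
        hp1 = hyperparams[(sel.annotation, 1)]
        hp0 = hyperparams[(sel.annotation, 0)]
        if sel.kind == "binary":
            d = binary.column(sel.annotation).reindex(genes).to_numpy(dtype=float)
            lbf1 = binary_log_bf(1.0, hp1, hp0)
            lbf0 = binary_log_bf(0.0, hp1, hp0)
            vals = np.where(np.isnan(d), 0.0, np.where(d == 1.0, lbf1, lbf0))
        else:
            d = continuous.column(sel.annotation).reindex(genes).to_numpy(dtype=float)
            safe = np.where(np.isnan(d), 0.0, d)
            vals = nig_marginal_logpdf(safe, hp1) - nig_marginal_logpdf(safe, hp0)
            vals = np.where(np.isnan(d), 0.0, vals)
        cols[f"log10_bf:{sel.annotation}"] = vals / LN10
    df = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    df["log10_bf_total"] = df.sum(axis=1) if cols else 0.0
    return df
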