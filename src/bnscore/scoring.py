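"""Posterior odds (BNScore) and ranked candidate tables.

posterior odds = prior odds x total Bayes factor, combined in log10 space;
the primary score column is log10 posterior odds, with raw odds alongside.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_io import GeneSet

__all__ = ["posterior_odds", "rank_genes"]


def _roles(genes, seeds: GeneSet | None, background: GeneSet | None) -> pd.Series:
    roles = pd.Series("candidate", index=genes, name="role")
    if seeds is not None:
        roles[[g in seeds.members for g in genes]] = "seed"
    if background is not None:
        roles[[g in background.members for g in genes]] = "background"
    return roles


def posterior_odds(
    prior_odds: pd.Series,
    log10_bf_total: pd.Series,
    seeds: GeneSet | None = None,
    background: GeneSet | None = None,
) -> pd.DataFrame:
    """Combine per-gene prior odds and total log10 Bayes factor.

    Both inputs must cover exactly the same genes.  Genes with zero prior
    odds keep posterior odds 0 (log10 = -inf).  Returns an unranked score
    table indexed by gene.
    """
    a, b = set(prior_odds.index), set(log10_bf_total.index)
    if a != b:
        asym = sorted((a - b) | (b - a))
        raise ValueError(
            f"prior odds and Bayes factors cover different genes; "
            f"{len(asym)} asymmetric, e.g. {asym[:5]}"
        )
    genes = prior_odds.index
    prior = prior_odds.to_numpy(dtype=float)
    lbf = log10_bf_total.reindex(genes).to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log10_prior = np.log10(prior)
    log10_post = log10_prior + lbf
    post = np.where(prior == 0.0, 0.0, np.power(10.0, log10_post))
    table = pd.DataFrame(
        {
            "role": _roles(genes, seeds, background),
            "prior_odds": prior,
            "log10_bf_total": lbf,
            "log10_posterior_odds": log10_post,
            "posterior_odds": post,
        },
        index=pd.Index(genes, name="gene"),
    )
    return table


def rank_genes(table: pd.DataFrame, include_training: bool = False) -> pd.DataFrame:
    """Sort by posterior odds (descending), ties broken by gene identifier.

    Seed and background genes are excluded unless ``include_training``;
    ranks are 1..N over the retained rows.
    """
    out = table.copy()
    if not include_training and "role" in out.columns:
        out = out[out["role"] == "candidate"]
    out = (
        out.assign(_gene=out.index)
        .sort_values(by=["posterior_odds", "_gene"], ascending=[False, True])
        .drop(columns="_gene")
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out
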