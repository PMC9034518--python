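"""Network prior: weighted functional network, random walk with restart,
and conversion of seed-reaching probabilities into prior odds.

The prior odds of a gene being a risk gene are

    P(M1)/P(M0) = n_risk/(n_total - n_risk) * P(N_s),

where the constant ratio reflects the assumed genome-wide fraction of risk
genes (defaults 1000 of 18000) and P(N_s) is the average stationary
probability that a random walk with restart (RWR) started at the gene sits
on a seed gene.  The walk follows a row-stochastic transition matrix W with
update p <- (1-r) W^T p + r e_source, restart probability r in (0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .data_io import GeneSet, GeneUniverse

__all__ = [
    "WeightedGeneNetwork",
    "TransitionMatrix",
    "RWRConfig",
    "ReachProfile",
    "build_go_network",
    "read_edge_list",
    "read_gene_terms",
    "to_transition_matrix",
    "rwr",
    "rwr_solve",
    "seed_reach_probabilities",
    "avg_reach_to_seeds",
    "prior_odds",
]


@dataclass
class WeightedGeneNetwork:
    """Undirected weighted gene-gene network.

    ``weights`` is a symmetric sparse matrix with zero diagonal; zero-weight
    edges are dropped on construction.
    """

    nodes: tuple[str, ...]
    weights: sp.csr_matrix

    def __post_init__(self) -> None:
        w = sp.csr_matrix(self.weights, dtype=float)
        if w.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("weight matrix shape does not match node list")
        if w.diagonal().any():
            raise ValueError("self-edges are not allowed in the input network")
        data = w.data
        if not np.isfinite(data).all() or (data < 0).any():
            raise ValueError("edge weights must be finite and nonnegative")
        w.eliminate_zeros()
        asym = abs(w - w.T)
        if asym.nnz and asym.max() > 1e-9 * max(1.0, abs(w).max()):
            raise ValueError("weight matrix must be symmetric")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return self.weights.nnz // 2

    @classmethod
    def from_edges(
        cls,
        edges: list[tuple[str, str, float]],
        nodes: tuple[str, ...] | None = None,
    ) -> "WeightedGeneNetwork":
        """Build from (gene1, gene2, weight) triples; duplicates are summed."""
        if nodes is None:
            seen: dict[str, None] = {}
            for a, b, _ in edges:
                seen.setdefault(a)
                seen.setdefault(b)
            nodes = tuple(seen)
        idx = {g: i for i, g in enumerate(nodes)}
        rows, cols, vals = [], [], []
        pairs: set[tuple[int, int]] = set()
        dup = 0
        for a, b, w in edges:
            if a == b:
                raise ValueError(f"self-edge on gene {a!r}")
            i, j = idx[a], idx[b]
            key = (min(i, j), max(i, j))
            if key in pairs:
                dup += 1
            pairs.add(key)
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
        if dup:
            warnings.warn(f"{dup} duplicate edge pair(s) summed", stacklevel=2)
        n = len(nodes)
        w = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        return cls(nodes, w)


@dataclass
class TransitionMatrix:
    """Row-stochastic transition matrix over an ordered node list.

    Nodes that were isolated in the network carry a unit self-loop.
    ``missing_genes`` lists universe genes that were absent from the network.
    """

    nodes: tuple[str, ...]
    matrix: sp.csr_matrix
    missing_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        m = sp.csr_matrix(self.matrix, dtype=float)
        row_sums = np.asarray(m.sum(axis=1)).ravel()
        if not np.allclose(row_sums, 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        if (m.data < 0).any():
            raise ValueError("transition probabilities must be nonnegative")
        self.matrix = m
        self._index = {g: i for i, g in enumerate(self.nodes)}

    def node_index(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} is not a node of the network") from None


@dataclass(frozen=True)
class RWRConfig:
    """Random-walk-with-restart parameters."""

    restart_prob: float = 0.5
    tol: float = 1e-10
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 < self.restart_prob <= 1.0):
            raise ValueError("restart probability must lie in (0, 1]")
        if self.tol <= 0 or self.max_iter <= 0:
            raise ValueError("tol and max_iter must be positive")


@dataclass
class ReachProfile:
    """Stationary RWR distribution for one source gene."""

    source: str
    probabilities: pd.Series
    p_ns: float | None = None


# ---------------------------------------------------------------------------
# network construction


def build_go_network(
    gene_terms: dict[str, set[str]],
    min_weight: float = 0.0,
) -> WeightedGeneNetwork:
    """Weight gene pairs by the information content of their shared GO terms.

    w(i, j) = sum over shared terms t of -log2(f_t), with f_t the fraction of
    input genes carrying t.  The weight grows with the number of shared terms
    and with term rarity; a term present in every gene contributes nothing.
    Pairs below ``min_weight`` are omitted.  Genes with an empty term set are
    retained as isolated nodes.
    """
    genes = tuple(gene_terms)
    if sum(1 for ts in gene_terms.values() if ts) < 2:
        raise ValueError("need at least 2 genes with at least one term each")
    terms = sorted({t for ts in gene_terms.values() for t in ts})
    t_idx = {t: j for j, t in enumerate(terms)}
    n, m = len(genes), len(terms)
    rows, cols = [], []
    for i, g in enumerate(genes):
        for t in gene_terms[g]:
            rows.append(i)
            cols.append(t_idx[t])
    member = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, m)
    ).tocsr()
    freq = np.asarray(member.sum(axis=0)).ravel() / n
    ic = -np.log2(freq)
    w = (member @ sp.diags(ic) @ member.T).tocsr()
    w.setdiag(0.0)
    w.eliminate_zeros()
    if min_weight > 0:
        w.data[w.data < min_weight] = 0.0
        w.eliminate_zeros()
    return WeightedGeneNetwork(genes, w)


def read_edge_list(path) -> WeightedGeneNetwork:
    """Read an undirected weighted edge list TSV (gene1, gene2, weight)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ValueError("edge list needs columns gene1, gene2, weight")
    edges = [
        (str(a), str(b), float(w))
        for a, b, w in df.iloc[:, :3].itertuples(index=False)
    ]
    return WeightedGeneNetwork.from_edges(edges)


def write_edge_list(net: WeightedGeneNetwork, path) -> None:
    coo = sp.triu(net.weights, k=1).tocoo()
    df = pd.DataFrame(
        {
            "gene1": [net.nodes[i] for i in coo.row],
            "gene2": [net.nodes[j] for j in coo.col],
            "weight": coo.data,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_gene_terms(path) -> dict[str, set[str]]:
    """Read a two-column gene -> GO term TSV into a mapping."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("gene-term file needs columns gene, term")
    out: dict[str, set[str]] = {}
    for g, t in df.iloc[:, :2].itertuples(index=False):
        out.setdefault(str(g), set()).add(str(t))
    return out


def to_transition_matrix(
    net: WeightedGeneNetwork, universe: GeneUniverse | None = None
) -> TransitionMatrix:
    """Row-normalize edge weights; isolated nodes get a unit self-loop."""
    w = net.weights.tolil().tocsr()
    degree = np.asarray(w.sum(axis=1)).ravel()
    isolated = degree == 0
    inv = np.zeros_like(degree)
    inv[~isolated] = 1.0 / degree[~isolated]
    m = sp.diags(inv) @ w
    if isolated.any():
        m = m + sp.diags(isolated.astype(float))
    missing: tuple[str, ...] = ()
    if universe is not None:
        node_set = set(net.nodes)
        missing = tuple(g for g in universe.genes if g not in node_set)
    return TransitionMatrix(net.nodes, m.tocsr(), missing_genes=missing)


# ---------------------------------------------------------------------------
# random walk with restart


def rwr(W: TransitionMatrix, source: str, cfg: RWRConfig = RWRConfig()) -> ReachProfile:
    """Fixed-point iteration of p <- (1-r) W^T p + r e_source."""
    i = W.node_index(source)
    n = len(W.nodes)
    r = cfg.restart_prob
    e = np.zeros(n)
    e[i] = 1.0
    p = e.copy()
    wt = W.matrix.T.tocsr()
    for _ in range(cfg.max_iter):
        p_new = (1.0 - r) * (wt @ p) + r * e
        delta = np.abs(p_new - p).sum()
        p = p_new
        if delta < cfg.tol:
            break
    else:
        raise RuntimeError(
            f"RWR did not converge in {cfg.max_iter} iterations "
            f"(final L1 residual {delta:.3e})"
        )
    return ReachProfile(source, pd.Series(p, index=list(W.nodes)))


def rwr_solve(
    W: TransitionMatrix, source: str, cfg: RWRConfig = RWRConfig()
) -> ReachProfile:
    """Direct linear solve p* = r (I - (1-r) W^T)^-1 e_source."""
    i = W.node_index(source)
    n = len(W.nodes)
    r = cfg.restart_prob
    a = sp.eye(n, format="csc") - (1.0 - r) * W.matrix.T.tocsc()
    e = np.zeros(n)
    e[i] = 1.0
    p = r * spla.spsolve(a, e)
    return ReachProfile(source, pd.Series(p, index=list(W.nodes)))


def seed_reach_probabilities(
    W: TransitionMatrix,
    seeds: GeneSet,
    cfg: RWRConfig = RWRConfig(),
) -> pd.Series:
    """P(N_s) for every network node via a single adjoint linear solve.

    P_Ns(g) = mean over seeds s of p*_g(s) with p*_g = r (I-(1-r)W^T)^-1 e_g,
    so the full vector equals (r/|S|) (I-(1-r)W)^-1 1_S.  Identical to running
    ``rwr`` per gene and averaging the seed entries, at the cost of one solve.
    """
    node_set = set(W.nodes)
    present = sorted(seeds.members & node_set)
    skipped = len(seeds.members) - len(present)
    if not present:
        raise ValueError("no seed gene is present in the network")
    if skipped:
        warnings.warn(
            f"{skipped} seed gene(s) absent from the network were skipped",
            stacklevel=2,
        )
    n = len(W.nodes)
    r = cfg.restart_prob
    ind = np.zeros(n)
    for s in present:
        ind[W.node_index(s)] = 1.0
    a = sp.eye(n, format="csc") - (1.0 - r) * W.matrix.tocsc()
    y = spla.spsolve(a, ind)
    p_ns = (r / len(present)) * y
    return pd.Series(p_ns, index=list(W.nodes), name="P_Ns")


def avg_reach_to_seeds(
    profiles: dict[str, ReachProfile] | list[ReachProfile],
    seeds: GeneSet,
) -> pd.Series:
    """Average reaching probability to the seed genes, per source gene."""
    if isinstance(profiles, dict):
        profiles = list(profiles.values())
    if not profiles:
        raise ValueError("no reach profiles given")
    nodes = profiles[0].probabilities.index
    present = sorted(seeds.members & set(nodes))
    skipped = len(seeds.members) - len(present)
    if not present:
        raise ValueError("no seed gene is present in the network")
    if skipped:
        warnings.warn(
            f"{skipped} seed gene(s) absent from the network were skipped",
            stacklevel=2,
        )
    out = {}
    for prof in profiles:
        p_ns = float(prof.probabilities.loc[present].mean())
        prof.p_ns = p_ns
        out[prof.source] = p_ns
    return pd.Series(out, name="P_Ns")


# ---------------------------------------------------------------------------
# prior odds


def prior_odds(
    p_ns: pd.Series,
    n_risk: int = 1000,
    n_total: int = 18000,
    mode: str = "literal",
    universe: GeneUniverse | None = None,
    floor_percentile: float | None = None,
) -> pd.Series:
    """Convert seed-reaching probabilities into per-gene prior odds.

    ``literal``: odds(g) = n_risk/(n_total - n_risk) * P_Ns(g).
    ``mean_normalized``: P_Ns is first divided by its mean over scored genes,
    so the average prior odds equals the constant ratio.

    Universe genes lacking a P_Ns value default to odds 0; if
    ``floor_percentile`` is given they instead receive the odds implied by
    that percentile of the computed P_Ns values.
    """
    if not (0 < n_risk < n_total):
        raise ValueError("need 0 < n_risk < n_total")
    if mode not in ("literal", "mean_normalized"):
        raise ValueError(f"unknown prior mode {mode!r}")
    ratio = n_risk / (n_total - n_risk)
    vals = p_ns.astype(float)
    if mode == "mean_normalized":
        mean = vals.mean()
        if mean == 0:
            raise ValueError("all P_Ns are zero; cannot mean-normalize")
        vals = vals / mean
    odds = ratio * vals
    odds.name = "prior_odds"
    if universe is not None:
        fill = 0.0
        if floor_percentile is not None:
            fill = float(np.percentile(odds.to_numpy(), floor_percentile))
        odds = odds.reindex(list(universe.genes), fill_value=fill)
    return odds
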