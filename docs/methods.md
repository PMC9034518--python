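# Methods

This note documents the models implemented in `bnscore`, the defaults and
why they were chosen, what the synthetic data does and does not emulate,
and the numerical conventions a user needs to reproduce or audit a run.

## Posterior odds

Each gene is scored by posterior odds of being a risk gene,
`prior odds × Bayes factor`, with annotations assumed mutually independent
under both the risk model M1 and the non-risk model M0. The independence
assumption is a modeling convenience: correlated annotations double-count
evidence, and users should prune redundant columns (the selection step
removes uninformative ones but not correlated informative ones). Scores are
combined and reported in log10 space; raw odds are reported alongside.
Genes whose prior is exactly zero (unreachable from every seed in the
network) keep posterior 0 and a `-inf` log score rather than being dropped.

## Network prior

- Ingested networks are undirected weighted edge lists; alternatively a
  network can be built from gene→GO-term assignments with edge weight
  `w(i,j) = Σ_t −log2(f_t)` over shared terms `t`, `f_t` the term's
  frequency among input genes. This shared-term information-content sum is
  one standard instantiation of "number and strength of shared terms"; any
  precomputed weighted network can be supplied instead and is the primary
  ingestion path.
- The transition matrix is row-stochastic; isolated nodes get a unit
  self-loop. The walk updates `p ← (1−r)·Wᵀp + r·e_source`. The restart
  probability `r` defaults to 0.5 (midpoint of common practice, exposed in
  `RWRConfig`); results should be reported together with `r`.
- `P(N_s)` is the mean stationary probability mass the gene's walk places
  on the seed genes. It is computed for all genes at once by the adjoint
  identity `P_Ns = (r/|S|)·(I − (1−r)W)⁻¹ 1_S` (one sparse solve); tests
  pin this to the per-gene fixed-point iteration, so batching never changes
  results. `P(N_s)` is invariant to global rescaling of edge weights.
- Prior odds modes: `literal` multiplies the constant ratio
  `n_risk/(n_total−n_risk)` (defaults 1000/17000, configurable for other
  traits) by the raw `P(N_s)` — faithful to the stated formula but very
  small in absolute terms because `P(N_s)` is a probability mass spread
  over the network; `mean_normalized` first divides `P(N_s)` by its mean
  so the average prior odds equals the constant ratio. The two modes give
  identical rankings (they differ by a constant factor); only absolute
  odds change. Genes absent from the network default to prior 0; an
  optional percentile floor avoids annihilating annotation evidence for
  such genes.

## Annotation Bayes factors

- Selection: binary annotations are kept when a one-sided (enrichment)
  Fisher's exact test between seed and background genes gives p < 0.05;
  continuous annotations when a two-sided Welch t-test does. The threshold
  is configurable; no multiplicity correction is applied at this step
  (correction is reserved for downstream enrichment analyses).
- Binary fit: `α = k+1`, `β = n−k+1` from the group's `k` carriers among
  `n` non-missing values — the conjugate update of a uniform prior. The
  implied carrier probability `(k+1)/(n+2)` tracks the group frequency and
  never reaches 0 or 1, so degenerate groups stay usable. The estimator is
  deliberately simple and is isolated behind `fit_beta_hyperparams` so an
  alternative moment scheme can be swapped in.
- Continuous fit: `μ₀ = x̄`, `κ = n`, `ν = n−1`,
  `σ² = v·(ν−2)/ν·κ/(1+κ)` with `v` the sample variance. These choices
  make the implied single-observation marginal — the non-standardized t
  `t_ν(μ₀, σ²(1+κ)/κ)` — reproduce the group mean and variance exactly
  (moment matching). Requires `n ≥ 4` (so `ν > 2` and the marginal
  variance exists) and `v > 0`.
- Candidate-gene Bayes factors are single-observation marginal ratios
  (`n = 1`), i.e. each candidate is scored individually, not blockwise.
- Missing values contribute log BF = 0 ("no evidence") instead of dropping
  the gene, keeping the score defined genome-wide. Marginals are computed
  via log-gamma / t log-densities; no raw Beta functions are evaluated.

## Evaluation

- ROC-AUC is the Mann–Whitney probability with ties counted 1/2
  (scikit-learn). PR-AUC uses step interpolation (average precision);
  linear interpolation between recall points is deliberately avoided.
- DeLong's paired test is implemented from structural components
  (midrank formulation); the reported p is one-sided for
  `AUC_a > AUC_b`. Identical AUCs with zero variance give p = 0.5;
  unequal AUCs with degenerate variance give the sign-based limit
  (0 or 1) with a warning.
- Top-K enrichment: training (seed/background) genes are removed from both
  margins first; the 2×2 table is (top-K vs rest) × (benchmark vs not)
  over the remaining evaluated genes. Fisher's exact test is two-sided by
  default; the odds ratio gets a Haldane–Anscombe 0.5 correction only when
  a zero cell occurs, and the result is flagged.
- Benjamini–Hochberg adjustment preserves input order (statsmodels).

## Specificity index

For a target condition, each gene's fold change (with pseudocount 1e-8
against division by zero) versus every other condition is ranked across
genes, rank 1 = largest; SI is the mean rank over the `m−1` comparisons,
so `SI ∈ [1, G]` and lower is more specific. pSI is the permutation
p-value `P(SI_null ≤ SI_obs)` with the +1 correction
`(1 + hits)/(n_perm + 1)`, whose floor is `1/(n_perm+1)`.

The default null shuffles expression values **across genes within each
condition**. The alternative null — shuffling each gene's values across
conditions — preserves per-gene magnitudes and is available as an option,
but it cannot support the conventional 0.05 cutoff when conditions are
few: a gene whose specificity rests on one extreme value reproduces its
observed SI whenever the shuffle returns that value to the target column
(~1/m of rounds), flooring its pSI at ~1/m (0.17 at m = 6). The
across-gene null reaches the true floor regardless of m, which is why it
is the default. Replicate columns should be averaged into one column per
condition before computing SI (`average_replicates`).

## Synthetic data

`simulate_universe` plants `n_risk` risk genes in a universe of `n_genes`
and generates: binary annotations with distinct Bernoulli rates by class,
continuous annotations as class-shifted normals, a two-block network
(within-risk edge probability vs background probability, Exponential edge
weights), and an expression matrix of Gamma(2, 1) noise with a chosen set
of genes boosted `fold`-fold in the first condition. A random subset of
risk genes is "observed" as seeds; the rest serve as held-out positives,
emulating the train-on-early / test-on-late design used with real gene
discoveries.

Defaults: 2,000 genes, 100 risk, 50 observed seeds, 500 sampled background
genes; five binary annotations at rates 0.6 (risk) vs 0.1, five continuous
annotations shifted by 1 SD, block network 0.3 vs 0.02, six expression
conditions with 50 specific genes boosted 10-fold. This scale runs the
whole pipeline in about a second per replicate while keeping enrichment
tables non-degenerate; replicated experiments (20 seeds) finish in well
under a minute.

What the generator does **not** emulate: real GO term topology and its
annotation-depth biases, heavy-tailed degree distributions of curated
functional networks, realistic pLI-like bimodality, expression
correlation across conditions, or dependence between annotations and the
network. Passing recovery tests therefore demonstrate correctness of the
machinery and qualitative behavior (integration helps, null is
calibrated), not expected performance on real genomes.

One behavior of the defaults is worth knowing: the planted two-block
network is a much cleaner signal than real functional networks, so the
network-only ranking alone nearly saturates held-out AUC (~0.997); the
integrated score is statistically indistinguishable from it at that
ceiling (while clearly beating the annotation-only ablations). On real
data the ordering typically reverses — network evidence weakest,
integration clearly best — because curated functional networks are far
noisier than this generator's planted blocks.

## Determinism and numerics

- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical seeds give bit-identical
  simulations, background samples and pSI values, and byte-identical CLI
  output tables (`%.10g` float formatting).
- RWR iteration stops when the L1 change falls below `tol` (default
  1e-10, max 1000 iterations; non-convergence is an error, not a warning).
- Ranking ties are broken lexicographically by gene identifier, so ranked
  tables are stable across runs and platforms.
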