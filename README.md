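# bnscore

Bayesian model-selection prioritization of disease risk genes.

`bnscore` ranks every gene in a genome by its posterior odds of being a risk
gene for a complex trait (the motivating application is autism spectrum
disorder), integrating three kinds of evidence that are individually weak
but complementary:

1. **seed genes** — a small set of established risk genes (e.g. 65 genes
   from a large exome sequencing study);
2. **functional annotations** — binary memberships in biological processes
   and continuous gene-level metrics (e.g. pLI);
3. **network proximity** — closeness to the seed genes in a weighted
   gene–gene functional network.

## The model

For each gene, two models are compared: `M1` (risk gene) and `M0` (non-risk
gene). With annotation data `D = (D_1, …, D_p)` assumed independent across
annotations under both models, the score is the posterior odds

```
P(M1 | D)     P(M1)     p   P(D_l | M1)
---------  =  -----  ·  ∏   -----------
P(M0 | D)     P(M0)    l=1  P(D_l | M0)
```

**Prior odds.** `P(M1)/P(M0) = n_risk/(n_total − n_risk) · P(N_s)`, where
the constant ratio (defaults 1000 / 17000) reflects the assumed genome-wide
fraction of risk genes and `P(N_s)` is the gene's average reaching
probability to the seed genes under a random walk with restart (restart
probability `r`, default 0.5) on the row-normalized network.

**Bayes factors.** Each annotation contributes a ratio of marginal
likelihoods with hyperparameters fitted by empirical Bayes — `M1` from the
seed genes, `M0` from a random background gene set (default 500 genes):

- *binary*: Beta–Bernoulli, `p(D_l | α, β) = B(α+k, n−k+β) / B(α, β)`;
- *continuous*: Normal-Inverse-Gamma, whose single-observation marginal is
  the non-standardized Student t `t_ν(μ₀, σ²(1+κ)/κ)`.

Annotations are pre-selected with a one-sided Fisher's exact test (binary)
or a two-sided Welch t-test (continuous) between seeds and background.
All products are accumulated in log10 space; a missing annotation value is
evidence-neutral (log BF = 0).

The package also ships the benchmarking suite used to evaluate such rankings
(ROC/PR AUC, one-sided DeLong test, sliding top-K Fisher enrichment with
Benjamini–Hochberg correction) and the expression specificity index SI with
its permutation p-value pSI (genes with pSI < 0.05 form a condition-specific
gene list).

No external datasets are bundled or downloaded: the `synthetic_data` module
generates gene universes with planted risk genes, class-shifted annotations,
a two-block functional network and condition-specific expression, so the
whole pipeline is testable end to end.

## Worked example

```python
from bnscore.synthetic_data import SimulationConfig, recovery_experiment

cfg = SimulationConfig(rng_seed=7)          # 2000 genes, 100 planted risk,
report = recovery_experiment(cfg, keep_table=True)  # 50 observed as seeds
print(f"held-out ROC-AUC : {report.roc_auc:.3f}")
print(f"held-out PR-AUC  : {report.pr_auc:.3f}")
print(f"top-{report.k} enrichment OR: {report.topk_or:.1f} (p = {report.topk_p:.2e})")
for name, auc in report.ablation_auc.items():
    print(f"ablation {name:16s}: AUC {auc:.3f}")
```

prints

```
held-out ROC-AUC : 0.999
held-out PR-AUC  : 0.963
top-100 enrichment OR: 1595.1 (p = 8.00e-47)
ablation network_only    : AUC 0.997
ablation binary_only     : AUC 0.984
ablation continuous_only : AUC 0.944
```

The experiment trains on the 50 observed seed genes plus a sampled
background, scores all remaining genes, and evaluates against the 50
held-out planted risk genes: the integrated score recovers them nearly
perfectly, and each single-evidence ablation (network proximity alone,
binary annotations alone, continuous annotations alone) is weaker than or
comparable to the combination. The head of the ranked table:

```
             role  prior_odds  log10_bf_total  log10_posterior_odds  posterior_odds  rank
gene
G00369  candidate      0.2208           4.862                 4.206       1.605e+04     1
G01528  candidate      0.1196           4.945                 4.023       1.054e+04     2
G01451  candidate        0.16           4.288                 3.492            3103     3
```

The same pipeline is available from the shell on TSV/plain-text inputs:

```sh
bnscore simulate --seed 7 --out data/
bnscore ingest   --genes data/genes.txt --seeds data/seeds.txt \
                 --sample-background 500 --seed 7 --out data/background.txt
bnscore prior    --network data/network.tsv --seeds data/seeds.txt \
                 --genes data/genes.txt --out prior.tsv
bnscore select   --binary data/binary.tsv --continuous data/continuous.tsv \
                 --seeds data/seeds.txt --background data/background.txt \
                 --out selection.tsv
bnscore bf       --binary data/binary.tsv --continuous data/continuous.tsv \
                 --seeds data/seeds.txt --background data/background.txt \
                 --selection selection.tsv --out bf.tsv
bnscore score    --prior prior.tsv --bf bf.tsv --seeds data/seeds.txt \
                 --background data/background.txt --out bnscore.tsv
bnscore evaluate --scores bnscore.tsv --benchmark data/risk_truth.txt \
                 --universe data/genes.txt --topk 100,1000 --out eval.tsv
bnscore psi      --expr data/expression.tsv --condition cond0 \
                 --nperm 1000 --seed 7 --out psi.tsv
```

Runs with identical seeds produce byte-identical output tables.

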