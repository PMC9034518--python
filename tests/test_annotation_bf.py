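import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import comb

from bnscore.annotation_bf import (
    AnnotationSelection,
    BetaHyperparams,
    NIGHyperparams,
    bayes_factor_table,
    binary_log_bf,
    binary_log_marginal,
    binary_marginal,
    continuous_log_bf,
    fit_beta_hyperparams,
    fit_hyperparams,
    fit_nig_hyperparams,
    gene_bayes_factor,
    nig_marginal_logpdf,
    select_binary_annotations,
    select_continuous_annotations,
)
from bnscore.data_io import GeneSet


def _hp_beta(alpha, beta):
    return BetaHyperparams("a", 1, alpha, beta)


def _hp_nig(mu0, kappa, nu, sigma2):
    return NIGHyperparams("a", 1, mu0, kappa, nu, sigma2)


class TestSelection:
    def test_fully_enriched_annotation_selected(self, binary_matrix, seeds,
                                                background, small_universe):
        sels = select_binary_annotations(binary_matrix, seeds, background)
        by_name = {s.annotation: s for s in sels}
        assert by_name["enriched"].selected

    def test_identical_prevalence_not_selected(self, small_universe):
        import pandas as pd
        genes = list(small_universe.genes)
        col = [1.0 if i % 2 == 0 else 0.0 for i in range(len(genes))]
        from bnscore.data_io import BinaryAnnotationMatrix
        B = BinaryAnnotationMatrix(
            pd.DataFrame({"even": col}, index=pd.Index(genes, name="gene")))
        seeds = GeneSet("s", frozenset(genes[:10]), role="seed")
        bg = GeneSet("b", frozenset(genes[10:]), role="background")
        sel = select_binary_annotations(B, seeds, bg)[0]
        assert sel.p_value >= 0.5
        assert not sel.selected

    def test_fisher_p_matches_hypergeometric_tail(self):
        """One-sided enrichment p equals the hypergeometric upper tail."""
        import pandas as pd
        from bnscore.data_io import BinaryAnnotationMatrix
        # 8/10 seeds and 5/50 background genes carry the annotation
        genes = [f"s{i}" for i in range(10)] + [f"b{i}" for i in range(50)]
        vals = [1.0] * 8 + [0.0] * 2 + [1.0] * 5 + [0.0] * 45
        B = BinaryAnnotationMatrix(
            pd.DataFrame({"ann": vals}, index=pd.Index(genes, name="gene")))
        seeds = GeneSet("s", frozenset(genes[:10]), role="seed")
        bg = GeneSet("b", frozenset(genes[10:]), role="background")
        sel = select_binary_annotations(B, seeds, bg)[0]
        # P(X >= 8) with X ~ Hypergeom(N=60, K=13 carriers, n=10 seeds)
        expect = sum(
            comb(13, x) * comb(47, 10 - x) / comb(60, 10) for x in range(8, 11)
        )
        assert sel.p_value == pytest.approx(expect, rel=1e-10)

    def test_welch_t_matches_hand_formula(self):
        import pandas as pd
        from bnscore.data_io import ContinuousAnnotationMatrix
        rng = np.random.default_rng(2)
        s_vals, b_vals = rng.normal(1.0, 1.0, 8), rng.normal(0.0, 2.0, 12)
        genes = [f"s{i}" for i in range(8)] + [f"b{i}" for i in range(12)]
        C = ContinuousAnnotationMatrix(pd.DataFrame(
            {"ann": np.concatenate([s_vals, b_vals])},
            index=pd.Index(genes, name="gene")))
        seeds = GeneSet("s", frozenset(genes[:8]), role="seed")
        bg = GeneSet("b", frozenset(genes[8:]), role="background")
        sel = select_continuous_annotations(C, seeds, bg)[0]
        v1, v2 = s_vals.var(ddof=1) / 8, b_vals.var(ddof=1) / 12
        t_stat = (s_vals.mean() - b_vals.mean()) / np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / 7 + v2**2 / 11)
        p = 2 * stats.t.sf(abs(t_stat), df)
        assert sel.statistic == pytest.approx(t_stat, rel=1e-12)
        assert sel.p_value == pytest.approx(p, rel=1e-10)

    def test_identical_groups_give_p_one(self):
        import pandas as pd
        from bnscore.data_io import ContinuousAnnotationMatrix
        genes = [f"g{i}" for i in range(10)]
        C = ContinuousAnnotationMatrix(pd.DataFrame(
            {"ann": [1.0] * 10}, index=pd.Index(genes, name="gene")))
        seeds = GeneSet("s", frozenset(genes[:5]), role="seed")
        bg = GeneSet("b", frozenset(genes[5:]), role="background")
        sel = select_continuous_annotations(C, seeds, bg)[0]
        assert sel.p_value == 1.0
        assert not sel.selected


class TestBetaBernoulli:
    @pytest.mark.parametrize("n,k,expect", [(65, 65, (66.0, 1.0)),
                                            (500, 0, (1.0, 501.0))])
    def test_laplace_smoothed_fit(self, n, k, expect):
        import pandas as pd
        from bnscore.data_io import BinaryAnnotationMatrix
        genes = [f"g{i}" for i in range(n)]
        B = BinaryAnnotationMatrix(pd.DataFrame(
            {"ann": [1.0] * k + [0.0] * (n - k)},
            index=pd.Index(genes, name="gene")))
        hp = fit_beta_hyperparams(B, "ann", GeneSet("g", frozenset(genes)), 1)
        assert (hp.alpha, hp.beta) == expect

    def test_single_draw_marginal_is_prior_mean(self):
        # B(a+1, b)/B(a, b) = a/(a+b)
        for a, b in [(1.0, 1.0), (2.0, 3.0), (7.3, 0.4)]:
            hp = _hp_beta(a, b)
            assert binary_marginal(1, 1, hp) == pytest.approx(a / (a + b))
            assert binary_marginal(0, 1, hp) == pytest.approx(b / (a + b))

    def test_marginal_matches_quadrature(self):
        hp = _hp_beta(2.5, 7.1)
        n, k = 6, 2
        val, _ = integrate.quad(
            lambda t: t**k * (1 - t) ** (n - k) * stats.beta.pdf(t, 2.5, 7.1),
            0, 1,
        )
        assert binary_marginal(k, n, hp) == pytest.approx(val, rel=1e-8)

    def test_beta_binomial_normalization(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a, b = rng.uniform(0.2, 10.0, 2)
            n = int(rng.integers(1, 12))
            hp = _hp_beta(a, b)
            total = sum(comb(n, k) * binary_marginal(k, n, hp)
                        for k in range(n + 1))
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_bf_values_from_fit_extremes(self):
        hp1 = _hp_beta(66.0, 1.0)
        hp0 = _hp_beta(1.0, 501.0)
        bf1 = np.exp(binary_log_bf(1.0, hp1, hp0))
        bf0 = np.exp(binary_log_bf(0.0, hp1, hp0))
        assert bf1 == pytest.approx((66 / 67) / (1 / 502), rel=1e-12)
        assert bf0 == pytest.approx((1 / 67) / (501 / 502), rel=1e-12)

    def test_missing_observation_is_neutral(self):
        assert binary_log_bf(float("nan"), _hp_beta(2, 1), _hp_beta(1, 2)) == 0.0

    def test_invalid_hyperparams_rejected(self):
        with pytest.raises(ValueError):
            BetaHyperparams("a", 1, 0.0, 1.0)


class TestNIG:
    def test_moment_matching_fit_arithmetic(self):
        import pandas as pd
        from bnscore.data_io import ContinuousAnnotationMatrix
        genes = ["a", "b", "c", "d"]
        C = ContinuousAnnotationMatrix(pd.DataFrame(
            {"ann": [0.0, 0.0, 2.0, 2.0]}, index=pd.Index(genes, name="gene")))
        hp = fit_nig_hyperparams(C, "ann", GeneSet("g", frozenset(genes)), 1)
        assert hp.mu0 == pytest.approx(1.0)
        assert hp.kappa == 4.0
        assert hp.nu == 3.0
        assert hp.sigma2 == pytest.approx(16.0 / 45.0)

    def test_implied_marginal_moments_match_sample(self):
        """The fitted t marginal reproduces group mean and variance exactly."""
        import pandas as pd
        from bnscore.data_io import ContinuousAnnotationMatrix
        rng = np.random.default_rng(4)
        vals = rng.normal(3.0, 2.0, 30)
        genes = [f"g{i}" for i in range(30)]
        C = ContinuousAnnotationMatrix(pd.DataFrame(
            {"ann": vals}, index=pd.Index(genes, name="gene")))
        hp = fit_nig_hyperparams(C, "ann", GeneSet("g", frozenset(genes)), 0)
        marg_var = hp.marginal_scale2 * hp.nu / (hp.nu - 2.0)
        assert hp.mu0 == pytest.approx(vals.mean())
        assert marg_var == pytest.approx(vals.var(ddof=1))

    def test_fit_requires_enough_values_and_variance(self):
        import pandas as pd
        from bnscore.data_io import ContinuousAnnotationMatrix
        genes = ["a", "b", "c", "d"]
        C = ContinuousAnnotationMatrix(pd.DataFrame(
            {"flat": [1.0] * 4, "short": [1.0, 2.0, np.nan, np.nan]},
            index=pd.Index(genes, name="gene")))
        grp = GeneSet("g", frozenset(genes))
        with pytest.raises(ValueError, match="variance"):
            fit_nig_hyperparams(C, "flat", grp, 1)
        with pytest.raises(ValueError, match=">= 4"):
            fit_nig_hyperparams(C, "short", grp, 1)

    def test_marginal_density_matches_double_integration(self):
        """Closed-form t marginal vs numerical NIG mixture integration."""
        hp = _hp_nig(mu0=0.7, kappa=3.0, nu=5.0, sigma2=1.3)
        a_ig, b_ig = hp.nu / 2.0, hp.nu * hp.sigma2 / 2.0
        for d in (-1.0, 0.7, 2.5):
            def outer(theta):
                inner, _ = integrate.quad(
                    lambda mu: stats.norm.pdf(d, mu, np.sqrt(theta))
                    * stats.norm.pdf(mu, hp.mu0, np.sqrt(theta / hp.kappa)),
                    hp.mu0 - 40, hp.mu0 + 40,
                )
                return inner * stats.invgamma.pdf(theta, a_ig, scale=b_ig)
            lo = stats.invgamma.ppf(1e-12, a_ig, scale=b_ig)
            hi = stats.invgamma.ppf(1 - 1e-10, a_ig, scale=b_ig)
            val, _ = integrate.quad(outer, lo, hi, limit=200)
            assert np.exp(nig_marginal_logpdf(d, hp)) == pytest.approx(
                val, rel=1e-6
            )

    def test_missing_observation_is_neutral(self):
        hp1, hp0 = _hp_nig(1, 2, 3, 1), _hp_nig(0, 2, 3, 1)
        assert continuous_log_bf(float("nan"), hp1, hp0) == 0.0

    def test_location_pull_raises_bf(self):
        hp1, hp0 = _hp_nig(2.0, 3.0, 5.0, 1.0), _hp_nig(-2.0, 3.0, 5.0, 1.0)
        assert continuous_log_bf(2.0, hp1, hp0) > 0
        assert continuous_log_bf(0.0, hp1, hp0) == pytest.approx(0.0, abs=1e-12)


class TestBFProperties:
    def test_swap_inverts_bf(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            hpb1 = _hp_beta(*rng.uniform(0.3, 9.0, 2))
            hpb0 = _hp_beta(*rng.uniform(0.3, 9.0, 2))
            d = float(rng.integers(0, 2))
            assert binary_log_bf(d, hpb1, hpb0) == pytest.approx(
                -binary_log_bf(d, hpb0, hpb1), rel=1e-12, abs=1e-12
            )
            hpn1 = _hp_nig(rng.normal(), *rng.uniform(0.5, 8.0, 3))
            hpn0 = _hp_nig(rng.normal(), *rng.uniform(0.5, 8.0, 3))
            x = float(rng.normal())
            assert continuous_log_bf(x, hpn1, hpn0) == pytest.approx(
                -continuous_log_bf(x, hpn0, hpn1), rel=1e-12, abs=1e-12
            )

    def test_identical_hyperparams_give_unit_bf(self):
        hp = _hp_beta(3.0, 4.0)
        assert binary_log_bf(1.0, hp, hp) == 0.0
        hpn = _hp_nig(0.5, 2.0, 6.0, 1.5)
        assert continuous_log_bf(1.7, hpn, hpn) == 0.0

    def test_identical_fit_groups_give_bf_one_for_all_genes(
        self, binary_matrix, continuous_matrix, seeds, small_universe
    ):
        sels = [
            AnnotationSelection("enriched", "binary", 0.0, 0.0, True),
            AnnotationSelection("shifted", "continuous", 0.0, 0.0, True),
        ]
        hps = fit_hyperparams(binary_matrix, continuous_matrix, sels,
                              seeds, seeds)
        table = bayes_factor_table(binary_matrix, continuous_matrix, sels,
                                   hps, small_universe.genes)
        assert np.allclose(table["log10_bf_total"].to_numpy(), 0.0, atol=1e-14)


class TestGeneCombination:
    def test_total_is_sum_of_selected_logs(self, binary_matrix,
                                           continuous_matrix, seeds,
                                           background, small_universe):
        sels = select_binary_annotations(binary_matrix, seeds, background) + \
            select_continuous_annotations(continuous_matrix, seeds, background)
        hps = fit_hyperparams(binary_matrix, continuous_matrix, sels,
                              seeds, background)
        table = bayes_factor_table(binary_matrix, continuous_matrix, sels,
                                   hps, small_universe.genes)
        gene = small_universe.genes[17]
        total_ln, per_ann = gene_bayes_factor(gene, binary_matrix,
                                              continuous_matrix, sels, hps)
        assert table.loc[gene, "log10_bf_total"] == pytest.approx(
            total_ln / np.log(10), rel=1e-12
        )
        # exp(sum of logs) equals the direct product of per-annotation BFs
        assert np.exp(total_ln) == pytest.approx(
            np.prod([np.exp(v) for v in per_ann.values()]), rel=1e-12
        )

    def test_planted_rate_difference_separates_classes(self):
        """Mean log-BF positive for planted carriers at 0.6 vs 0.1 rates."""
        import pandas as pd
        from bnscore.data_io import BinaryAnnotationMatrix
        rng = np.random.default_rng(21)
        n_r, n_b = 60, 500
        genes = [f"r{i}" for i in range(n_r)] + [f"b{i}" for i in range(n_b)]
        vals = np.concatenate([
            (rng.random(n_r) < 0.6), (rng.random(n_b) < 0.1)
        ]).astype(float)
        B = BinaryAnnotationMatrix(pd.DataFrame(
            {"ann": vals}, index=pd.Index(genes, name="gene")))
        risk = GeneSet("r", frozenset(genes[:n_r]), role="seed")
        bg = GeneSet("b", frozenset(genes[n_r:]), role="background")
        sels = select_binary_annotations(B, risk, bg)
        hps = fit_hyperparams(B, None, sels, risk, bg)
        table = bayes_factor_table(B, None, sels, hps, genes)
        lbf = table["log10_bf_total"]
        assert lbf.iloc[:n_r].mean() > 0
        assert lbf.iloc[n_r:].mean() < 0
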