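"""Comparative scores, covariance, PGLS and exact tests."""

import math

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from readthru import comparative as cp
from readthru import synthetic_data as sd
from readthru.comparative import (
    brownian_cov,
    estimate_ne,
    fisher_exact_2x2,
    parse_formula,
    pgls_fit,
    rank_tests,
    taa_disparity,
    taa_enrichment_score,
)

from conftest import make_context


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


class TestTaaEnrichmentScore:
    def _contexts(self, primary_taa, downstream_taa, n=10):
        """n contexts; primary TAA fraction and per-position downstream TAA
        usage set exactly (every context has a stop triplet at all six
        positions)."""
        ctx = []
        for i in range(n):
            stop = "TAA" if i < primary_taa * n else "TGA"
            down = "TAA" if i < downstream_taa * n else "TGA"
            ctx.append(make_context(downstream=down * 6, stop=stop, gene_id=f"g{i}"))
        return ctx

    def test_equal_usage_scores_zero(self):
        ctx = self._contexts(0.4, 0.4)
        assert taa_enrichment_score(ctx) == pytest.approx(0.0)

    def test_arithmetic(self):
        ctx = self._contexts(0.6, 0.4)
        assert taa_enrichment_score(ctx) == pytest.approx(0.5)

    def test_invariant_to_order_and_duplication(self):
        ctx = self._contexts(0.6, 0.4)
        shuffled = list(reversed(ctx))
        assert taa_enrichment_score(shuffled) == pytest.approx(taa_enrichment_score(ctx))
        assert taa_enrichment_score(ctx + ctx) == pytest.approx(taa_enrichment_score(ctx))

    def test_sign_tracks_primary_taa_excess(self):
        assert taa_enrichment_score(self._contexts(0.8, 0.4)) > 0
        assert taa_enrichment_score(self._contexts(0.2, 0.4)) < 0


class TestNe:
    def test_arithmetic(self):
        assert estimate_ne(0.01, 2.5e-9) == pytest.approx(1.0e6)
        assert estimate_ne(4e-9, 1e-9) == pytest.approx(1.0)

    def test_linearity(self):
        assert estimate_ne(0.02, 1e-8) == pytest.approx(2 * estimate_ne(0.01, 1e-8))

    def test_domain(self):
        with pytest.raises(ValueError):
            estimate_ne(0.0, 1e-8)


class TestBrownianCov:
    def test_three_tip_example(self):
        V = brownian_cov(_tree("((A:1,B:1):1,C:2);"), ["A", "B", "C"])
        assert V[0, 1] == pytest.approx(1.0)
        assert V[0, 0] == pytest.approx(2.0)
        assert V[0, 2] == pytest.approx(0.0)

    def test_star_tree_is_diagonal(self):
        V = brownian_cov(_tree("(A:1,B:1,C:1,D:1);"), list("ABCD"))
        assert np.allclose(V, np.eye(4))

    def test_ultrametric_constant_diagonal(self):
        V = brownian_cov(_tree("((A:1,B:1):1,(C:1.5,D:1.5):0.5);"), list("ABCD"))
        assert np.allclose(np.diag(V), 2.0)

    def test_missing_tip_errors(self):
        with pytest.raises(ValueError, match="Z"):
            brownian_cov(_tree("((A:1,B:1):1,C:2);"), ["A", "Z"])


class TestPgls:
    def test_lambda_zero_equals_ols(self):
        import statsmodels.api as sm

        tree, traits, _ = sd.build_comparative(sd.ComparativeSimConfig(n_species=30, seed=4))
        fit = pgls_fit(traits["taa_enrichment"], traits[["log_ne"]], tree, lam=0.0)
        ols = sm.OLS(
            traits["taa_enrichment"].values, sm.add_constant(traits[["log_ne"]].values)
        ).fit()
        assert np.allclose(fit.params.values, ols.params, rtol=1e-8)
        assert np.allclose(fit.bse.values, ols.bse, rtol=1e-8)
        assert fit.pvalues["log_ne"] == pytest.approx(ols.pvalues[1], rel=1e-8)

    def test_ml_lambda_beats_grid(self):
        tree, traits, _ = sd.build_comparative(sd.ComparativeSimConfig(n_species=40, seed=8))
        y = traits["taa_enrichment"]
        X = traits[["log_ne"]]
        fit = pgls_fit(y, X, tree)
        V = brownian_cov(tree, list(y.index))
        for lam in np.linspace(0, 1, 21):
            ll = cp._profile_loglik(y.values, np.column_stack([np.ones(len(y)), X.values]), V, lam)
            assert fit.loglik >= ll - 1e-6

    def test_iid_noise_gives_low_lambda(self):
        lams = []
        for seed in range(15):
            tree, traits, _ = sd.build_comparative(
                sd.ComparativeSimConfig(n_species=40, lambda_true=0.0, b=0.0, seed=seed)
            )
            rng = np.random.default_rng(seed + 1000)
            y = pd.Series(rng.standard_normal(len(traits)), index=traits.index)
            lams.append(pgls_fit(y, traits[["log_ne"]], tree).lam)
        assert np.median(lams) < 0.1

    def test_singular_design_names_columns(self):
        tree, traits, _ = sd.build_comparative(sd.ComparativeSimConfig(n_species=20, seed=2))
        X = traits[["log_ne"]].copy()
        X["log_ne_copy"] = X["log_ne"]
        with pytest.raises(ValueError, match="log_ne"):
            pgls_fit(traits["taa_enrichment"], X, tree)

    def test_multiple_regression_with_cellularity(self):
        tree, traits, _ = sd.build_comparative(sd.ComparativeSimConfig(n_species=40, seed=6))
        fit = pgls_fit(
            traits["taa_enrichment"],
            traits[["log_ne", "cellularity"]].astype(float),
            tree,
        )
        assert set(fit.params.index) == {"intercept", "log_ne", "cellularity"}
        assert fit.r2_adj <= 1.0

    def test_null_slope_pvalues_uniform(self):
        """With b = 0 and lambda_true = 0, slope p-values are uniform
        across replicate simulations (KS test at alpha = 0.01)."""
        from scipy.stats import kstest

        pvals = []
        for seed in range(500):
            tree, traits, _ = sd.build_comparative(
                sd.ComparativeSimConfig(n_species=25, lambda_true=0.0, b=0.0, seed=seed)
            )
            fit = pgls_fit(traits["taa_enrichment"], traits[["log_ne"]], tree)
            pvals.append(fit.pvalues["log_ne"])
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestFisherExact:
    def test_identity_table(self):
        assert fisher_exact_2x2([[1, 0], [0, 1]]) == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        """Brute force over all tables with the observed margins."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            t = rng.integers(0, 13, size=(2, 2))
            r1, r2 = t[0].sum(), t[1].sum()
            c1 = t[:, 0].sum()

            def prob(a):
                return (
                    comb(r1, a, exact=True)
                    * comb(r2, c1 - a, exact=True)
                    / comb(r1 + r2, c1, exact=True)
                )

            lo, hi = max(0, c1 - r2), min(r1, c1)
            p_obs = prob(t[0, 0])
            expected = sum(prob(a) for a in range(lo, hi + 1) if prob(a) <= p_obs * (1 + 1e-9))
            assert fisher_exact_2x2(t.tolist()) == pytest.approx(expected, rel=1e-9)


class TestTaaDisparity:
    def test_equal_frequencies(self):
        ctx = [make_context(stop="TAA"), make_context(stop="TGA")]
        assert taa_disparity(ctx, list(ctx)) == pytest.approx(1.0)

    def test_arithmetic(self):
        heg = [make_context(stop="TAA")] * 6 + [make_context(stop="TGA")] * 4
        leg = [make_context(stop="TAA")] * 4 + [make_context(stop="TGA")] * 6
        assert taa_disparity(heg, leg) == pytest.approx(1.5)

    def test_zero_leg_frequency_errors(self):
        heg = [make_context(stop="TAA")]
        leg = [make_context(stop="TGA")]
        with pytest.raises(ValueError):
            taa_disparity(heg, leg)


class TestRankTests:
    def test_spearman_perfect_correlation(self):
        rho, _ = rank_tests([1, 2, 3, 4], [10, 20, 30, 40], "spearman")
        assert rho == pytest.approx(1.0)
        rho, _ = rank_tests([1, 2, 3, 4], [40, 30, 20, 10], "spearman")
        assert rho == pytest.approx(-1.0)

    def test_wilcoxon_zero_differences_error(self):
        with pytest.raises(ValueError):
            rank_tests([1.0, 2.0], [1.0, 2.0], "wilcoxon")

    def test_wilcoxon_type_i_calibration(self):
        """Symmetric-about-zero differences reject at ~alpha."""
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            a = rng.standard_normal(25)
            _, p = rank_tests(a, np.zeros(25), "wilcoxon")
            rejections += p < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / reps)


def test_parse_formula():
    assert parse_formula("asc_enrichment ~ ne + cellularity") == (
        "asc_enrichment",
        ["ne", "cellularity"],
    )
    with pytest.raises(ValueError):
        parse_formula("no_tilde_here")
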