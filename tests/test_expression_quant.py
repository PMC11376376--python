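"""Delta-Ct normalization, repeatability, group tests and PCA."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pipeqtl as pq
from pipeqtl._reml import fit_random_intercept
from pipeqtl.exceptions import ConfigurationError, EstimationError, UnknownIdentifierError


def ct_frame(rows):
    return pd.DataFrame(rows, columns=["line", "bio_rep", "tech_rep", "gene", "ct"])


class TestRelativeExpression:
    def test_hand_computed_delta_ct(self):
        """target 24 vs references (21, 22, 23): dCt = 22 - 24 = -2, 2^dCt = 0.25."""
        ct = ct_frame(
            [("A", 1, 1, "tgt", 24.0), ("A", 1, 1, "r1", 21.0),
             ("A", 1, 1, "r2", 22.0), ("A", 1, 1, "r3", 23.0)]
        )
        expr = pq.relative_expression(ct, ["r1", "r2", "r3"])
        val = expr.loc[expr.gene == "tgt", "log2_rel_expr"].iloc[0]
        assert val == pytest.approx(-2.0)
        assert 2.0**val == pytest.approx(0.25)

    def test_target_equal_to_reference_mean_is_zero(self):
        ct = ct_frame(
            [("A", 1, 1, "tgt", 22.0), ("A", 1, 1, "r1", 21.0), ("A", 1, 1, "r2", 23.0)]
        )
        expr = pq.relative_expression(ct, ["r1", "r2"])
        assert expr["log2_rel_expr"].iloc[0] == pytest.approx(0.0)

    def test_technical_replicates_averaged_on_ct_scale_first(self):
        """tech means 24.2 and 22.1 give dCt = -2.1 (averaging order matters)."""
        ct = ct_frame(
            [("A", 1, 1, "tgt", 24.0), ("A", 1, 2, "tgt", 24.4),
             ("A", 1, 1, "ref", 22.0), ("A", 1, 2, "ref", 22.2)]
        )
        expr = pq.relative_expression(ct, ["ref"])
        assert expr["log2_rel_expr"].iloc[0] == pytest.approx(-2.1)

    def test_unknown_reference_raises(self):
        ct = ct_frame([("A", 1, 1, "tgt", 24.0), ("A", 1, 1, "ref", 22.0)])
        with pytest.raises(ConfigurationError):
            pq.relative_expression(ct, ["ghost"])

    def test_sample_missing_a_reference_is_emitted_missing(self):
        ct = ct_frame(
            [("A", 1, 1, "tgt", 24.0), ("A", 1, 1, "r1", 22.0), ("A", 1, 1, "r2", 21.0),
             ("B", 1, 1, "tgt", 25.0), ("B", 1, 1, "r1", 22.0)]
        )
        expr = pq.relative_expression(ct, ["r1", "r2"])
        b = expr[(expr.line == "B") & (expr.gene == "tgt")]
        assert len(b) == 1 and np.isnan(b["log2_rel_expr"].iloc[0])

    @given(st.floats(-5, 5), st.floats(15, 30))
    @settings(max_examples=25, deadline=None)
    def test_log2_of_quantity_is_delta_ct(self, dct, ref_ct):
        """log2(2^dCt) == dCt: normalization and log compose to identity."""
        ct = ct_frame(
            [("A", 1, 1, "tgt", ref_ct - dct), ("A", 1, 1, "r1", ref_ct - 1), ("A", 1, 1, "r2", ref_ct + 1)]
        )
        expr = pq.relative_expression(ct, ["r1", "r2"])
        val = expr["log2_rel_expr"].iloc[0]
        assert np.log2(2.0**val) == pytest.approx(val)
        assert val == pytest.approx(dct, abs=1e-9)


class TestGenotypeMeans:
    def test_mean_and_missing_handling(self):
        expr = pd.DataFrame(
            {"line": ["A"] * 3 + ["B"] * 3, "bio_rep": [1, 2, 3] * 2, "gene": "t",
             "log2_rel_expr": [-2.0, -1.0, 0.0, -2.0, -1.0, np.nan]}
        )
        gm = pq.genotype_means(expr, "t")
        assert gm.loc["A", "value"] == pytest.approx(-1.0) and gm.loc["A", "n_reps"] == 3
        assert gm.loc["B", "value"] == pytest.approx(-1.5) and gm.loc["B", "n_reps"] == 2

    def test_replicate_order_invariance(self):
        expr = pd.DataFrame(
            {"line": "A", "bio_rep": [1, 2, 3], "gene": "t", "log2_rel_expr": [0.3, -1.2, 2.0]}
        )
        shuffled = expr.sample(frac=1.0, random_state=1)
        assert pq.genotype_means(expr, "t").equals(pq.genotype_means(shuffled, "t"))

    def test_unknown_trait(self):
        expr = pd.DataFrame({"line": ["A"], "bio_rep": [1], "gene": ["t"], "log2_rel_expr": [0.0]})
        with pytest.raises(UnknownIdentifierError):
            pq.genotype_means(expr, "ghost")


def balanced_expr(values):
    n_geno, n_rep = values.shape
    return pd.DataFrame(
        {
            "line": np.repeat([f"G{i}" for i in range(n_geno)], n_rep),
            "bio_rep": np.tile(np.arange(1, n_rep + 1), n_geno),
            "gene": "t",
            "log2_rel_expr": values.ravel(),
        }
    )


class TestHeritability:
    def test_zero_within_variance_gives_one(self):
        vals = np.repeat([[0.0], [1.0], [2.0]], 3, axis=1)
        h = pq.heritability(balanced_expr(vals), "t")
        assert h.h == pytest.approx(1.0, abs=1e-4)

    def test_all_equal_gives_zero(self):
        h = pq.heritability(balanced_expr(np.full((5, 3), 2.5)), "t")
        assert h.vg == 0.0 and h.h == 0.0

    def test_single_genotype_raises(self):
        with pytest.raises(EstimationError):
            pq.heritability(balanced_expr(np.array([[1.0, 2.0, 3.0]])), "t")

    def test_reml_matches_moment_estimator_on_balanced_design(self):
        """REML equals the balanced-ANOVA (MSB-MSW)/n estimator."""
        rng = np.random.default_rng(4)
        for _ in range(5):
            vals = rng.normal(0, 1, (80, 3)) + rng.normal(0, 1.5, (80, 1))
            expr = balanced_expr(vals)
            fit = pq.heritability(expr, "t")
            msb = vals.mean(axis=1).var(ddof=1) * 3
            msw = vals.var(axis=1, ddof=1).mean()
            vg_mom, ve_mom = max((msb - msw) / 3, 0.0), msw
            assert fit.vg == pytest.approx(vg_mom, abs=1e-6)
            assert fit.ve == pytest.approx(ve_mom, abs=1e-6)

    @given(st.floats(-50, 50), st.floats(0.1, 10))
    @settings(max_examples=15, deadline=None)
    def test_shift_and_scale_invariance(self, shift, scale):
        rng = np.random.default_rng(12)
        vals = rng.normal(0, 1, (40, 3)) + rng.normal(0, 1, (40, 1))
        h0 = pq.heritability(balanced_expr(vals), "t").h
        h1 = pq.heritability(balanced_expr(vals * scale + shift), "t").h
        assert h1 == pytest.approx(h0, abs=1e-5)

    def test_cross_check_against_statsmodels_mixedlm(self):
        """Dual route: the profiled REML matches statsmodels MixedLM."""
        import warnings
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(8)
        vals = rng.normal(0, 1, (60, 3)) + rng.normal(0, 1.2, (60, 1))
        expr = balanced_expr(vals)
        ours = pq.heritability(expr, "t")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm_fit = smf.mixedlm("log2_rel_expr ~ 1", expr, groups=expr["line"]).fit(reml=True)
        assert ours.vg == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]), rel=1e-3, abs=1e-4)
        assert ours.ve == pytest.approx(float(sm_fit.scale), rel=1e-3, abs=1e-4)


class TestGroupTests:
    def test_kruskal_matches_brute_force_rank_formula(self):
        """H on {1,2,3} vs {4,5,6} from the rank definition."""
        trait = pd.Series([1, 2, 3, 4, 5, 6.0], index=list("abcdef"))
        groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=trait.index)
        res = pq.group_tests(trait, groups)
        n = 6
        ranks = trait.rank()
        h_oracle = 12.0 / (n * (n + 1)) * sum(
            3 * (ranks[groups == g].mean() - (n + 1) / 2) ** 2 for g in ("g1", "g2")
        )
        assert res.statistic == pytest.approx(h_oracle)

    def test_permutation_null_uniform(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, 45)
        groups = pd.Series(
            np.repeat(["a", "b", "c"], 15), index=[f"L{i}" for i in range(45)]
        )
        ps = []
        for _ in range(500):
            perm = rng.permutation(base)
            trait = pd.Series(perm, index=groups.index)
            ps.append(pq.group_tests(trait, groups).pvalue)
        from scipy import stats

        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_separated_pair_has_smallest_adjusted_p(self):
        trait = pd.Series(
            [1, 2, 3, 10, 11, 12, 1, 2, 3.0],
            index=[f"L{i}" for i in range(9)],
        )
        groups = pd.Series(np.repeat(["a", "b", "c"], 3), index=trait.index)
        res = pq.group_tests(trait, groups)
        best = res.pairwise.sort_values("p_holm").iloc[0]
        assert {best["group1"], best["group2"]} in ({"a", "b"}, {"b", "c"})

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        trait = pd.Series(rng.normal(0, 1, 30), index=[f"L{i}" for i in range(30)])
        groups = pd.Series(np.repeat(["a", "b", "c"], 10), index=trait.index)
        p0 = pq.group_tests(trait, groups).pvalue
        p1 = pq.group_tests(np.exp(trait), groups).pvalue
        assert p0 == pytest.approx(p1)

    def test_small_group_skipped(self):
        trait = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        groups = pd.Series(["g1", "g1", "g2", "g2", "g3"], index=trait.index)
        res = pq.group_tests(trait, groups)
        assert set(res.pairwise[["group1", "group2"]].stack()) == {"g1", "g2"}


class TestPCA:
    def test_two_perfectly_correlated_traits(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 30)
        df = pd.DataFrame({"t1": a, "t2": 2 * a + 1}, index=[f"L{i}" for i in range(30)])
        res = pq.pca_summary(df)
        assert res.percent_variance[0] == pytest.approx(100.0)

    def test_loadings_orthonormal_and_variance_sums_to_100(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.normal(0, 1, (50, 4)), columns=list("abcd"))
        res = pq.pca_summary(df)
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(4), atol=1e-10)
        assert res.percent_variance.sum() == pytest.approx(100.0)

    def test_independent_trait_dominates_later_component(self):
        rng = np.random.default_rng(9)
        base = rng.normal(0, 1, 200)
        df = pd.DataFrame(
            {
                "t1": base + 0.2 * rng.normal(size=200),
                "t2": base + 0.2 * rng.normal(size=200),
                "t3": base + 0.2 * rng.normal(size=200),
                "solo": rng.normal(size=200),
            }
        )
        res = pq.pca_summary(df)
        # the independent trait carries its own (second) component
        assert abs(res.loadings.loc["solo", "PC2"]) > 0.9

    def test_constant_trait_removed(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"a": rng.normal(size=20), "b": rng.normal(size=20), "c": 1.0})
        res = pq.pca_summary(df)
        assert "c" not in res.loadings.index


def test_random_intercept_reml_against_statsmodels():
    """The shared LMM engine agrees with statsmodels on an unbalanced design."""
    import warnings
    import statsmodels.formula.api as smf

    rng = np.random.default_rng(10)
    groups = np.repeat(np.arange(8), rng.integers(4, 12, 8).tolist()[:8])
    # rebuild with actual sizes
    sizes = rng.integers(4, 12, 8)
    groups = np.concatenate([np.full(s, i) for i, s in enumerate(sizes)])
    x = rng.normal(0, 1, len(groups))
    y = 0.7 * x + np.repeat(rng.normal(0, 0.8, 8), sizes) + rng.normal(0, 1.1, len(groups))
    X = np.column_stack([np.ones_like(x), x])
    fit = fit_random_intercept(y, X, groups)
    df = pd.DataFrame({"y": y, "x": x, "g": groups})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sm_fit = smf.mixedlm("y ~ x", df, groups=df["g"]).fit(reml=True)
    assert fit.beta[1] == pytest.approx(float(sm_fit.params["x"]), abs=1e-4)
    assert fit.sigma_e2 == pytest.approx(float(sm_fit.scale), rel=1e-3)
    assert fit.sigma_u2 == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]), rel=1e-2, abs=1e-3)
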