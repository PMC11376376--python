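"""Kinship, spectral REML, GLS scan, conditional and subpanel variants."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pipeqtl as pq
from pipeqtl.containers import KinshipSet
from pipeqtl.exceptions import DesignError, EstimationError, UnknownIdentifierError
from pipeqtl.mixed_model_gwas import compute_kinship, fit_null

from conftest import make_genotypes


def brute_force_kinship(dosages):
    """Naive O(n^2 m) VanRaden method 1 on mean-imputed dosages."""
    x = dosages.copy()
    for j in range(x.shape[1]):
        col = x[:, j]
        col[np.isnan(col)] = np.nanmean(col)
    p = x.mean(axis=0) / 2
    keep = (p > 0) & (p < 1)
    x, p = x[:, keep], p[keep]
    z = x - 2 * p
    denom = 2 * np.sum(p * (1 - p))
    n = x.shape[0]
    k = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            k[i, j] = np.dot(z[i], z[j]) / denom
    return k


def dense_gls_pvalues(y, X0, markers, V):
    """Explicit (X'V^-1 X)^-1 X'V^-1 y oracle with the same 1-df F-test."""
    Vi = np.linalg.inv(V)
    n = len(y)
    A0 = X0.T @ Vi @ X0
    b0 = np.linalg.solve(A0, X0.T @ Vi @ y)
    r0 = y - X0 @ b0
    rss0 = float(r0 @ Vi @ r0)
    out_p, out_beta = [], []
    dof = n - X0.shape[1] - 1
    for j in range(markers.shape[1]):
        X = np.column_stack([X0, markers[:, j]])
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        r = y - X @ beta
        rss1 = float(r @ Vi @ r)
        f = (rss0 - rss1) / (rss1 / dof)
        out_p.append(stats.f.sf(f, 1, dof))
        out_beta.append(beta[-1])
    return np.array(out_p), np.array(out_beta)


class TestKinship:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        dos = rng.integers(0, 3, (50, 500)).astype(float)
        dos[rng.random((50, 500)) < 0.02] = np.nan
        geno = make_genotypes(dos)
        k = compute_kinship(geno)
        assert np.max(np.abs(k - brute_force_kinship(dos.copy()))) < 1e-10

    def test_identical_lines_have_equal_rows(self):
        rng = np.random.default_rng(1)
        dos = rng.integers(0, 3, (10, 100)).astype(float)
        dos[1] = dos[0]
        k = compute_kinship(make_genotypes(dos))
        assert np.allclose(k[0], k[1])
        assert k[0, 0] == pytest.approx(k[0, 1])

    def test_excluding_all_markers_raises(self):
        rng = np.random.default_rng(2)
        geno = make_genotypes(rng.integers(0, 3, (10, 50)).astype(float), chrom="1")
        with pytest.raises(EstimationError):
            compute_kinship(geno, exclude_chromosome="1")

    def test_loco_set_excludes_each_chromosome(self, small_panel):
        geno, _ = small_panel
        ks = pq.build_kinship_set(geno)
        assert set(ks.loco) == set(geno.chromosomes)
        for c, n_used in ks.n_markers_used.items():
            assert n_used == (geno.markers["chrom"] != c).sum()


class TestFitNull:
    def test_constant_trait_degenerate(self, small_panel):
        geno, _ = small_panel
        k = compute_kinship(geno)
        vc = fit_null(np.full(geno.n_lines, 3.0), k)
        assert vc.sigma_g2 == 0.0 and vc.sigma_e2 == 0.0 and not vc.converged

    def test_pure_noise_concentrates_genetic_fraction_near_zero(self):
        """With no genetic signal the estimated genetic fraction stays small.

        The REML ratio has a positive sampling tail even under the null, so
        the check is on concentration: small mean and small upper quantile of
        h^2 at panel scale.
        """
        cfg = pq.PanelConfig(n_lines=252, n_chrom=3, markers_per_chrom=500, seed=11)
        geno, _ = pq.simulate_panel(cfg)
        k = compute_kinship(geno)
        rng = np.random.default_rng(3)
        h2 = []
        for _ in range(200):
            vc = fit_null(rng.normal(0, 1, geno.n_lines), k)
            h2.append(vc.h2)
        h2 = np.array(h2)
        assert h2.mean() < 0.05
        assert np.mean(h2 < 0.15) >= 0.95

    def test_h2_recovery(self):
        """Planted sigma_g^2 = sigma_e^2 recovers h^2 = 0.5 on average."""
        cfg = pq.PanelConfig(n_lines=200, n_chrom=2, markers_per_chrom=200, seed=7)
        geno, _ = pq.simulate_panel(cfg)
        k = compute_kinship(geno)
        kn = k / np.mean(np.diag(k))
        L = np.linalg.cholesky(kn + 1e-8 * np.eye(200))
        rng = np.random.default_rng(8)
        h2 = []
        for _ in range(100):
            y = L @ rng.standard_normal(200) + rng.standard_normal(200)
            vc = fit_null(y, kn)
            h2.append(vc.h2)
        assert np.mean(h2) == pytest.approx(0.5, abs=0.05)


class TestScan:
    def test_ols_limit_with_identity_kinship(self):
        """K = I: mixed-model p-values equal simple linear regression."""
        rng = np.random.default_rng(4)
        n, m = 80, 40
        geno = make_genotypes(rng.integers(0, 3, (n, m)).astype(float))
        y = pd.Series(rng.normal(0, 1, n), index=geno.lines)
        kin = KinshipSet(lines=geno.lines, global_k=np.eye(n), loco={"1": np.eye(n)})
        rec = pq.scan(y, geno, kin, pq.ScanConfig(maf_min=0.0))
        for _, r in rec.iterrows():
            sl = stats.linregress(geno.dosage(r["marker"]), y.to_numpy())
            assert r["p"] == pytest.approx(sl.pvalue, abs=1e-10)

    def test_spectral_equals_dense_gls_oracle(self):
        """Spectral shortcut == explicit dense GLS on a 50-line panel."""
        cfg = pq.PanelConfig(n_lines=50, n_chrom=2, markers_per_chrom=150, seed=13)
        geno, _ = pq.simulate_panel(cfg)
        kin = pq.build_kinship_set(geno)
        rng = np.random.default_rng(14)
        mid = pq.marker_near(geno, "1", 0.4)
        y = pd.Series(
            0.4 * geno.dosage(mid, imputed=True) + rng.normal(0, 1, 50), index=geno.lines
        )
        rec = pq.scan(y, geno, kin, pq.ScanConfig(maf_min=0.0))
        for chrom in geno.chromosomes:
            K = kin.loco[chrom]
            vc = fit_null(y.to_numpy(), K)
            V = vc.sigma_g2 * K + vc.sigma_e2 * np.eye(50)
            sub = rec[rec["chrom"] == chrom]
            cols = [geno.marker_index(mk) for mk in sub["marker"]]
            p_oracle, b_oracle = dense_gls_pvalues(
                y.to_numpy(), np.ones((50, 1)), geno.imputed(np.array(cols)), V
            )
            rel = np.abs(p_oracle - sub["p"].to_numpy()) / np.maximum(p_oracle, 1e-300)
            assert rel.max() < 1e-8
            assert np.max(np.abs(b_oracle - sub["beta"].to_numpy())) < 1e-8

    def test_affine_trait_invariance(self, small_panel):
        geno, _ = small_panel
        kin = pq.build_kinship_set(geno)
        rng = np.random.default_rng(6)
        y = pd.Series(rng.normal(0, 1, geno.n_lines), index=geno.lines)
        r0 = pq.scan(y, geno, kin)
        r1 = pq.scan(3.0 * y - 7.0, geno, kin)
        assert np.allclose(r0["p"], r1["p"], atol=1e-9, equal_nan=True)

    def test_maf_filter_and_counts(self, small_panel):
        geno, _ = small_panel
        kin = pq.build_kinship_set(geno)
        rng = np.random.default_rng(6)
        y = pd.Series(rng.normal(0, 1, geno.n_lines), index=geno.lines)
        rec = pq.scan(y, geno, kin, pq.ScanConfig(maf_min=0.2))
        assert (rec["maf"] > 0.2).all()
        skipped = rec.attrs["n_skipped_maf"] + rec.attrs["n_monomorphic"]
        assert len(rec) + skipped == geno.n_markers

    def test_logp_precision_for_strong_signals(self):
        """logp is computed on the log scale (no underflow at logp ~ 40)."""
        rng = np.random.default_rng(15)
        n = 250
        x = rng.integers(0, 2, n) * 2.0
        dos = np.column_stack([x, rng.integers(0, 3, (n, 20)).astype(float)])
        geno = make_genotypes(dos)
        kin = KinshipSet(lines=geno.lines, global_k=np.eye(n), loco={"1": np.eye(n)})
        y = pd.Series(1.2 * x + rng.normal(0, 0.8, n), index=geno.lines)
        rec = pq.scan(y, geno, kin)
        top = rec.loc[rec["logp"].idxmax()]
        assert top["marker"] == "M0" and np.isfinite(top["logp"]) and top["logp"] > 30


class TestRefitPerMarker:
    def test_exact_refit_close_to_p3d_for_planted_signal(self):
        cfg = pq.PanelConfig(n_lines=80, n_chrom=2, markers_per_chrom=60, seed=23)
        geno, _ = pq.simulate_panel(cfg)
        kin = pq.build_kinship_set(geno)
        mid = pq.marker_near(geno, "1", 0.5)
        rng = np.random.default_rng(24)
        y = pd.Series(
            0.6 * geno.dosage(mid, imputed=True) + rng.normal(0, 0.8, 80), index=geno.lines
        )
        p3d = pq.scan(y, geno, kin)
        exact = pq.scan(y, geno, kin, pq.ScanConfig(refit_per_marker=True))
        sig = p3d["logp"] >= 5
        if sig.any():
            assert np.max(np.abs(p3d.loc[sig, "logp"] - exact.loc[sig, "logp"])) < 0.2


class TestConditionalScan:
    def test_orthogonal_covariate_leaves_pvalues_unchanged(self):
        """Conditioning on a marker uncorrelated with trait and testers."""
        rng = np.random.default_rng(16)
        n = 120
        dos = rng.integers(0, 3, (n, 30)).astype(float)
        cov = np.zeros(n)
        cov[: n // 2] = 2.0
        rng.shuffle(cov)
        # make the covariate orthogonal to every tested marker
        dos = np.column_stack([dos - dos.mean(0), cov])
        for j in range(30):
            dos[:, j] -= (dos[:, j] @ (cov - cov.mean())) / np.sum((cov - cov.mean()) ** 2) * (cov - cov.mean())
        dos[:, :30] += 1.0
        geno = make_genotypes(dos)
        kin = KinshipSet(lines=geno.lines, global_k=np.eye(n), loco={"1": np.eye(n)})
        y = pd.Series(rng.normal(0, 1, n), index=geno.lines)
        y -= (y @ (cov - cov.mean())) / np.sum((cov - cov.mean()) ** 2) * (cov - cov.mean())
        r0 = pq.scan(y, geno, kin, pq.ScanConfig(maf_min=0.0))
        r1 = pq.conditional_scan(
            y, geno, kin, pq.ScanConfig(maf_min=0.0, covariate_markers=("M30",))
        )
        both = r0.merge(r1, on="marker", suffixes=("_0", "_1"))
        both = both[both["marker"] != "M30"].dropna(subset=["p_0", "p_1"])
        # effect estimates are exactly unchanged; p-values shift only by the
        # one residual degree of freedom the covariate consumes (O(1/n))
        assert np.max(np.abs(both["beta_0"] - both["beta_1"])) < 1e-9
        assert np.max(np.abs(both["p_0"] - both["p_1"])) < 5e-3

    def test_testing_the_covariate_itself_is_missing(self, small_panel):
        geno, _ = small_panel
        kin = pq.build_kinship_set(geno)
        rng = np.random.default_rng(17)
        y = pd.Series(rng.normal(0, 1, geno.n_lines), index=geno.lines)
        mid = pq.marker_near(geno, "1", 0.5)
        rec = pq.conditional_scan(
            y, geno, kin, pq.ScanConfig(covariate_markers=(mid,))
        )
        row = rec[rec["marker"] == mid]
        assert len(row) == 1 and np.isnan(row["p"].iloc[0])

    def test_unknown_covariate_raises(self, small_panel):
        geno, _ = small_panel
        kin = pq.build_kinship_set(geno)
        y = pd.Series(0.0, index=geno.lines)
        with pytest.raises(UnknownIdentifierError):
            pq.conditional_scan(
                y, geno, kin, pq.ScanConfig(covariate_markers=("ghost",))
            )


class TestSubpanelScan:
    def test_full_mask_identical_to_scan(self, small_panel):
        geno, _ = small_panel
        kin = pq.build_kinship_set(geno)
        rng = np.random.default_rng(18)
        y = pd.Series(rng.normal(0, 1, geno.n_lines), index=geno.lines)
        full = pq.scan(y, geno, kin)
        sub = pq.subpanel_scan(y, geno, np.ones(geno.n_lines, bool))
        pd.testing.assert_frame_equal(full, sub)

    def test_paper_style_mask_arithmetic(self):
        """252 lines minus 29 unfavorable and 3 heterozygous leaves 220."""
        mask = np.ones(252, bool)
        mask[:29] = False  # unfavorable homozygotes
        mask[29:32] = False  # heterozygotes
        assert mask.sum() == 220

    def test_too_few_lines_raises(self, small_panel):
        geno, _ = small_panel
        y = pd.Series(0.0, index=geno.lines)
        mask = np.zeros(geno.n_lines, bool)
        mask[:10] = True
        with pytest.raises(EstimationError):
            pq.subpanel_scan(y, geno, mask)


class TestR2LR:
    def test_equal_likelihoods_give_zero(self):
        vc = pq.VarianceComponents(1.0, 1.0, -100.0, True, 50)
        assert pq.r2_lr(vc, vc, 50) == 0.0

    def test_mismatched_observations_raise(self):
        a = pq.VarianceComponents(1.0, 1.0, -100.0, True, 50)
        b = pq.VarianceComponents(1.0, 1.0, -90.0, True, 40)
        with pytest.raises(DesignError):
            pq.r2_lr(a, b, 50)

    def test_ols_equivalence_at_identity_kinship(self):
        """r2_LR approaches the classical R^2 when the marker is the signal."""
        rng = np.random.default_rng(19)
        n = 200
        x = rng.integers(0, 3, n).astype(float)
        y = x + rng.normal(0, 0.6, n)
        dos = np.column_stack([x, rng.integers(0, 3, (n, 10)).astype(float)])
        geno = make_genotypes(dos)
        kin = KinshipSet(lines=geno.lines, global_k=np.eye(n), loco={"1": np.eye(n)})
        rec = pq.scan(pd.Series(y, index=geno.lines), geno, kin, pq.ScanConfig(maf_min=0.0))
        classical = np.corrcoef(x, y)[0, 1] ** 2
        assert rec.loc[rec["marker"] == "M0", "r2_lr"].iloc[0] == pytest.approx(
            classical, abs=0.02
        )

    def test_planted_r2_recovery(self):
        """Planted marker R^2 = 0.5 at n = 250 is recovered on average."""
        vals = []
        for s in range(25):
            cfg = pq.PanelConfig(n_lines=250, n_chrom=2, markers_per_chrom=120, seed=400 + s)
            geno, _ = pq.simulate_panel(cfg)
            mid = pq.marker_near(geno, "1", 0.5, min_maf=0.25)
            eff = pq.effect_for_marker_r2(geno, mid, 0.5, other_var=0.3)
            rng = np.random.default_rng(s)
            y = pd.Series(
                eff * geno.dosage(mid, imputed=True) + rng.normal(0, np.sqrt(0.3), 250),
                index=geno.lines,
            )
            kin = pq.build_kinship_set(geno)
            rec = pq.scan(y, geno, kin)
            vals.append(float(rec.loc[rec["marker"] == mid, "r2_lr"].iloc[0]))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.08)


def test_effect_allele_convention_flips_sign(small_panel):
    geno, _ = small_panel
    kin = pq.build_kinship_set(geno)
    rng = np.random.default_rng(20)
    y = pd.Series(rng.normal(0, 1, geno.n_lines), index=geno.lines)
    alt = pq.scan(y, geno, kin, pq.ScanConfig(effect_allele="alt"))
    ref = pq.scan(y, geno, kin, pq.ScanConfig(effect_allele="ref"))
    assert np.allclose(alt["beta"], -ref["beta"], equal_nan=True)
    assert np.allclose(alt["p"], ref["p"], equal_nan=True)
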