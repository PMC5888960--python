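"""REML engine and the per-environment marker scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import namqxe as nq
from namqxe.mmscan import (
    KinshipEigen,
    design_matrices,
    fit_null_reml,
    reml_objective,
    scan_per_se,
)
from namqxe.mmscan import test_marker as marker_test


def random_kinship(n, rank, rng):
    A = rng.normal(size=(n, rank))
    K = A @ A.T / rank + 0.5 * np.eye(n)
    return K / np.diag(K).mean()


class TestFitNullReml:
    def test_matches_dense_grid_oracle_small_instance(self):
        """On n=12 instances the optimiser's REML objective must be at
        least that of a 10,000-point log-spaced grid search."""
        rng = np.random.default_rng(3)
        grid = 10.0 ** np.linspace(-5, 5, 10_000)
        for rep in range(4):
            n = 12
            K = random_kinship(n, 3, rng)
            X0 = np.column_stack([np.ones(n), rng.normal(size=n)])
            y = rng.multivariate_normal(np.zeros(n), 2.0 * K + np.eye(n))
            eig = KinshipEigen(K)
            vc = fit_null_reml(y, X0, eig)
            y_rot, X_rot = eig.rotate(y), eig.rotate(X0)
            best_grid = max(reml_objective(l, y_rot, X_rot, eig.s) for l in grid)
            assert vc.reml_loglik >= best_grid - 1e-6

    def test_identity_kinship_reduces_to_ols_variance(self):
        """With K = I the covariance is (sigma2_g + sigma2_e) I, so the
        total variance must equal the OLS residual variance estimate."""
        rng = np.random.default_rng(4)
        n = 80
        X0 = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X0 @ np.array([1.0, 2.0]) + rng.normal(size=n)
        vc = fit_null_reml(y, X0, np.eye(n))
        beta, *_ = np.linalg.lstsq(X0, y, rcond=None)
        s2_ols = np.sum((y - X0 @ beta) ** 2) / (n - 2)
        assert vc.sigma2_g + vc.sigma2_e == pytest.approx(s2_ols, rel=1e-6)

    def test_null_lambda_recovery(self):
        """y generated with sigma2_g = 0: the REML ratio estimate piles up
        at the boundary, so its median over replicates is ~0."""
        rng = np.random.default_rng(5)
        n = 500
        K = random_kinship(n, 40, rng)
        eig = KinshipEigen(K)
        lams = []
        for _ in range(11):
            y = rng.normal(size=n)
            lams.append(fit_null_reml(y, np.ones((n, 1)), eig).lam)
        assert np.median(lams) < 1e-3

    def test_zero_variance_response_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_null_reml(np.ones(10), np.ones((10, 1)), np.eye(10))

    def test_non_psd_kinship_rejected(self):
        K = np.eye(5)
        K[0, 0] = -1.0
        with pytest.raises(ValueError, match="PSD"):
            KinshipEigen(K)


class TestTestMarker:
    def test_identity_kinship_equals_ols_ftest(self):
        rng = np.random.default_rng(6)
        n = 120
        codes = rng.choice([0.0, 1.0, 2.0], size=n, p=[0.7, 0.06, 0.24])
        y = rng.normal(size=n)
        X0 = np.ones((n, 1))
        eig = KinshipEigen(np.eye(n))
        vc = fit_null_reml(y, X0, eig)
        res = marker_test(y, X0, codes, eig, vc)

        import statsmodels.formula.api as smf

        df = pd.DataFrame({"y": y, "g": codes.astype(int).astype(str)})
        fit = smf.ols("y ~ C(g)", df).fit()
        assert res["fstat"] == pytest.approx(fit.fvalue, abs=1e-8)
        assert res["pvalue"] == pytest.approx(fit.f_pvalue, abs=1e-8)

    def test_effect_recovery(self):
        """A simulated Hs/Hs-vs-Hv/Hv effect of +5 units is recovered
        within sampling error at n = 1000."""
        rng = np.random.default_rng(7)
        n = 1000
        codes = rng.choice([0.0, 1.0, 2.0], size=n, p=[0.7, 0.06, 0.24])
        y = 2.5 * codes + rng.normal(size=n)  # Hs/Hs - Hv/Hv = 5
        eig = KinshipEigen(np.eye(n))
        vc = fit_null_reml(y, np.ones((n, 1)), eig)
        res = marker_test(y, np.ones((n, 1)), codes, eig, vc)
        assert res["effect_hshs"] == pytest.approx(5.0, abs=0.35)

    def test_effect_sign_convention(self, nam_pop, nam_kinship):
        """Code-2 carriers constructed to have the higher trait mean must
        yield a positive Hs/Hs effect."""
        marker = nam_pop.markers[4]
        codes = nam_pop.genotypes[marker].to_numpy(float)
        rng = np.random.default_rng(8)
        y = 3.0 * (codes == 2) + rng.normal(size=len(codes), scale=0.5)
        eig = KinshipEigen(nam_kinship.to_numpy())
        X0 = design_matrices(nam_pop.families)
        vc = fit_null_reml(y, X0, eig)
        res = marker_test(y, X0, codes, eig, vc)
        assert res["effect_hshs"] > 0

    def test_monomorphic_flagged(self):
        n = 30
        y = np.random.default_rng(9).normal(size=n)
        eig = KinshipEigen(np.eye(n))
        vc = fit_null_reml(y, np.ones((n, 1)), eig)
        res = marker_test(y, np.ones((n, 1)), np.zeros(n), eig, vc)
        assert res["monomorphic"] and np.isnan(res["pvalue"])

    def test_missing_lines_dropped(self, nam_pop, nam_kinship, qxe_world):
        means = qxe_world["means"]
        codes = nam_pop.genotypes[nam_pop.markers[3]].to_numpy(float).copy()
        codes[:10] = np.nan
        lines, = np.where(~np.isnan(codes))
        y = (
            means[(means["trait"] == "GN") & (means["environment"] == "WW")]
            .set_index("line").loc[nam_pop.genotypes.index, "value"].to_numpy()
        )
        eig = KinshipEigen(nam_kinship.to_numpy())
        X0 = design_matrices(nam_pop.families)
        vc = fit_null_reml(y, X0, eig)
        res = marker_test(y, X0, codes, eig, vc)
        assert res["n"] == len(lines)
        assert np.isfinite(res["pvalue"])


class TestScanPerSe:
    def test_causal_marker_attains_minimum_p(self, small_map):
        pop = nq.simulate_population(small_map, n_families=5, n_per_family=80,
                                     missing_rate=0.0, seed=30)
        K = nq.compute_kinship(pop)
        marker = pop.markers[7]
        arch = nq.ArchitectureSpec(
            trait="T", mean=50.0, loci=[nq.QtlEffect(marker, effect=6.0)],
            heritability=0.2, residual_sd={"WW": 2.0, "WL": 2.0},
        )
        means = nq.line_means(nq.simulate_phenotypes(pop, arch, kinship=K, seed=31))
        scan = scan_per_se(pop, means, "T", "WW", kinship=K)
        assert scan.loc[scan["pvalue"].idxmin(), "marker"] == marker

    def test_identical_input_identical_output(self, nam_pop, nam_kinship, qxe_world):
        means = qxe_world["means"].copy()
        ww = means[means["environment"] == "WW"].copy()
        fake_wl = ww.copy()
        fake_wl["environment"] = "WL"
        both = pd.concat([ww, fake_wl])
        a = scan_per_se(nam_pop, both, "GN", "WW", kinship=nam_kinship)
        b = scan_per_se(nam_pop, both, "GN", "WL", kinship=nam_kinship)
        pd.testing.assert_series_equal(a["pvalue"], b["pvalue"])

    def test_line_permutation_invariance(self, nam_pop, nam_kinship, qxe_world):
        """Consistently permuting line order of all inputs leaves every
        statistic unchanged."""
        means = qxe_world["means"]
        a = scan_per_se(nam_pop, means, "GN", "WL", kinship=nam_kinship)
        rng = np.random.default_rng(12)
        perm = rng.permutation(nam_pop.genotypes.index.to_numpy())
        pop_p = nam_pop.subset_lines(list(perm))
        b = scan_per_se(pop_p, means, "GN", "WL",
                        kinship=nam_kinship.loc[perm, perm])
        np.testing.assert_allclose(a["pvalue"], b["pvalue"], rtol=1e-4)
        np.testing.assert_allclose(a["effect_hshs"], b["effect_hshs"], rtol=1e-5, atol=1e-8)

    def test_p3d_close_to_exact_refit(self, small_map):
        """P3D variance-component reuse changes -log10 p by < 0.2 relative
        to the exact per-marker refit (documented approximation bound)."""
        pop = nq.simulate_population(small_map, n_families=5, n_per_family=60,
                                     missing_rate=0.0, seed=33)
        K = nq.compute_kinship(pop)
        arch = nq.ArchitectureSpec(
            trait="T", mean=50.0,
            loci=[nq.QtlEffect(pop.markers[10], effect=3.0)],
            heritability=0.3, residual_sd={"WW": 2.0, "WL": 2.0},
        )
        means = nq.line_means(nq.simulate_phenotypes(pop, arch, kinship=K, seed=34))
        markers = pop.markers  # 30 markers incl. one causal
        fast = scan_per_se(pop, means, "T", "WW", kinship=K, markers=markers, p3d=True)
        exact = scan_per_se(pop, means, "T", "WW", kinship=K, markers=markers, p3d=False)
        mask = (exact["pvalue"] > 1e-8) & (fast["pvalue"] > 1e-8)
        dlog = np.abs(np.log10(fast.loc[mask, "pvalue"]) - np.log10(exact.loc[mask, "pvalue"]))
        assert dlog.max() < 0.2

    def test_null_pvalues_uniform(self, small_map):
        """All-null architecture: ~5% of markers reach p < 0.05 and the
        p-value distribution is uniform."""
        pop = nq.simulate_population(small_map, n_families=6, n_per_family=85,
                                     missing_rate=0.0, seed=35)
        K = nq.compute_kinship(pop)
        pvals = []
        for seed in (36, 37, 38):
            arch = nq.ArchitectureSpec(trait="T", mean=50.0, heritability=0.3,
                                       residual_sd={"WW": 2.0, "WL": 2.0})
            means = nq.line_means(nq.simulate_phenotypes(pop, arch, kinship=K, seed=seed))
            scan = scan_per_se(pop, means, "T", "WW", kinship=K)
            pvals.extend(scan["pvalue"].dropna().tolist())
        pvals = np.array(pvals)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01
        lo, hi = stats.binom.interval(0.99, len(pvals), 0.05)
        assert lo <= (pvals < 0.05).sum() <= hi
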