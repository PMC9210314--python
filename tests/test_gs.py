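"""Mixed-model solver, prediction kernels and GEBV computation."""

import numpy as np
import pytest

from tritigs import qc
from tritigs.core import GenotypeMatrix
from tritigs.gs import (GSModel, KernelSpec, a_matrix, gauss_kernel,
                        marker_design, predict_gebv, solve_mixed)
from tritigs.mixed import MixedModel
from tritigs.simulate import SimulationConfig, simulate_genotypes


def _sim_geno(seed=0, n=80, m=200):
    cfg = SimulationConfig(seed=seed, n_accessions=n, n_markers=m, missing_rate=0.0)
    geno, _, truth = simulate_genotypes(cfg)
    return geno, truth


class TestMixedModel:
    def test_noiseless_fixed_effects(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(50), rng.normal(size=50)])
        y = X @ np.array([2.0, -1.5])
        res = MixedModel(y, X=X).fit()
        assert res.sigma2_e < 1e-6 * y.var()
        np.testing.assert_allclose(res.u, 0.0, atol=1e-4)
        np.testing.assert_allclose(res.beta, [2.0, -1.5], atol=1e-6)

    def test_ridge_closed_form_at_fixed_lambda(self):
        """BLUP with K=I at externally fixed λ equals the ridge-regression
        closed form (Z'Z + λI)⁻¹ Z'(y − Xβ̂)."""
        rng = np.random.default_rng(1)
        n, q = 60, 25
        Z = rng.normal(size=(n, q))
        y = Z @ rng.normal(size=q) + rng.normal(size=n)
        lam = 3.7
        res = MixedModel(y, Z=Z).fit(fixed_lambda=lam)
        r = y - res.model.X @ res.beta
        oracle = np.linalg.solve(Z.T @ Z + lam * np.eye(q), Z.T @ r)
        np.testing.assert_allclose(res.u, oracle, atol=1e-8)

    def test_h2_recovery(self):
        """REML ĥ² within ±0.1 of the generating h²=0.5 over 20 replicates."""
        h2_hats = []
        geno, _ = _sim_geno(seed=3, n=300, m=400)
        K = a_matrix(geno).K
        L = np.linalg.cholesky(K + 1e-8 * np.eye(len(K)))
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            u = L @ rng.standard_normal(len(K))
            u = u / u.std()
            e = rng.standard_normal(len(K))
            y = 5.0 + u + e * (u.var() / e.var()) ** 0.5  # var(u)=var(e)
            res = MixedModel(y, K=K).fit()
            h2_hats.append(res.h2)
        assert abs(np.mean(h2_hats) - 0.5) < 0.1

    def test_all_equal_y_returns_zero_genetic_variance(self):
        res = MixedModel(np.full(30, 4.2), K=np.eye(30)).fit()
        assert res.sigma2_u == pytest.approx(0.0, abs=1e-10)

    def test_singular_x_rejected(self):
        X = np.ones((10, 2))
        with pytest.raises(ValueError, match="singular"):
            MixedModel(np.arange(10.0), X=X)

    def test_loglik_at_optimum_dominates_grid(self):
        rng = np.random.default_rng(4)
        Z = rng.normal(size=(40, 10))
        y = Z @ rng.normal(size=10) + rng.normal(size=40)
        res = MixedModel(y, Z=Z).fit()
        assert res.loglik >= res.grid_loglik.max() - 1e-9


class TestAMatrix:
    def test_hand_computed_two_accession_panel(self):
        # one marker, p=0.5, dosages (0,2): W=(-1,1)', denom 0.5
        g = GenotypeMatrix(["a", "b"], ["m"], np.array([[0.0], [2.0]]))
        A = a_matrix(g).K
        np.testing.assert_allclose(A, [[2.0, -2.0], [-2.0, 2.0]], atol=1e-12)

    def test_duplicated_accessions(self):
        rng = np.random.default_rng(5)
        d = rng.integers(0, 3, size=(10, 50)).astype(float)
        d[1] = d[0]
        g = GenotypeMatrix([f"a{i}" for i in range(10)],
                           [f"m{j}" for j in range(50)], d)
        A = a_matrix(g).K
        np.testing.assert_allclose(A[0], A[1], atol=1e-12)
        assert A[0, 1] == pytest.approx(A[0, 0], abs=1e-12)

    def test_off_diagonal_mean_near_zero(self):
        geno, _ = _sim_geno(seed=6, n=100, m=500)
        # single unstructured population for the centering property
        cfg = SimulationConfig(seed=6, n_accessions=100, n_markers=500,
                               n_subpops=1, missing_rate=0.0)
        geno, _, _ = simulate_genotypes(cfg)
        A = a_matrix(geno).K
        off = A[np.triu_indices_from(A, k=1)]
        assert abs(off.mean()) < 0.05

    def test_monomorphic_markers_excluded(self):
        d = np.column_stack([np.zeros(6), [0, 1, 2, 0, 1, 2]])
        g = GenotypeMatrix(list("abcdef"), ["m0", "m1"], d)
        with pytest.warns(UserWarning, match="monomorphic"):
            A = a_matrix(g).K
        assert np.isfinite(A).all()


class TestGaussKernel:
    def test_large_theta_approaches_all_ones(self):
        geno, _ = _sim_geno(seed=7, n=20, m=50)
        spec = gauss_kernel(geno)
        K = spec.materialize(theta=1e6)
        np.testing.assert_allclose(K, 1.0, atol=1e-6)

    def test_identical_accessions_have_kernel_one(self):
        d = np.tile([0.0, 1.0, 2.0, 1.0], (3, 1))
        d[2, 0] = 2.0  # make the panel non-degenerate
        g = GenotypeMatrix(["a", "b", "c"], [f"m{j}" for j in range(4)], d)
        spec = gauss_kernel(g)
        assert spec.materialize(theta=1.0)[0, 1] == pytest.approx(1.0)

    def test_identical_panel_rejected(self):
        d = np.tile([0.0, 1.0, 2.0], (4, 1))
        g = GenotypeMatrix(list("abcd"), ["m0", "m1", "m2"], d)
        with pytest.raises(ValueError, match="identical"):
            gauss_kernel(g)

    def test_grid_selection_maximizes_restricted_likelihood(self):
        geno, truth = _sim_geno(seed=8, n=60, m=150)
        rng = np.random.default_rng(0)
        y = truth.breeding_values / truth.breeding_values.std() + rng.normal(size=60)
        spec = gauss_kernel(geno)
        res = solve_mixed(y, spec)
        # brute force over the same grid
        best_ll = -np.inf
        for th in spec.theta_grid:
            ll = MixedModel(y, K=np.exp(-((spec.D / th) ** 2))).fit().loglik
            best_ll = max(best_ll, ll)
        assert res.loglik == pytest.approx(best_ll, abs=1e-9)
        assert spec.grid_loglik.max() == pytest.approx(best_ll, abs=1e-9)


class TestPredictGEBV:
    def test_rrblup_gblup_equivalence(self):
        """RRBLUP and GBLUP (A = WW'/c) give identical GEBVs on the same
        split: the two parametrizations share one covariance family."""
        geno, truth = _sim_geno(seed=9, n=50, m=200)
        rng = np.random.default_rng(1)
        y = truth.breeding_values / truth.breeding_values.std() + 0.8 * rng.normal(size=50)
        train = np.sort(rng.choice(50, size=35, replace=False))
        test = np.setdiff1d(np.arange(50), train)
        g_rr = GSModel(y, geno, model="rrblup").fit(train).predict(test)
        g_gb = GSModel(y, geno, model="gblup").fit(train).predict(test)
        np.testing.assert_allclose(g_rr, g_gb, atol=1e-6)

    def test_clone_of_training_accession_gets_its_fitted_value(self):
        geno, truth = _sim_geno(seed=10, n=40, m=100)
        d = geno.dosages.copy()
        d[-1] = d[0]  # last accession is a clone of the first
        clone = GenotypeMatrix(geno.accession_ids, geno.marker_ids, d)
        rng = np.random.default_rng(2)
        y = rng.normal(size=40)
        train = np.arange(30)
        res = GSModel(y, clone, model="gblup").fit(train)
        gebv_train = res.predict(np.array([0]))
        gebv_clone = res.predict(np.array([39]))
        assert gebv_clone[0] == pytest.approx(gebv_train[0], abs=1e-6)

    def test_infinite_shrinkage_returns_grand_mean(self):
        geno, _ = _sim_geno(seed=11, n=30, m=80)
        rng = np.random.default_rng(3)
        y = rng.normal(size=30)
        spec = a_matrix(geno)
        sub = KernelSpec("additive_A", K=spec.K[np.ix_(range(20), range(20))])
        fit = MixedModel(y[:20], K=sub.K).fit(fixed_lambda=1e12)
        fit.theta = None
        gebv = predict_gebv(fit, spec, np.arange(20), np.arange(20, 30))
        np.testing.assert_allclose(gebv, fit.beta[0], atol=1e-6)

    def test_translation_equivariance(self):
        geno, truth = _sim_geno(seed=12, n=40, m=100)
        rng = np.random.default_rng(4)
        y = rng.normal(size=40)
        train = np.arange(30)
        test = np.arange(30, 40)
        g1 = GSModel(y, geno, model="gblup").fit(train).predict(test)
        g2 = GSModel(y + 7.5, geno, model="gblup").fit(train).predict(test)
        np.testing.assert_allclose(g2 - g1, 7.5, atol=1e-6)

    def test_out_of_kernel_index_rejected(self):
        geno, _ = _sim_geno(seed=13, n=20, m=50)
        y = np.random.default_rng(0).normal(size=20)
        res = GSModel(y, geno, model="gblup").fit(np.arange(15))
        with pytest.raises(ValueError, match="outside"):
            predict_gebv(res.mixed, res.gsmodel.spec, np.arange(15), np.array([25]))


def test_summary_prints_model_and_varcomps():
    geno, truth = _sim_geno(seed=14, n=40, m=100)
    y = truth.breeding_values
    res = GSModel(y, geno, model="gblup").fit()
    s = res.summary()
    assert "GBLUP" in s and "sigma2_u" in s
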