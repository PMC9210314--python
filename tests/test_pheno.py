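"""Lattice/spatial trial adjustment, heritability and environment combination."""

import numpy as np
import pandas as pd
import pytest

from tritigs import pheno
from tritigs.mixed import fit_schall
from tritigs.simulate import FieldTrial, SimulationConfig, simulate_panel


def _make_trial(n_geno=30, n_reps=2, block_sd=0.0, resid_sd=1.0, seed=0,
                geno_sd=5.0, block_size=None):
    """Hand-built balanced lattice trial with known effects."""
    rng = np.random.default_rng(seed)
    block_size = block_size or int(np.sqrt(n_geno))
    g = rng.normal(0, geno_sd, n_geno)
    records = []
    plot = 0
    n_cols = block_size
    for rep in range(n_reps):
        order = rng.permutation(n_geno)
        for k, gi in enumerate(order):
            block_id = f"R{rep}B{k // block_size}"
            records.append({
                "env": "E1", "row": plot // n_cols, "col": plot % n_cols,
                "rep": rep + 1, "block": block_id, "genotype": f"G{gi:03d}",
                "yield_g_m2": 100 + g[gi] + rng.normal(0, resid_sd),
            })
            plot += 1
    df = pd.DataFrame.from_records(records)
    # inject block effects after layout
    blocks = df["block"].unique()
    be = dict(zip(blocks, rng.normal(0, block_sd, len(blocks))))
    df["yield_g_m2"] += df["block"].map(be)
    return FieldTrial("E1", df), g


class TestLattice:
    def test_zero_block_variance_gives_raw_means(self):
        t, _ = _make_trial(block_sd=0.0, resid_sd=0.5, seed=1)
        fit = pheno.fit_lattice(t)
        raw = t.plots.groupby("genotype")["yield_g_m2"].mean().sort_index()
        np.testing.assert_allclose(fit.adjusted_means.to_numpy(),
                                   raw.to_numpy(), atol=0.2)
        assert fit.varcomps["sigma2_b"] < 0.5

    def test_block_variance_recovered(self):
        """Mean REML block variance over 10 trials within 2 MC-SE of truth."""
        true_var = 16.0
        ests = []
        for seed in range(10):
            t, _ = _make_trial(n_geno=64, n_reps=2, block_sd=4.0, resid_sd=2.0,
                               seed=seed)
            ests.append(pheno.fit_lattice(t).varcomps["sigma2_b"])
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - true_var) < 2 * se + 2.0

    def test_single_rep_returns_raw_means_with_warning(self):
        t, _ = _make_trial(n_reps=1, seed=2)
        with pytest.warns(UserWarning, match="single-replicate"):
            fit = pheno.fit_lattice(t)
        raw = t.plots.groupby("genotype")["yield_g_m2"].mean().sort_index()
        pd.testing.assert_series_equal(fit.adjusted_means, raw, check_names=False)

    def test_effect_free_balanced_data_reproduces_raw_means(self):
        t, _ = _make_trial(block_sd=0.0, resid_sd=1e-6, seed=3)
        fit = pheno.fit_lattice(t)
        raw = t.plots.groupby("genotype")["yield_g_m2"].mean().sort_index()
        np.testing.assert_allclose(fit.adjusted_means.to_numpy(), raw.to_numpy(),
                                   atol=1e-6)


class TestSpatial:
    def test_flat_field_fits_constant_surface(self):
        cfg = SimulationConfig(seed=21, n_accessions=60, n_markers=100, n_envs=1,
                               field_rows=12, field_cols=10, n_reps=2,
                               spatial_amplitude=0.0, row_col_sd=0.0)
        _, _, _, trials = simulate_panel(cfg)
        fit = pheno.fit_spatial(trials[0])
        # the unpenalized bilinear part absorbs some noise; "constant" means
        # small relative to the residual scale (sigma_e ~ 68 here)
        assert fit.surface.std() < 0.5 * np.sqrt(fit.varcomps["sigma2_e"])
        # row/col components ~0 up to REML sampling noise (order sigma2_e/n_plots-per-line)
        assert fit.varcomps["sigma2_r"] < 0.1 * fit.varcomps["sigma2_e"]
        assert fit.varcomps["sigma2_c"] < 0.1 * fit.varcomps["sigma2_e"]

    def test_surface_recovery(self):
        cfg = SimulationConfig(seed=400, n_accessions=200, n_markers=100, n_envs=1,
                               field_rows=25, field_cols=16, n_reps=2,
                               spatial_amplitude=100.0, h2_plot=0.6, row_col_sd=10.0)
        _, _, truth, trials = simulate_panel(cfg)
        fit = pheno.fit_spatial(trials[0])
        df = trials[0].plots
        true_s = truth.spatial_surfaces[0][df["row"], df["col"]]
        assert np.corrcoef(fit.surface, true_s)[0, 1] > 0.9

    def test_noiseless_ranking_matches_breeding_values(self):
        cfg = SimulationConfig(seed=23, n_accessions=50, n_markers=100, n_envs=1,
                               field_rows=10, field_cols=10, n_reps=2,
                               spatial_amplitude=0.0, row_col_sd=0.0,
                               ge_variance_ratio=0.0, h2_plot=1 - 1e-9)
        geno, _, truth, trials = simulate_panel(cfg)
        fit = pheno.fit_spatial(trials[0])
        bv = pd.Series(truth.breeding_values, index=geno.accession_ids)
        got = fit.adjusted_means.rank()
        want = bv.loc[fit.adjusted_means.index].rank()
        assert (got == want).all()

    def test_non_grid_layout_rejected(self):
        t, _ = _make_trial(seed=4)
        t.plots["row"] = t.plots["row"] + 0.5
        with pytest.raises(ValueError, match="grid"):
            pheno.fit_spatial(t)

    def test_too_few_knots_rejected(self, small_panel):
        trials = small_panel[3]
        with pytest.raises(ValueError, match="knots"):
            pheno.fit_spatial(trials[0], knots_r=3)


class TestEfficiencyAndH2:
    def test_efficiency_arithmetic(self):
        a = pheno.TrialFit("spatial", "E", {"sigma2_g": 1, "sigma2_e": 80.0},
                           pd.Series(dtype=float), 2)
        b = pheno.TrialFit("lattice", "E", {"sigma2_g": 1, "sigma2_e": 100.0},
                           pd.Series(dtype=float), 2)
        assert pheno.efficiency(a, b) == pytest.approx(20.0)
        assert pheno.efficiency(b, b) == pytest.approx(0.0)

    def test_efficiency_scale_invariant(self):
        for c in (0.01, 1.0, 250.0):
            a = pheno.TrialFit("spatial", "E", {"sigma2_g": 1, "sigma2_e": 60.0 * c},
                               pd.Series(dtype=float), 2)
            b = pheno.TrialFit("lattice", "E", {"sigma2_g": 1, "sigma2_e": 100.0 * c},
                               pd.Series(dtype=float), 2)
            assert pheno.efficiency(a, b) == pytest.approx(40.0)

    def test_zero_lattice_residual_rejected(self):
        a = pheno.TrialFit("spatial", "E", {"sigma2_g": 1, "sigma2_e": 1.0},
                           pd.Series(dtype=float), 2)
        b = pheno.TrialFit("lattice", "E", {"sigma2_g": 1, "sigma2_e": 0.0},
                           pd.Series(dtype=float), 2)
        with pytest.raises(ValueError):
            pheno.efficiency(a, b)

    def test_h2_formula(self):
        fit = pheno.TrialFit("lattice", "E", {"sigma2_g": 50.0, "sigma2_e": 50.0},
                             pd.Series(dtype=float), 2)
        assert pheno.heritability(fit, 2) == pytest.approx(2.0 / 3.0)
        fit0 = pheno.TrialFit("lattice", "E", {"sigma2_g": 0.0, "sigma2_e": 50.0},
                              pd.Series(dtype=float), 2)
        assert pheno.heritability(fit0, 2) == 0.0
        bad = pheno.TrialFit("lattice", "E", {"sigma2_g": 0.0, "sigma2_e": 0.0},
                             pd.Series(dtype=float), 2)
        with pytest.raises(ValueError):
            pheno.heritability(bad, 2)

    def test_h2_recovery_on_simulated_trials(self):
        """Mean spatial Ĥ² within ±0.1 of the generator's entry-mean H²."""
        ests, truths = [], []
        for seed in range(8):
            cfg = SimulationConfig(seed=500 + seed, n_accessions=100, n_markers=150,
                                   n_envs=1, field_rows=20, field_cols=10, n_reps=2)
            _, _, truth, trials = simulate_panel(cfg)
            fit = pheno.fit_spatial(trials[0])
            ests.append(pheno.heritability(fit))
            truths.append(truth.entry_mean_h2(0, 2))
        assert abs(np.mean(ests) - np.mean(truths)) < 0.1


class TestSchallDiagnostics:
    def test_variances_non_negative_and_loglik_non_decreasing(self):
        t, _ = _make_trial(n_geno=36, block_sd=3.0, resid_sd=2.0, seed=5)
        df = t.plots
        X = np.ones((len(df), 1))
        Zb = pd.get_dummies(df["block"]).to_numpy(float)
        Zg = pd.get_dummies(df["genotype"]).to_numpy(float)
        fit = fit_schall(df["yield_g_m2"].to_numpy(), X,
                         {"block": Zb, "genotype": Zg}, track_loglik=True)
        assert all(v >= 0 for v in fit.sigma2.values()) and fit.sigma2_e >= 0
        trace = np.array(fit.loglik_trace)
        assert np.all(np.diff(trace) > -1e-4 * np.abs(trace[:-1]))


class TestCombineEnvironments:
    def _stage1(self, n_geno=20, n_envs=3, shift=None, seed=0, noise=0.0):
        rng = np.random.default_rng(seed)
        base = rng.normal(100, 5, n_geno)
        out = []
        for e in range(n_envs):
            vals = base + (shift[e] if shift else 0.0)
            if noise:
                vals = vals + rng.normal(0, noise, n_geno)
            out.append((f"E{e}", pd.Series(vals, index=[f"G{i}" for i in range(n_geno)])))
        return out, base

    def test_identical_environments(self):
        stage1, base = self._stage1()
        blue = pheno.combine_environments(stage1)
        want = pd.Series(base, index=[f"G{i}" for i in range(len(base))])
        np.testing.assert_allclose(blue.pebv.loc[want.index].to_numpy(),
                                   want.to_numpy(), atol=1e-6)
        assert blue.varcomps["sigma2_env"] == pytest.approx(0.0, abs=1e-6)

    def test_constant_shift_leaves_differences_unchanged(self):
        s_flat, _ = self._stage1(seed=1)
        s_shift, _ = self._stage1(shift=[0.0, 50.0, -30.0], seed=1)
        b1 = pheno.combine_environments(s_flat).pebv
        b2 = pheno.combine_environments(s_shift).pebv
        d1 = b1 - b1.mean()
        d2 = b2 - b2.mean()
        np.testing.assert_allclose(d1.to_numpy(), d2.to_numpy(), atol=1e-6)

    def test_single_environment_rejected(self):
        stage1, _ = self._stage1(n_envs=1)
        with pytest.raises(ValueError, match="2 environments"):
            pheno.combine_environments(stage1)

    def test_averaging_beats_single_environment(self):
        """With GxE present, combined PEBVs track true breeding values better
        than any single environment's means in most replicates."""
        wins = 0
        for seed in range(10):
            cfg = SimulationConfig(seed=700 + seed, n_accessions=80, n_markers=150,
                                   n_envs=3, field_rows=16, field_cols=10, n_reps=2,
                                   ge_variance_ratio=0.5)
            geno, _, truth, trials = simulate_panel(cfg)
            stage1 = [(t.environment,
                       t.plots.groupby("genotype")["yield_g_m2"].mean())
                      for t in trials]
            blue = pheno.combine_environments(stage1)
            bv = pd.Series(truth.breeding_values, index=geno.accession_ids)
            r_comb = np.corrcoef(blue.pebv, bv.loc[blue.pebv.index])[0, 1]
            r_single = np.mean([
                np.corrcoef(m, bv.loc[m.index])[0, 1] for _, m in stage1])
            wins += r_comb > r_single
        assert wins >= 8

    def test_genotype_in_single_environment_warns(self):
        stage1, _ = self._stage1(n_envs=2)
        env, series = stage1[1]
        stage1[1] = (env, series.drop("G0"))
        with pytest.warns(UserWarning, match="single environment"):
            blue = pheno.combine_environments(stage1)
        assert "G0" in blue.pebv.index
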