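"""Inference backend: exactness oracles, DIC, prediction, diagnostics."""

import numpy as np
import pytest

import overlapshift as o
from overlapshift.gmrf import icar_structure
from overlapshift.inference import InferenceConfig, dic, extract_common_trend, fit, predict_missing


def _gaussian_oracle(grid, y, tau_z, tau_v, tau_obs, cfg):
    """Closed-form GMRF conditional for the identity-link Gaussian reduction."""
    adj = o.build_adjacency(grid, cfg.contiguity)
    n = grid.n_active
    r = icar_structure(adj).toarray()
    d = 1 + 2 * n
    qp = np.zeros((d, d))
    qp[0, 0] = cfg.intercept_precision
    qp[1:n + 1, 1:n + 1] = tau_z * r + cfg.jitter * np.eye(n)
    qp[n + 1:, n + 1:] = tau_v * np.eye(n)
    a = np.zeros((n, d))
    a[:, 0] = 1.0
    a[np.arange(n), 1 + np.arange(n)] = 1.0
    a[np.arange(n), n + 1 + np.arange(n)] = 1.0
    q = qp + tau_obs * a.T @ a
    b = tau_obs * a.T @ y
    c = np.zeros((1, d))
    c[0, 1:n + 1] = 1.0 / n
    qi = np.linalg.inv(q)
    m = qi @ b
    mean = m - qi @ c.T @ np.linalg.solve(c @ qi @ c.T, c @ m)
    cov = qi - qi @ c.T @ np.linalg.solve(c @ qi @ c.T, c @ qi)
    return mean, np.sqrt(np.diag(cov)), n


def test_gaussian_reduction_matches_closed_form_posterior():
    grid = o.build_grid(5, 5)
    rng = np.random.default_rng(0)
    y = rng.normal(1.0, 0.7, 25)
    surf = o.SpeciesSurface(grid=grid, values=np.abs(y) + 1e-9, family="gamma")
    spec = o.ModelSpec(species=("s",), family={"s": "gaussian"})
    cfg = InferenceConfig(n_samples=50, fixed_hyperparameters={
        "tau_z": 2.0, "tau_v": 5.0, "tau_obs:s": 4.0})
    f = fit(spec, {"s": surf}, {}, cfg)
    mean, sd, n = _gaussian_oracle(grid, surf.values, 2.0, 5.0, 4.0, cfg)
    assert abs(f.intercepts["s"][0] - mean[0]) < 1e-6
    assert abs(f.intercepts["s"][1] - sd[0]) < 1e-6
    np.testing.assert_allclose(f.cst.mean, mean[1:n + 1], atol=1e-6)
    np.testing.assert_allclose(f.cst.sd, sd[1:n + 1], atol=1e-6)


class TestDic:
    def test_effective_parameters_approach_one_in_conjugate_toy(self):
        """Gaussian mean with a flat prior: pD -> 1 as n grows."""
        n_side = 15
        grid = o.build_grid(n_side, n_side)   # 225 > 200 observations
        rng = np.random.default_rng(1)
        y = rng.normal(2.0, 1.0, n_side**2)
        surf = o.SpeciesSurface(grid=grid, values=np.abs(y) + 1e-9, family="gamma")
        spec = o.ModelSpec(species=("s",), family={"s": "gaussian"},
                           include_spatial=False, include_heterogeneity=False)
        cfg = InferenceConfig(n_samples=2000, seed=3,
                              intercept_precision=1e-9,
                              fixed_hyperparameters={"tau_obs:s": 1.0})
        f = fit(spec, {"s": surf}, {}, cfg)
        assert abs(f.p_d - 1.0) < 0.1
        assert f.dic == pytest.approx(f.deviance_mean + f.p_d)

    def test_identical_seeds_give_identical_dic(self, grid10):
        rng = np.random.default_rng(2)
        y = rng.gamma(2.0, 1.0, 100)
        surf = o.SpeciesSurface(grid=grid10, values=y, family="gamma")
        spec = o.ModelSpec(species=("s",))
        cfg = InferenceConfig(seed=11, n_samples=60, max_opt_evals=60,
                              estimate_hyperparameter_uncertainty=False)
        f1 = fit(spec, {"s": surf}, {}, cfg)
        f2 = fit(spec, {"s": surf}, {}, cfg)
        assert dic(f1) == dic(f2)

    def test_structured_model_beats_intercept_on_structured_data(self, grid10):
        rng = np.random.default_rng(3)
        z = o.icar_field(grid10, sd=0.8, seed=4)
        y = rng.gamma(4.0, np.exp(0.5 + z) / 4.0)
        surf = o.SpeciesSurface(grid=grid10, values=y, family="gamma")
        cfg = InferenceConfig(seed=5, n_samples=60, max_opt_evals=80,
                              estimate_hyperparameter_uncertainty=False)
        spatial = fit(o.ModelSpec(species=("s",)), {"s": surf}, {}, cfg)
        null = fit(o.ModelSpec(species=("s",), include_spatial=False,
                               include_heterogeneity=False), {"s": surf}, {}, cfg)
        assert spatial.dic < null.dic


class TestFitContracts:
    def test_vanishing_heterogeneity_is_detected(self, grid10):
        rng = np.random.default_rng(6)
        z = o.icar_field(grid10, sd=0.7, seed=7)
        y = rng.gamma(3.0, np.exp(1.0 + z) / 3.0)   # no iid noise in truth
        surf = o.SpeciesSurface(grid=grid10, values=y, family="gamma")
        cfg = InferenceConfig(seed=8, n_samples=60, max_opt_evals=120,
                              estimate_hyperparameter_uncertainty=False)
        f = fit(o.ModelSpec(species=("s",)), {"s": surf}, {}, cfg)
        assert f.hyperparameters["tau_v"] > f.hyperparameters["tau_z"]

    def test_hurdle_family_requires_zeros(self, grid10):
        surf = o.SpeciesSurface(grid=grid10, values=np.ones(100),
                                family="hurdle-gamma")
        spec = o.ModelSpec(species=("s",), family={"s": "hurdle-gamma"})
        with pytest.raises(ValueError, match="zeros"):
            fit(spec, {"s": surf}, {}, InferenceConfig())

    def test_common_trend_requires_joint_fit(self, grid10):
        rng = np.random.default_rng(9)
        surf = o.SpeciesSurface(grid=grid10, values=rng.gamma(2, 1, 100),
                                family="gamma")
        cfg = InferenceConfig(seed=1, n_samples=40, max_opt_evals=40,
                              estimate_hyperparameter_uncertainty=False)
        f = fit(o.ModelSpec(species=("s",)), {"s": surf}, {}, cfg)
        with pytest.raises(ValueError, match="joint"):
            extract_common_trend(f)

    def test_identifiability_constraints_hold_after_fit(self, joint_fit):
        backend = joint_fit._backend
        resid = backend.md.constraints @ backend.x_mode
        assert np.max(np.abs(resid)) < 1e-8
        assert abs(joint_fit.cst.mean.sum()) < 1e-6

    def test_significance_flags_consistent_with_quantiles(self, joint_fit):
        cst = extract_common_trend(joint_fit)
        flags = (cst.q2_5 > 0) | (cst.q97_5 < 0)
        assert np.array_equal(cst.significant, flags)

    def test_delta_scaling_estimated_for_second_species(self, joint_fit):
        assert joint_fit.fields["predator"].spatial_scaling == 1.0
        assert joint_fit.fields["prey"].spatial_scaling == pytest.approx(
            joint_fit.hyperparameters["delta2"])


class TestSmoothRecovery:
    def test_known_quadratic_recovered_within_bands(self):
        grid = o.build_grid(25, 25)
        covs = {f.name: f for f in o.simulate_covariates(grid, ["NPP"], seed=10)}
        x = covs["NPP"].values
        rng = np.random.default_rng(11)
        fx = 0.25 - 0.35 * (x - 0.1) ** 2
        fx = fx - fx.mean()
        y = rng.gamma(4.0, np.exp(0.8 + fx) / 4.0)
        surf = o.SpeciesSurface(grid=grid, values=y, family="gamma")
        spec = o.ModelSpec(species=("s",), covariates=("NPP",),
                           include_spatial=False, include_heterogeneity=False)
        cfg = InferenceConfig(seed=12, n_samples=60, max_opt_evals=100)
        f = fit(spec, {"s": surf}, covs, cfg)
        sm = f.smooths["NPP"]
        truth = 0.25 - 0.35 * (sm.bin_mid - 0.1) ** 2
        # align levels with the fitted smooth's cell-weighted centering
        idx = np.clip(((x - sm.bin_edges[0]) /
                       (sm.bin_edges[-1] - sm.bin_edges[0]) * sm.n_bins).astype(int),
                      0, sm.n_bins - 1)
        weights = np.bincount(idx, minlength=sm.n_bins).astype(float)
        truth = truth - np.average(truth, weights=weights)
        inside = np.abs(sm.mean - truth) <= 1.96 * sm.sd
        assert inside.mean() >= 0.9


class TestPrediction:
    def test_identity_scenario_reproduces_present_surface(self, joint_fit, joint_synthetic):
        covmap, _, _ = joint_synthetic
        preds = predict_missing(joint_fit, covmap, n_samples=100, seed=21)
        for s in ("predator", "prey"):
            p, f_ = preds["present"][s].mean, preds["future"][s].mean
            rel_rmse = np.sqrt(np.mean((p - f_) ** 2)) / np.mean(p)
            assert rel_rmse <= 0.05
            assert np.array_equal(p, f_)   # identical covariates, shared draws

    def test_shifted_covariates_track_true_future_mean(self, joint_fit, joint_synthetic):
        covmap, truth, _ = joint_synthetic
        future = {k: o.shift_scenario(v, mean_shift=0.4,
                                      pattern_shift_fraction=0.2, seed=30 + i)
                  for i, (k, v) in enumerate(covmap.items())}
        preds = predict_missing(joint_fit, future, n_samples=150, seed=22)
        contrib = np.zeros(truth.z.size)
        for k, fn in truth.smooths.items():
            fx = fn(future[k].values)
            contrib += fx - fn(covmap[k].values).mean()
        for s in ("predator", "prey"):
            eta_true = truth.intercepts[s] + contrib + truth.delta[s] * truth.z
            mu_true = np.exp(eta_true)
            if s in truth.occupancy_intercepts:
                zeta = truth.occupancy_intercepts[s] + contrib + truth.delta[s] * truth.z
                mu_true = mu_true / (1 + np.exp(-zeta))
            r = np.corrcoef(preds["future"][s].mean, mu_true)[0, 1]
            assert r >= 0.8

    def test_extrapolated_cells_get_wider_intervals(self, joint_fit, joint_synthetic):
        covmap, _, _ = joint_synthetic
        future = {k: o.CovariateField(name=k, season=v.season, scenario="future",
                                      grid=v.grid, values=v.values.copy())
                  for k, v in covmap.items()}
        vals = future["PEA"].values
        boundary = np.argsort(vals)[-40:]           # push past the fitted range
        vals[boundary] = vals.max() + 2.0
        preds = predict_missing(joint_fit, future, n_samples=150, seed=23)
        surf = preds["future"]["predator"]
        rel_width = (surf.q97_5 - surf.q2_5) / np.maximum(surf.mean, 1e-12)
        interior = np.setdiff1d(np.arange(vals.size), boundary)
        assert rel_width[boundary].mean() > np.median(rel_width[interior])
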