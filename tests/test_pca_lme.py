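"""Calibration core: PCA, nested LME, RMSECV selection, cadaver-out CV."""

import numpy as np
import pandas as pd
import pytest

import cartigrade as cg
from cartigrade.pca_lme import (
    LeakageError,
    LmeSpec,
    fit_lme,
    fit_pca,
    kfold_rmsecv_scores,
    leave_one_cadaver_out,
    loco_iteration_models,
    predict_fixed,
    project,
)


def _nested_groups(n_cadavers=6, rows_per_knee=8, rng=None):
    rows = []
    for c in range(n_cadavers):
        for knee in ("left", "right"):
            for i in range(rows_per_knee):
                rows.append({"cadaver_id": f"C{c + 1}", "knee_side": knee,
                             "surface": ("femur", "tibia", "patella")[i % 3],
                             "site_index": i + 1})
    return pd.DataFrame(rows)


class TestPca:
    def test_rank_one_data(self, rng):
        direction = rng.normal(size=40)
        t = rng.normal(size=15)
        x = np.outer(t, direction) + 0.3
        pca = fit_pca(x, max_components=5)
        assert pca.explained_variance[0] == pytest.approx(1.0, abs=1e-9)
        assert pca.n_components <= 5

    def test_scores_uncorrelated(self, rng):
        x = rng.normal(size=(20, 50))
        pca = fit_pca(x, max_components=6)
        scores = project(pca, x)
        cov = np.cov(scores, rowvar=False)
        off_diag = cov - np.diag(np.diag(cov))
        np.testing.assert_allclose(off_diag, 0.0, atol=1e-8)

    def test_truncated_to_rank(self, rng):
        x = rng.normal(size=(4, 30))  # rank ≤ 3 after centering
        pca = fit_pca(x, max_components=12)
        assert pca.n_components <= 3

    def test_projection_identities(self, rng):
        x = rng.normal(size=(15, 25))
        pca = fit_pca(x, max_components=4)
        # training mean → zero scores
        np.testing.assert_allclose(project(pca, pca.mean_spectrum), 0.0, atol=1e-10)
        # mean + 2·(loading 1) → scores (2, 0, 0, 0)
        synthetic = pca.mean_spectrum + 2.0 * pca.loadings[0]
        np.testing.assert_allclose(project(pca, synthetic)[0],
                                   [2.0, 0.0, 0.0, 0.0], atol=1e-10)
        # loadings orthonormal
        np.testing.assert_allclose(pca.loadings @ pca.loadings.T,
                                   np.eye(pca.n_components), atol=1e-10)


class TestLme:
    def test_structural_reduction_to_ols(self, rng):
        groups = _nested_groups()
        X = rng.normal(size=(len(groups), 3))
        beta = np.array([1.0, 0.5, -0.8, 0.3])
        y = beta[0] + X @ beta[1:] + rng.normal(0, 0.4, len(groups))
        fit = fit_lme(X, groups, y, spec=LmeSpec(cadaver=False, knee=False, surface=False))
        import statsmodels.api as sm

        ols = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(fit.fe_params, np.asarray(ols.params), atol=1e-6)
        assert fit.variance_components == {}

    def test_zero_variance_data_close_to_ols(self, rng):
        # generative random-effect variances are zero: mixed fit agrees with
        # OLS statistically (estimated components shrink toward the boundary)
        groups = _nested_groups()
        X = rng.normal(size=(len(groups), 2))
        y = 2.0 + X @ [1.0, -0.5] + rng.normal(0, 0.3, len(groups))
        fit = fit_lme(X, groups, y)
        import statsmodels.api as sm

        ols = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(fit.fe_params, np.asarray(ols.params), atol=0.05)

    def test_recovers_coefficients_within_3se(self, rng):
        groups = _nested_groups(n_cadavers=8, rows_per_knee=10)
        X = rng.normal(size=(len(groups), 2))
        cadaver_fx = dict(zip(groups["cadaver_id"].unique(),
                              rng.normal(0, 0.5, groups["cadaver_id"].nunique())))
        beta = np.array([2.0, 1.2, -0.7])
        y = (beta[0] + X @ beta[1:]
             + groups["cadaver_id"].map(cadaver_fx).to_numpy()
             + rng.normal(0, 0.4, len(groups)))
        fit = fit_lme(X, groups, y)
        se = np.sqrt(np.diag(fit.fe_cov))
        assert np.all(np.abs(fit.fe_params - beta) < 3 * se)
        assert fit.variance_components.get("cadaver", 0.0) > 0.0

    def test_single_cadaver_warns(self, rng):
        groups = _nested_groups(n_cadavers=1, rows_per_knee=10)
        X = rng.normal(size=(len(groups), 2))
        y = X @ [1.0, 0.5] + rng.normal(0, 0.3, len(groups))
        with pytest.warns(UserWarning, match="single cadaver"):
            fit = fit_lme(X, groups, y)
        assert np.all(np.isfinite(fit.fe_params))


class TestRmsecvSelection:
    def test_pure_noise_rmsecv_near_sd(self, rng):
        groups = _nested_groups(n_cadavers=4, rows_per_knee=8)
        x = rng.normal(size=(len(groups), 30))
        y = rng.normal(0, 1.0, len(groups))  # independent of the spectra
        res = kfold_rmsecv_scores(groups, x, y, n_folds=5, max_components=3, seed=0)
        assert 0.75 <= res.rmsecv.min() <= 1.35
        # selection optimality invariant
        assert res.selected == res.component_counts[int(np.argmin(res.rmsecv))]

    def test_planted_three_component_signal(self, rng):
        groups = _nested_groups(n_cadavers=4, rows_per_knee=10)
        n = len(groups)
        basis = np.linalg.qr(rng.normal(size=(30, 3)))[0].T  # 3 orthonormal rows
        t = rng.normal(size=(n, 3)) * [3.0, 2.0, 1.5]
        x = t @ basis + rng.normal(0, 0.02, (n, 30))
        y = t @ [1.0, -0.8, 0.6] + rng.normal(0, 0.05, n)
        res = kfold_rmsecv_scores(groups, x, y, n_folds=5, max_components=6, seed=0)
        assert res.selected >= 3
        assert res.rmsecv.min() < 0.25  # near the noise floor

    def test_leave_one_location_out_special_case(self, rng):
        groups = _nested_groups(n_cadavers=2, rows_per_knee=3)
        x = rng.normal(size=(len(groups), 10))
        y = x[:, 0] + rng.normal(0, 0.1, len(groups))
        res = kfold_rmsecv_scores(groups, x, y, n_folds=len(groups),
                                  max_components=2, seed=0)
        assert res.selected in res.component_counts

    def test_too_few_locations_rejected(self, rng):
        groups = _nested_groups(n_cadavers=1, rows_per_knee=2)
        x = rng.normal(size=(len(groups), 5))
        with pytest.raises(ValueError):
            kfold_rmsecv_scores(groups, x, np.zeros(len(groups)), n_folds=50)


@pytest.fixture(scope="module")
def loco_run(tiny_cohort, snv_config):
    """One shared cadaver-out search: a signal-preserving config against a
    signal-destroying one (tiny-segment LSNV + 2nd derivative)."""
    ds, _ = tiny_cohort
    bad = cg.PreprocessConfig(scatter="lsnv", lsnv_window=2, sg_deriv=2, sg_window=15)
    search, models = leave_one_cadaver_out(
        ds, [snv_config, bad], "mankin", n_folds=3, max_components=3, seed=5,
        return_models=True)
    return ds, search, models, snv_config, bad


class TestLeaveOneCadaverOut:
    def test_one_iteration_per_cadaver(self, loco_run):
        ds, search, models, *_ = loco_run
        n_cadavers = ds.meta["cadaver_id"].nunique()
        for result in search.results:
            assert len(result.per_iteration) == n_cadavers
        assert len(models) == n_cadavers

    def test_dominant_config_selected(self, loco_run):
        _, search, _, good, bad = loco_run
        good_rho = search.result_for(good).median_test_rho()
        bad_rho = search.result_for(bad).median_test_rho()
        assert good_rho > bad_rho
        assert search.selected == good

    def test_strong_signal_median_rho(self, loco_run):
        _, search, *_ = loco_run
        assert search.result_for(search.selected).median_test_rho() > 0.5

    def test_selected_components_attain_curve_minimum(self, loco_run):
        _, _, models, *_ = loco_run
        for _, model in models:
            assert model.rmsecv == pytest.approx(float(model.rmsecv_curve.min()))

    def test_no_leakage_from_heldout_references(self, tiny_cohort, snv_config):
        """Perturbing the held-out cadaver's reference values must leave the
        trained model bit-identical."""
        ds, _ = tiny_cohort
        models_clean = loco_iteration_models(ds, snv_config, "mankin",
                                             n_folds=3, max_components=3, seed=5)
        holdout = models_clean[0][0]
        refs2 = ds.references.copy()
        mask = refs2["cadaver_id"].astype(str) == holdout
        refs2.loc[mask, "mankin"] = (refs2.loc[mask, "mankin"] * 0.5 + 1.7).clip(0, 13)
        ds2 = cg.SpectralDataset(grid=ds.grid, meta=ds.meta.copy(),
                                 absorbance=ds.absorbance.copy(), references=refs2,
                                 provenance=dict(ds.provenance))
        models_pert = loco_iteration_models(ds2, snv_config, "mankin",
                                            n_folds=3, max_components=3, seed=5)
        m1 = dict(models_clean)[holdout]
        m2 = dict(models_pert)[holdout]
        assert np.array_equal(m1.lme.fe_params, m2.lme.fe_params)
        assert np.array_equal(m1.pca.loadings, m2.pca.loadings)
        assert m1.rmsecv == m2.rmsecv
        assert m1.n_components_selected == m2.n_components_selected


class TestPredictFixed:
    def test_zero_scores_give_intercept(self, loco_run):
        _, _, models, *_ = loco_run
        model = models[0][1]
        pred = model.lme.predict_fixed(np.zeros((1, model.n_components_selected)))
        assert pred[0] == pytest.approx(model.lme.fe_params[0])

    def test_training_cadaver_raises_leakage(self, loco_run):
        ds, _, models, *_ = loco_run
        holdout, model = models[0]
        training = ds.subset((ds.meta["cadaver_id"].astype(str) != holdout).to_numpy())
        with pytest.raises(LeakageError):
            predict_fixed(model, training)

    def test_unseen_cadaver_id_irrelevant(self, loco_run):
        ds, _, models, *_ = loco_run
        holdout, model = models[0]
        held = ds.subset((ds.meta["cadaver_id"].astype(str) == holdout).to_numpy())
        renamed_meta = held.meta.copy()
        renamed_meta["cadaver_id"] = "ZZZ"
        renamed = cg.SpectralDataset(grid=held.grid, meta=renamed_meta,
                                     absorbance=held.absorbance,
                                     references=held.references,
                                     provenance={"reference_missing_ok": True})
        p1 = predict_fixed(model, held)["prediction"].to_numpy()
        p2 = predict_fixed(model, renamed)["prediction"].to_numpy()
        np.testing.assert_array_equal(p1, p2)

    def test_model_json_round_trip(self, loco_run):
        import json

        from cartigrade.pca_lme import CalibratedModel

        ds, _, models, *_ = loco_run
        holdout, model = models[0]
        doc = json.loads(json.dumps(model.to_dict()))
        back = CalibratedModel.from_dict(doc)
        held = ds.subset((ds.meta["cadaver_id"].astype(str) == holdout).to_numpy())
        np.testing.assert_allclose(back.predict_matrix(held.absorbance, held.grid),
                                   model.predict_matrix(held.absorbance, held.grid),
                                   rtol=1e-12)
        assert back.preprocess == model.preprocess

    def test_predictions_track_truth_on_heldout(self, loco_run, tiny_cohort):
        ds, _, models, *_ = loco_run
        _, truth = tiny_cohort
        holdout, model = models[0]
        held = ds.select_setting("in_vitro").average_replicates()
        held = held.subset((held.meta["cadaver_id"].astype(str) == holdout).to_numpy())
        pred = model.predict_matrix(held.absorbance, held.grid)
        y = held.reference_frame()["mankin"].to_numpy()
        rho, _ = cg.spearman(pred, y)
        assert rho > 0.0
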