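"""Engine contracts: fitting behaviour, prediction purity, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from gridsdm import (
    FittedSDM,
    NicheSpec,
    fit_gam,
    fit_glm,
    fit_maxent,
    fit_rf,
    predict_probabilities,
    roc_score,
    simulate_species,
)
from gridsdm.engines import _make_term, _term_columns
from gridsdm.errors import ConfigurationError, DataError, ValidationError
from gridsdm.tables import PredictorMeta, PredictorTable


def _table(columns: dict, kinds: dict | None = None, levels: dict | None = None) -> PredictorTable:
    n = len(next(iter(columns.values())))
    df = pd.DataFrame({"cell_id": np.arange(n), **columns})
    kinds = kinds or {}
    levels = levels or {}
    meta = {
        k: PredictorMeta(k, "climate", kinds.get(k, "continuous"), levels=levels.get(k))
        for k in columns
    }
    return PredictorTable(df, meta)


class TestGLM:
    def test_intercept_only_truth_returns_prevalence(self, rng):
        n = 800
        t = _table({"xv": rng.standard_normal(n)})
        y = (rng.random(n) < 0.3).astype(int)
        model = fit_glm(t, y, ["xv"], seed=1)
        assert model.selected_predictors == []
        p = predict_probabilities(model, t).p
        # closed-form binomial MLE: constant probability = sample prevalence
        np.testing.assert_allclose(p, y.mean(), atol=1e-6)

    def test_coefficient_recovery_within_three_se(self, rng):
        n = 3000
        x = rng.standard_normal(n)
        p = expit(-1.0 + 1.5 * x)
        y = (rng.random(n) < p).astype(int)
        t = _table({"xv": x})
        model = fit_glm(t, y, ["xv"], seed=2)
        assert model.selected_predictors == ["xv"]
        b0, b1 = model.parameters["coef"]
        se = np.sqrt(3.0 / n)  # generous bound on either standard error
        assert abs(b0 - (-1.0)) < 3 * max(se, 0.08)
        assert abs(b1 - 1.5) < 3 * max(se, 0.08)

    def test_pure_noise_predictor_usually_excluded(self, rng):
        excluded = 0
        trials = 50
        for _ in range(trials):
            n = 400
            x = rng.standard_normal(n)
            noise = rng.standard_normal(n)
            y = (rng.random(n) < expit(-0.5 + 1.2 * x)).astype(int)
            t = _table({"xv": x, "noise": noise})
            model = fit_glm(t, y, ["xv", "noise"], seed=3)
            if "noise" not in model.selected_predictors:
                excluded += 1
        assert excluded >= 0.8 * trials

    def test_separation_triggers_ridge_fallback(self):
        x = np.linspace(-1, 1, 40)
        y = (x > 0).astype(int)
        t = _table({"xv": x})
        with pytest.warns(RuntimeWarning, match="separation"):
            model = fit_glm(t, y, ["xv"], seed=4)
        assert model.parameters["ridge_fallback"]
        p = predict_probabilities(model, t).p
        assert ((0 <= p) & (p <= 1)).all()

    def test_calibration_ranges_recorded_for_selected(self, rng):
        n = 500
        x = rng.standard_normal(n)
        y = (rng.random(n) < expit(2.0 * x)).astype(int)
        t = _table({"xv": x})
        model = fit_glm(t, y, ["xv"], seed=5)
        lo, hi = model.calibration_ranges["xv"]
        assert lo == x.min() and hi == x.max()


class TestGAM:
    def test_spline_term_has_exactly_four_columns(self, small_grid):
        term = _make_term("AnnTMean", small_grid, smooth=True)
        cols = _term_columns(term, small_grid)
        assert term["type"] == "spline"
        assert cols.shape == (small_grid.n_cells, 4)

    def test_few_distinct_values_demoted_to_linear(self):
        t = _table({"xv": np.tile([1.0, 2.0, 3.0], 30)})
        with pytest.warns(RuntimeWarning, match="demoted"):
            term = _make_term("xv", t, smooth=True)
        assert term["type"] == "linear"

    def test_captures_unimodal_response_linear_glm_misses(self, rng):
        n = 1200
        x = rng.uniform(-2, 2, n)
        p = expit(1.5 - 2.0 * x**2)  # symmetric niche: no linear signal
        y = (rng.random(n) < p).astype(int)
        t = _table({"xv": x})
        gam = fit_gam(t, y, ["xv"], seed=6)
        glm = fit_glm(t, y, ["xv"], seed=6)
        auc_gam = roc_score(predict_probabilities(gam, t).p, y)
        auc_glm = roc_score(predict_probabilities(glm, t).p, y)
        assert auc_gam > auc_glm + 0.1


class TestRF:
    def test_determinism_given_seed(self, rng):
        n = 300
        x = rng.standard_normal(n)
        z = rng.standard_normal(n)
        y = (rng.random(n) < expit(1.5 * x)).astype(int)
        t = _table({"xv": x, "zv": z})
        a = fit_rf(t, y, ["xv", "zv"], seed=7, n_trees=100)
        b = fit_rf(t, y, ["xv", "zv"], seed=7, n_trees=100)
        np.testing.assert_array_equal(predict_probabilities(a, t).p, predict_probabilities(b, t).p)

    def test_perfect_separator_gives_calibration_auc_one(self):
        x = np.linspace(0, 1, 200)
        y = (x > 0.5).astype(int)
        t = _table({"xv": x})
        model = fit_rf(t, y, ["xv"], seed=8, n_trees=100)
        assert roc_score(predict_probabilities(model, t).p, y) == 1.0

    def test_overfits_calibration_relative_to_validation(self, rng):
        gaps = 0
        for rep in range(5):
            n = 400
            x = rng.standard_normal(n)
            y = (rng.random(n) < expit(0.8 * x)).astype(int)
            t = _table({"xv": x})
            cal = t.subset_cells(np.arange(0, 280))
            val = t.subset_cells(np.arange(280, 400))
            model = fit_rf(cal, y[:280], ["xv"], seed=rep, n_trees=100)
            cal_auc = roc_score(predict_probabilities(model, cal).p, y[:280])
            val_auc = roc_score(predict_probabilities(model, val).p, y[280:])
            gaps += cal_auc >= val_auc
        assert gaps >= 4

    def test_invalid_tree_count_rejected(self, rng):
        t = _table({"xv": rng.standard_normal(20)})
        with pytest.raises(ConfigurationError):
            fit_rf(t, np.array([0, 1] * 10), ["xv"], n_trees=0)


class TestMaxEnt:
    def test_no_features_yields_uniform_suitability(self, rng):
        n = 200
        t = _table({"xv": rng.standard_normal(n)})
        y = np.zeros(n, dtype=int)
        y[rng.choice(n, 40, replace=False)] = 1
        model = fit_maxent(t, y, [], seed=9)
        np.testing.assert_allclose(predict_probabilities(model, t).p, 1.0)

    def test_infinite_regularization_shrinks_to_uniform(self, rng):
        n = 300
        x = rng.standard_normal(n)
        y = (rng.random(n) < expit(2 * x)).astype(int)
        t = _table({"xv": x})
        model = fit_maxent(t, y, ["xv"], seed=10, reg=1e9)
        assert np.allclose(model.parameters["weights"], 0.0)
        np.testing.assert_allclose(predict_probabilities(model, t).p, 1.0)

    def test_kkt_feature_expectations_within_l1_tolerance(self, rng):
        n = 600
        x = rng.standard_normal(n)
        y = (rng.random(n) < expit(1.0 + 2.0 * x - 1.0 * x**2)).astype(int)
        t = _table({"xv": x})
        reg = 0.5
        model = fit_maxent(t, y, ["xv"], seed=11, reg=reg)
        w = np.asarray(model.parameters["weights"])
        spec = model.parameters["feature_spec"]["xv"]
        z = (x - spec["mean"]) / spec["sd"]
        F = np.column_stack([z, z**2])
        eta = F @ w
        gibbs = np.exp(eta - eta.max())
        gibbs /= gibbs.sum()
        n_pres = y.sum()
        for j in range(2):
            e_gibbs = float(F[:, j] @ gibbs)
            e_pres = float(F[y == 1, j].mean())
            assert abs(e_gibbs - e_pres) <= reg / n_pres + 1e-4

    def test_affine_rescaling_invariance(self, rng):
        n = 400
        x = rng.standard_normal(n)
        y = (rng.random(n) < expit(1.5 * x)).astype(int)
        t1 = _table({"xv": x})
        t2 = _table({"xv": 10.0 * x + 5.0})
        m1 = fit_maxent(t1, y, ["xv"], seed=12)
        m2 = fit_maxent(t2, y, ["xv"], seed=12)
        np.testing.assert_allclose(predict_probabilities(m1, t1).p, predict_probabilities(m2, t2).p, atol=1e-5)

    def test_too_few_presences_rejected(self, rng):
        t = _table({"xv": rng.standard_normal(50)})
        y = np.zeros(50, dtype=int)
        y[:5] = 1
        with pytest.raises(DataError, match="presence"):
            fit_maxent(t, y, ["xv"])

    def test_degenerate_support_rejected(self):
        x = np.array([1.0] * 15 + list(np.linspace(0, 1, 30)))
        y = np.array([1] * 15 + [0] * 30)
        t = _table({"xv": x})
        with pytest.raises(DataError, match="degenerate"):
            fit_maxent(t, y, ["xv"])


class TestPredictProbabilities:
    def test_hand_computed_logistic_values(self):
        t = _table({"xv": np.array([0.0, 1.0, 2.0])})
        model = FittedSDM("GLM", "sp", ["xv"],
                          {"terms": [{"type": "linear", "name": "xv"}], "coef": [-1.0, 2.0]},
                          None, 0, 0, {"xv": (0.0, 2.0)})
        p = predict_probabilities(model, t).p
        np.testing.assert_allclose(p, expit(np.array([-1.0, 1.0, 3.0])), atol=1e-12)

    def test_missing_predictor_rejected(self):
        t = _table({"other": np.arange(3.0)})
        model = FittedSDM("GLM", "sp", ["xv"],
                          {"terms": [{"type": "linear", "name": "xv"}], "coef": [0.0, 1.0]},
                          None, 0, 0, {})
        with pytest.raises(ValidationError, match="lacks"):
            predict_probabilities(model, t)

    def test_unseen_categorical_level_rejected(self, rng):
        n = 60
        t = _table({"r": np.repeat([1, 2, 3], 20)}, kinds={"r": "categorical"}, levels={"r": (1, 2, 3)})
        y = np.tile([0, 1], 30)
        model = fit_glm(t, y, ["r"], seed=13)
        t_bad = _table({"r": np.repeat([1, 2, 9], 20)}, kinds={"r": "categorical"}, levels={"r": (1, 2, 9)})
        if "r" in model.selected_predictors:
            with pytest.raises(ValidationError, match="unseen"):
                predict_probabilities(model, t_bad)

    def test_cell_order_permutation_permutes_output(self, rng):
        n = 100
        x = rng.standard_normal(n)
        y = (rng.random(n) < expit(x)).astype(int)
        t = _table({"xv": x})
        model = fit_glm(t, y, ["xv"], seed=14)
        perm = rng.permutation(n)
        shuffled = t.subset_cells(t.cell_ids[perm])
        p_direct = predict_probabilities(model, t).p[perm]
        p_shuffled = predict_probabilities(model, shuffled).p
        np.testing.assert_allclose(p_direct, p_shuffled, atol=1e-15)

    def test_probabilities_within_unit_interval_all_engines(self, small_grid, rng):
        occ, _ = simulate_species(small_grid, [NicheSpec("s", linear_coefs={"AnnTMean": 0.5}, intercept=-4.0)], seed=15)
        y = occ.presence("s")
        offered = ["AnnTMean", "Strahler"]
        for fitter, kwargs in [(fit_glm, {}), (fit_gam, {}), (fit_rf, {"n_trees": 50}), (fit_maxent, {})]:
            model = fitter(small_grid, y, offered, seed=16, **kwargs)
            p = predict_probabilities(model, small_grid).p
            assert ((0.0 <= p) & (p <= 1.0)).all()
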