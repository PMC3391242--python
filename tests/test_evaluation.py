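"""Splits, thresholding, scoring, and permutation importance."""

import numpy as np
import pytest

from gridsdm import (
    FittedSDM,
    binary_metrics,
    choose_threshold,
    classify_performance,
    make_splits,
    permutation_importance,
    roc_score,
)
from gridsdm.errors import ConfigurationError, UndefinedMetricError, ValidationError
from gridsdm.tables import PredictorMeta, PredictorTable
import pandas as pd


def _exhaustive_threshold(p, truth):
    """Independent scan over all unique candidate thresholds."""
    best = None
    for t in np.unique(p):
        pred = (p >= t).astype(int)
        tp = ((pred == 1) & (truth == 1)).sum()
        fn = ((pred == 0) & (truth == 1)).sum()
        tn = ((pred == 0) & (truth == 0)).sum()
        fp = ((pred == 1) & (truth == 0)).sum()
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        key = (-min(sens, spec), abs(sens - spec), t)
        if best is None or key < best[0]:
            best = (key, t)
    return best[1]


def _pair_count_auc(p, truth):
    pos = p[truth == 1]
    neg = p[truth == 0]
    wins = ties = 0
    for a in pos:
        for b in neg:
            if a > b:
                wins += 1
            elif a == b:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestMakeSplits:
    def test_stated_sizes_and_partition(self):
        scheme = make_splits(np.arange(1000), frac=0.7, reps=10, seed=1)
        assert scheme.n_repetitions == 10
        for cal, val in scheme:
            assert len(cal) == 700 and len(val) == 300
            assert set(cal).isdisjoint(val)
            assert set(cal) | set(val) == set(range(1000))

    def test_determinism_and_seed_sensitivity(self):
        a = make_splits(np.arange(100), seed=5)
        b = make_splits(np.arange(100), seed=5)
        assert a == b
        for s in range(10):
            assert make_splits(np.arange(100), seed=s) != make_splits(np.arange(100), seed=s + 1)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ConfigurationError):
            make_splits(np.arange(100), frac=1.0)


class TestChooseThreshold:
    def test_separable_case(self):
        t, sens, spec = choose_threshold(np.array([0.2, 0.3, 0.7, 0.8]), np.array([0, 0, 1, 1]))
        assert t == 0.7 and sens == 100.0 and spec == 100.0

    def test_tie_breaking_by_sens_spec_balance(self):
        # min(sens,spec)=0.5 at t in {0.4, 0.6, 0.9}; |sens-spec|=0 only at 0.6
        t, sens, spec = choose_threshold(np.array([0.1, 0.6, 0.4, 0.9]), np.array([0, 0, 1, 1]))
        assert t == 0.6 and sens == 50.0 and spec == 50.0

    def test_degenerate_constant_probabilities_warn(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            t, _, _ = choose_threshold(np.full(6, 0.4), np.array([0, 1, 0, 1, 0, 1]))
        assert t == 0.4

    def test_matches_exhaustive_scan_on_random_instances(self, rng):
        for _ in range(500):
            n = rng.integers(8, 40)
            p = np.round(rng.random(n), 2)  # coarse grid forces ties
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n) or len(np.unique(p)) == 1:
                continue
            t, _, _ = choose_threshold(p, y)
            assert t == _exhaustive_threshold(p, y)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            choose_threshold(np.array([0.1, 0.9]), np.array([1, 1]))


class TestBinaryMetrics:
    def test_exact_and_inverted_predictions(self):
        y = np.array([1, 0, 1, 0])
        assert binary_metrics(y, y) == (100.0, 100.0)
        assert binary_metrics(1 - y, y) == (0.0, 0.0)

    def test_half_right_in_each_class(self):
        assert binary_metrics(np.array([1, 1, 0, 0]), np.array([1, 0, 1, 0])) == (50.0, 50.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            binary_metrics(np.array([1]), np.array([1, 0]))


class TestRocScore:
    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(1000):
            n = rng.integers(6, 25)
            p = rng.integers(0, 5, size=n) / 4.0
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                continue
            assert abs(roc_score(p, y) - _pair_count_auc(p, y)) < 1e-12

    @pytest.mark.parametrize(
        "roc,band",
        [(0.55, "fail"), (0.65, "poor"), (0.75, "fair"), (0.85, "good"), (0.95, "excellent"),
         (0.6, "poor"), (0.7, "fair"), (0.8, "good"), (0.9, "excellent"), (1.0, "excellent"),
         (0.3, "fail")],
    )
    def test_performance_bands(self, roc, band):
        assert classify_performance(roc) == band


def _linear_glm(coefs: dict, intercept: float, species="sp") -> FittedSDM:
    """Hand-built additive-linear model: deterministic, no fitting involved."""
    names = list(coefs)
    return FittedSDM(
        engine="GLM",
        species_code=species,
        selected_predictors=names,
        parameters={"terms": [{"type": "linear", "name": n} for n in names],
                    "coef": [intercept] + [coefs[n] for n in names]},
        threshold=0.5,
        repetition_id=0,
        seed=0,
        calibration_ranges={n: (-5.0, 5.0) for n in names},
    )


def _table(columns: dict) -> PredictorTable:
    n = len(next(iter(columns.values())))
    df = pd.DataFrame({"cell_id": np.arange(n), **columns})
    return PredictorTable(df, {k: PredictorMeta(k, "climate", "continuous") for k in columns})


class TestPermutationImportance:
    def test_single_predictor_model_gets_all_importance(self, rng):
        t = _table({"a": rng.standard_normal(300), "b": rng.standard_normal(300)})
        model = _linear_glm({"a": 1.0}, 0.0)
        prof = permutation_importance(model, t, n_perm=5, seed=1, predictors=["a", "b"])
        assert prof.pi["a"] == 100.0
        assert prof.pi["b"] == 0.0  # unused predictor leaves predictions unchanged

    def test_profile_sums_to_hundred(self, rng):
        t = _table({"a": rng.standard_normal(300), "b": rng.standard_normal(300)})
        model = _linear_glm({"a": 1.0, "b": 0.5}, -0.2)
        prof = permutation_importance(model, t, n_perm=20, seed=2)
        assert prof.total() == pytest.approx(100.0, abs=1e-6)
        assert all(v >= 0 for v in prof.pi.values())

    def test_constant_predictions_flagged_undefined(self, rng):
        t = _table({"a": rng.standard_normal(50)})
        model = _linear_glm({}, 0.3)
        model.selected_predictors = []
        with pytest.warns(RuntimeWarning, match="constant"):
            prof = permutation_importance(model, t, n_perm=3, seed=0, predictors=["a"])
        assert not prof.defined

    def test_determinism(self, rng):
        t = _table({"a": rng.standard_normal(200), "b": rng.standard_normal(200)})
        model = _linear_glm({"a": 0.8, "b": 0.8}, 0.0)
        p1 = permutation_importance(model, t, n_perm=10, seed=7)
        p2 = permutation_importance(model, t, n_perm=10, seed=7)
        assert p1.pi == p2.pi
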