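"""Predictor screening: univariate ROC, correlation capping, PCA, relevance rule."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from gridsdm import (
    PredictorMeta,
    PredictorTable,
    correlation_filter,
    pca_representatives,
    select_relevant_predictors,
    univariate_auc,
)
from gridsdm.errors import ConfigurationError, UndefinedMetricError, ValidationError
from gridsdm.selection import association_matrix


def _numeric_table(columns: dict) -> PredictorTable:
    n = len(next(iter(columns.values())))
    df = pd.DataFrame({"cell_id": np.arange(n), **columns})
    meta = {k: PredictorMeta(k, "climate", "continuous") for k in columns}
    return PredictorTable(df, meta)


class TestUnivariateAuc:
    def test_perfect_separation(self):
        assert univariate_auc(np.array([1, 2, 3, 4, 5, 6]), np.array([0, 0, 0, 1, 1, 1])) == 1.0

    def test_constant_values_score_half(self):
        assert univariate_auc(np.full(10, 3.0), np.array([0, 1] * 5)) == 0.5

    def test_pair_enumeration_example(self):
        # pairs (pos, neg): (1,2) win 0, (1,3) loss, (4,2) win, (4,3) win -> 2/4... folded stays 0.5
        assert univariate_auc(np.array([2, 1, 3, 4]), np.array([0, 1, 0, 1])) == 0.5

    def test_orientation_correction(self):
        descending = univariate_auc(np.array([6, 5, 4, 3, 2, 1]), np.array([0, 0, 0, 1, 1, 1]))
        assert descending == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            univariate_auc(np.arange(4.0), np.ones(4))

    def test_matches_mann_whitney_on_random_instances(self, rng):
        for _ in range(1000):
            n = rng.integers(10, 40)
            v = rng.integers(0, 6, size=n).astype(float)  # heavy ties
            y = rng.integers(0, 2, size=n)
            if y.sum() in (0, n):
                continue
            u = mannwhitneyu(v[y == 1], v[y == 0], alternative="two-sided").statistic
            auc = u / (y.sum() * (n - y.sum()))
            assert abs(univariate_auc(v, y) - max(auc, 1 - auc)) < 1e-12


class TestCorrelationFilter:
    def test_lower_ranked_member_of_a_redundant_pair_dropped(self, rng):
        x = rng.standard_normal(500)
        t = _numeric_table({"a": x + 0.2 * rng.standard_normal(500), "b": x})
        kept, dropped = correlation_filter(t, {"a": 0.70, "b": 0.60}, cap=0.75)
        assert kept == ["a"]
        assert dropped[0][1] == "b"

    def test_compliant_set_unchanged(self, rng):
        t = _numeric_table({"a": rng.standard_normal(500), "b": rng.standard_normal(500)})
        kept, dropped = correlation_filter(t, {"a": 0.6, "b": 0.7}, cap=0.75)
        assert kept == ["a", "b"] and dropped == []

    def test_chain_against_exhaustive_subset_oracle(self, rng):
        # r(A,B)~0.8, r(B,C)~0.8, r(A,C) small, with B ranked lowest -> {A, C}
        z = rng.standard_normal(4000)
        a = z + 0.72 * rng.standard_normal(4000)
        c = -z + 0.72 * rng.standard_normal(4000)
        b = (a - c) / 2 + 0.35 * rng.standard_normal(4000)
        t = _numeric_table({"A": a, "B": b, "C": c})
        ranking = {"A": 0.70, "B": 0.55, "C": 0.68}
        assoc = association_matrix(t)
        assert assoc.loc["A", "B"] >= 0.75 and assoc.loc["B", "C"] >= 0.75 and assoc.loc["A", "C"] < 0.75
        kept, _ = correlation_filter(t, ranking, cap=0.75)
        # oracle: the admissible subset with maximal summed ranking
        best, best_score = None, -1.0
        for k in range(1, 4):
            for subset in itertools.combinations(["A", "B", "C"], k):
                if all(assoc.loc[p, q] < 0.75 for p, q in itertools.combinations(subset, 2)):
                    score = sum(ranking[p] for p in subset)
                    if score > best_score:
                        best, best_score = sorted(subset), score
        assert kept == best == ["A", "C"]

    def test_output_always_satisfies_cap(self, rng):
        for trial in range(10):
            base = rng.standard_normal((300, 3))
            mix = rng.standard_normal((3, 6))
            X = base @ mix + 0.4 * rng.standard_normal((300, 6))
            names = [f"p{i}" for i in range(6)]
            t = _numeric_table(dict(zip(names, X.T)))
            ranking = {n: float(r) for n, r in zip(names, rng.random(6))}
            kept, _ = correlation_filter(t, ranking, cap=0.75)
            sub = association_matrix(t, kept).to_numpy()
            np.fill_diagonal(sub, 0.0)
            assert sub.max() < 0.75

    def test_invalid_cap_rejected(self, small_grid):
        with pytest.raises(ConfigurationError):
            correlation_filter(small_grid, {p: 0.5 for p in small_grid.predictors}, cap=1.5)

    def test_mixed_type_associations_in_range(self, small_grid):
        assoc = association_matrix(small_grid, ["AnnTMean", "RtypMost", "Lusemax", "Strahler"])
        vals = assoc.to_numpy()
        assert ((vals >= 0) & (vals <= 1 + 1e-12)).all()


class TestPcaRepresentatives:
    def test_single_predictor_identity(self, small_grid):
        reps, frac = pca_representatives(small_grid, ["AnnPMean"])
        assert reps == ["AnnPMean"] and frac == [1.0]

    def test_duplicated_columns_analytic_eigenstructure(self, rng):
        x = rng.standard_normal(400)
        z = rng.standard_normal(400)
        t = _numeric_table({"dup1": x, "dup2": x.copy(), "indep": z})
        reps, frac = pca_representatives(t, ["dup1", "dup2", "indep"], n_components=2)
        # correlation matrix eigenvalues are ~(2, 1, 0): PC1 carries the duplicated pair
        assert reps[0] in {"dup1", "dup2"}
        assert reps[1] == "indep"
        assert frac[0] == pytest.approx(2 / 3, abs=0.05)
        assert frac[1] == pytest.approx(1 / 3, abs=0.05)

    def test_constant_column_rejected(self):
        t = _numeric_table({"a": np.ones(20), "b": np.arange(20.0)})
        with pytest.raises(ValidationError, match="constant"):
            pca_representatives(t, ["a", "b"])


class TestRelevanceRule:
    # printed summary rows: (roc, pi, n_selected) out of 38 species
    @pytest.mark.parametrize(
        "name,roc,pi,n_sel,passed,relevant",
        [
            ("AnnTMean", 0.66, 7.6, 26, 3, True),
            ("Lusemax", 0.55, 1.7, 26, 1, False),
            ("TWetQuar", 0.66, 1.8, 18, 1, False),
        ],
    )
    def test_published_example_rows(self, name, roc, pi, n_sel, passed, relevant):
        rows = pd.DataFrame({"roc": [roc], "pi": [pi], "n_selected": [n_sel]}, index=[name])
        out = select_relevant_predictors(rows, n_species=38)
        assert out.loc[name, "criteria_passed"] == passed
        assert bool(out.loc[name, "relevant"]) is relevant

    def test_half_count_uses_ceiling(self):
        rows = pd.DataFrame({"roc": [0.5, 0.5], "pi": [9.0, 9.0], "n_selected": [2, 1]}, index=["a", "b"])
        out = select_relevant_predictors(rows, n_species=3)  # ceil(3/2) = 2
        assert bool(out.loc["a", "relevant"]) is True  # pi + count
        assert bool(out.loc["b", "relevant"]) is False  # pi only

    def test_missing_columns_rejected(self):
        with pytest.raises(ValidationError):
            select_relevant_predictors(pd.DataFrame({"roc": [0.7]}), n_species=10)
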