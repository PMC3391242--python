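"""Predictor screening and the basic-set selection rules.

The candidate predictor pool is reduced in three moves: PCA representatives
inside thematically related groups, greedy elimination of pairs whose
association exceeds a cap (0.75 by default), and a three-criteria relevance
rule combining univariate discrimination (mean ROC >= 0.65), multivariate
permutation importance (mean PI >= 5%), and the number of species whose
models retain the predictor (at least half).  A predictor passing at least
two of the three criteria is kept as relevant.

Associations are Pearson correlations between numeric predictors, the
correlation ratio (eta) between a categorical and a numeric predictor, and
Cramer's V between two categoricals — the standard mixed-type analogues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigurationError, UndefinedMetricError, ValidationError
from .tables import PredictorTable

__all__ = [
    "univariate_auc",
    "association_matrix",
    "correlation_filter",
    "pca_representatives",
    "select_relevant_predictors",
    "SelectionReport",
]


def univariate_auc(values: np.ndarray, truth: np.ndarray) -> float:
    """Orientation-corrected rank AUC of a single predictor.

    Midrank tie handling (the normalized Mann-Whitney U statistic); the
    result is folded to ``max(auc, 1 - auc)`` so predictors discriminating in
    descending direction score symmetrically.
    """
    values = np.asarray(values, dtype=float)
    truth = np.asarray(truth)
    if values.shape != truth.shape:
        raise ValidationError("values and truth must have equal length")
    n1 = int(truth.sum())
    n0 = len(truth) - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError("AUC undefined: truth contains a single class")
    ranks = rankdata(values)
    auc = (ranks[truth == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return float(max(auc, 1.0 - auc))


# ------------------------------------------------------------- mixed association
def _cramers_v(a: np.ndarray, b: np.ndarray) -> float:
    tab = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy().astype(float)
    n = tab.sum()
    expected = np.outer(tab.sum(1), tab.sum(0)) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.nansum(np.where(expected > 0, (tab - expected) ** 2 / expected, 0.0))
    r, k = tab.shape
    denom = n * (min(r, k) - 1)
    return float(np.sqrt(chi2 / denom)) if denom > 0 else 0.0

def _correlation_ratio(cat: np.ndarray, num: np.ndarray) -> float:
    num = np.asarray(num, dtype=float)
    grand = num.mean()
    ss_between = 0.0
    for level in np.unique(cat):
        sub = num[cat == level]
        ss_between += len(sub) * (sub.mean() - grand) ** 2
    ss_total = ((num - grand) ** 2).sum()
    return float(np.sqrt(ss_between / ss_total)) if ss_total > 0 else 0.0


def association_matrix(preds: PredictorTable, names: Sequence[str] | None = None) -> pd.DataFrame:
    """Symmetric |association| matrix over mixed-type predictors."""
    names = list(names) if names is not None else preds.predictors
    kinds = {n: preds.meta[n].kind for n in names}
    out = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if kinds[a] == "categorical" and kinds[b] == "categorical":
                r = _cramers_v(preds.values(a), preds.values(b))
            elif kinds[a] == "categorical":
                r = _correlation_ratio(preds.values(a), preds.values(b))
            elif kinds[b] == "categorical":
                r = _correlation_ratio(preds.values(b), preds.values(a))
            else:
                r = abs(np.corrcoef(preds.values(a).astype(float), preds.values(b).astype(float))[0, 1])
            out.loc[a, b] = out.loc[b, a] = r
    return out


def correlation_filter(
    preds: PredictorTable,
    ranking: Mapping[str, float],
    cap: float = 0.75,
    names: Sequence[str] | None = None,
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Greedy elimination until all retained pairwise associations are < cap.

    While a violating pair exists, the strongest-associated pair is resolved
    by dropping its lower-ranked member (rank = univariate ROC by
    convention); rank ties keep the alphabetically first name.  Returns the
    kept names and the ``(kept, dropped, r)`` audit trail.
    """
    if not 0 < cap <= 1:
        raise ConfigurationError("cap must lie in (0, 1]")
    names = list(names) if names is not None else preds.predictors
    missing = set(names) - set(ranking)
    if missing:
        raise ValidationError(f"ranking missing for predictors: {sorted(missing)}")
    assoc = association_matrix(preds, names)
    kept = sorted(names)
    dropped: list[tuple[str, str, float]] = []
    while True:
        worst, worst_r = None, cap
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                r = assoc.loc[a, b]
                if r >= worst_r:
                    worst, worst_r = (a, b), r
        if worst is None:
            break
        a, b = worst
        # drop the lower-ranked member; on a tie keep the alphabetically first
        if ranking[a] == ranking[b]:
            keep_name, drop_name = min(a, b), max(a, b)
        elif ranking[a] < ranking[b]:
            keep_name, drop_name = b, a
        else:
            keep_name, drop_name = a, b
        kept.remove(drop_name)
        dropped.append((keep_name, drop_name, float(worst_r)))
    return kept, dropped


def pca_representatives(
    preds: PredictorTable,
    group: Sequence[str],
    n_components: int = 2,
) -> tuple[list[str], list[float]]:
    """Representative predictors of a thematic group via PCA.

    Columns are standardized; for each of the first ``n_components``
    components the predictor most correlated (in absolute value) with the
    component scores is returned, together with explained-variance fractions.
    """
    group = list(group)
    if len(group) == 1:
        return [group[0]], [1.0]
    if len(group) < 1:
        raise ValidationError("group must contain at least one predictor")
    X = np.column_stack([preds.values(n).astype(float) for n in group])
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = [group[i] for i in np.nonzero(sd == 0)[0]]
        raise ValidationError(f"constant column(s) in PCA group: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    frac = (s**2) / (s**2).sum()
    k = min(n_components, len(group))
    reps = []
    for comp in range(k):
        scores = Z @ vt[comp]
        cors = [abs(np.corrcoef(Z[:, j], scores)[0, 1]) for j in range(len(group))]
        reps.append(group[int(np.argmax(cors))])
    return reps, [float(f) for f in frac[:k]]


# --------------------------------------------------------------- relevance rule
def select_relevant_predictors(
    rows: pd.DataFrame,
    n_species: int,
    roc_min: float = 0.65,
    pi_min: float = 5.0,
) -> pd.DataFrame:
    """Apply the three-criteria relevance rule to per-predictor summary rows.

    ``rows`` must carry columns ``roc`` (mean univariate ROC), ``pi`` (mean
    permutation importance, percent) and ``n_selected`` (species whose models
    retained the predictor), indexed by predictor name.  The count criterion
    is ``n_selected >= ceil(n_species / 2)`` ("at least for half").  A
    predictor is relevant iff at least two criteria pass.
    """
    required = {"roc", "pi", "n_selected"}
    if not required <= set(rows.columns):
        raise ValidationError(f"rows must have columns {sorted(required)}")
    half = math.ceil(n_species / 2)
    out = rows.copy()
    out["crit_roc"] = out["roc"] >= roc_min
    out["crit_pi"] = out["pi"] >= pi_min
    out["crit_count"] = out["n_selected"] >= half
    out["criteria_passed"] = out[["crit_roc", "crit_pi", "crit_count"]].sum(axis=1).astype(int)
    out["relevant"] = out["criteria_passed"] >= 2
    return out


@dataclass
class SelectionReport:
    """Aggregated predictor-selection audit."""

    per_predictor: pd.DataFrame  # roc, pi, n_selected, criteria columns, relevant
    dropped_by_correlation: list[tuple[str, str, float]] = field(default_factory=list)
    pca_representatives: dict[str, list[str]] = field(default_factory=dict)

    @property
    def relevant(self) -> list[str]:
        return sorted(self.per_predictor.index[self.per_predictor["relevant"]])

    def to_csv(self, path) -> None:
        self.per_predictor.to_csv(path, index_label="predictor")
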