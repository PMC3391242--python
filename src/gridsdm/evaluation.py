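"""Validation machinery: splits, thresholding, scoring, permutation importance.

The validation scheme is repetition-based: the grid cells are split at
random into a 70% calibration and a 30% validation set, ten times per model
family.  Occurrence probabilities are binarized at the threshold that
maximizes the smaller of sensitivity and specificity (which drives the two
towards equality), and discrimination is scored by the rank-based ROC AUC
with the conventional five-band interpretation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import ConfigurationError, UndefinedMetricError, ValidationError

__all__ = [
    "SplitScheme",
    "make_splits",
    "choose_threshold",
    "binary_metrics",
    "roc_score",
    "classify_performance",
    "permutation_importance",
    "ImportanceProfile",
]

PERFORMANCE_BANDS = ("fail", "poor", "fair", "good", "excellent")


@dataclass(frozen=True)
class SplitScheme:
    """Repeated random 70/30 partitions of the cell set."""

    calibration: tuple[tuple[int, ...], ...]  # per repetition: cell ids
    validation: tuple[tuple[int, ...], ...]
    seed: int

    @property
    def n_repetitions(self) -> int:
        return len(self.calibration)

    def __iter__(self):
        return iter(zip(self.calibration, self.validation))


def make_splits(cell_ids: Sequence[int], frac: float = 0.7, reps: int = 10, seed: int = 0) -> SplitScheme:
    """Uniformly random calibration/validation partitions, one per repetition."""
    if not 0 < frac < 1:
        raise ConfigurationError("frac must lie in (0, 1)")
    if reps < 1:
        raise ConfigurationError("reps must be >= 1")
    cell_ids = np.asarray(cell_ids)
    n = len(cell_ids)
    if n < 10:
        raise ConfigurationError("need at least 10 cells to split")
    n_calib = int(round(frac * n))
    rng = np.random.default_rng(seed)
    calib, valid = [], []
    for _ in range(reps):
        perm = rng.permutation(n)
        calib.append(tuple(int(c) for c in cell_ids[perm[:n_calib]]))
        valid.append(tuple(int(c) for c in cell_ids[perm[n_calib:]]))
    return SplitScheme(tuple(calib), tuple(valid), seed)


def _check_two_classes(truth: np.ndarray) -> tuple[int, int]:
    n1 = int(truth.sum())
    n0 = len(truth) - n1
    if n1 == 0 or n0 == 0:
        raise UndefinedMetricError("metric undefined: truth contains a single class")
    return n1, n0


def binary_metrics(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """(sensitivity %, specificity %) of a binary prediction."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValidationError("pred and truth must have equal length")
    _check_two_classes(truth)
    tp = int(((pred == 1) & (truth == 1)).sum())
    fn = int(((pred == 0) & (truth == 1)).sum())
    tn = int(((pred == 0) & (truth == 0)).sum())
    fp = int(((pred == 1) & (truth == 0)).sum())
    return 100.0 * tp / (tp + fn), 100.0 * tn / (tn + fp)


def choose_threshold(p: np.ndarray, truth: np.ndarray) -> tuple[float, float, float]:
    """Decision threshold maximizing min(sensitivity, specificity).

    Candidate thresholds are the unique probability values; the decision rule
    is ``p >= t -> presence``.  Ties on min(sens, spec) are broken by minimal
    |sens - spec|, then by the smallest threshold.  Returns
    ``(threshold, sensitivity %, specificity %)``.
    """
    p = np.asarray(p, dtype=float)
    truth = np.asarray(truth)
    if p.shape != truth.shape:
        raise ValidationError("p and truth must have equal length")
    _check_two_classes(truth)
    candidates = np.unique(p)
    if len(candidates) == 1:
        warnings.warn("all probabilities equal; threshold degenerate", RuntimeWarning, stacklevel=2)
        t = float(candidates[0])
        sens, spec = binary_metrics((p >= t).astype(int), truth)
        return t, sens, spec
    best = None
    for t in candidates:
        sens, spec = binary_metrics((p >= t).astype(int), truth)
        key = (-min(sens, spec), abs(sens - spec), t)
        if best is None or key < best[0]:
            best = (key, float(t), sens, spec)
    return best[1], best[2], best[3]


def roc_score(p: np.ndarray, truth: np.ndarray) -> float:
    """Rank-based ROC AUC with midrank tie correction."""
    p = np.asarray(p, dtype=float)
    truth = np.asarray(truth)
    if p.shape != truth.shape:
        raise ValidationError("p and truth must have equal length")
    n1, n0 = _check_two_classes(truth)
    ranks = rankdata(p)
    return float((ranks[truth == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def classify_performance(roc: float) -> str:
    """Five-band interpretation of a ROC score.

    Bands are left-closed, right-open, with the last interval closed:
    [0.5,0.6) fail, [0.6,0.7) poor, [0.7,0.8) fair, [0.8,0.9) good,
    [0.9,1] excellent.  Scores below 0.5 (worse than chance) map to "fail".
    """
    if not 0.0 <= roc <= 1.0:
        raise ValidationError("roc must lie in [0, 1]")
    if roc >= 0.9:
        return "excellent"
    if roc >= 0.8:
        return "good"
    if roc >= 0.7:
        return "fair"
    if roc >= 0.6:
        return "poor"
    return "fail"


@dataclass
class ImportanceProfile:
    """Permutation-importance shares (percent, summing to 100) for one model."""

    species: str
    engine: str
    repetition: int
    pi: dict[str, float] = field(default_factory=dict)
    n_perm: int = 0
    seed: int = 0
    defined: bool = True

    def total(self) -> float:
        return float(sum(self.pi.values()))


def permutation_importance(
    model,
    data,
    n_perm: int = 20,
    seed: int = 0,
    predictors: Sequence[str] | None = None,
) -> ImportanceProfile:
    """Permutation importance of each predictor used by a fitted model.

    For predictor ``v``, predictions on the intact table are compared with
    predictions on a table in which the column ``v`` is randomly permuted;
    the raw importance is ``max(0, 1 - mean Pearson r)`` over ``n_perm``
    permutations, normalized across predictors to percentages summing to
    100.  Predictors offered but absent from the model get PI = 0 exactly
    (permuting an unused column leaves predictions unchanged).
    """
    from .engines import predict_probabilities  # local import to avoid a cycle

    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    base = predict_probabilities(model, data).p
    names = list(predictors) if predictors is not None else list(model.selected_predictors)
    raw: dict[str, float] = {}
    if np.std(base) == 0:
        warnings.warn("constant prediction vector; importance profile undefined", RuntimeWarning, stacklevel=2)
        return ImportanceProfile(
            model.species_code, model.engine, model.repetition_id,
            {n: 0.0 for n in names}, n_perm, seed, defined=False,
        )
    for name in names:
        if name not in model.selected_predictors:
            raw[name] = 0.0
            continue
        rs = []
        for _ in range(n_perm):
            shuffled = data.copy()
            shuffled.df[name] = rng.permutation(shuffled.df[name].to_numpy())
            perturbed = predict_probabilities(model, shuffled).p
            if np.std(perturbed) == 0:
                rs.append(0.0)
            else:
                rs.append(float(np.corrcoef(base, perturbed)[0, 1]))
        raw[name] = max(0.0, 1.0 - float(np.mean(rs)))
    total = sum(raw.values())
    if total == 0:
        warnings.warn("all raw importances zero; profile undefined", RuntimeWarning, stacklevel=2)
        return ImportanceProfile(
            model.species_code, model.engine, model.repetition_id,
            {n: 0.0 for n in names}, n_perm, seed, defined=False,
        )
    pi = {n: 100.0 * v / total for n, v in raw.items()}
    return ImportanceProfile(model.species_code, model.engine, model.repetition_id, pi, n_perm, seed)
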