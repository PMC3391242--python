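"""The four niche-model engines: GLM, GAM, RF and maximum entropy.

All engines share one contract: fit on a calibration :class:`PredictorTable`
with binary occurrence, return a :class:`FittedSDM` carrying the selected
predictors, engine-specific parameters, the seed and the calibration value
ranges, and predict per-cell occurrence scores in [0, 1] through
:func:`predict_probabilities` as a pure function of (model, table).

Model search follows the parsimonious-model convention of the framework:
GLM and GAM use bidirectional stepwise selection on AIC from the
intercept-only start; RF (for which AIC is undefined) uses forward selection
on out-of-bag misclassification with a one-standard-error stopping rule; the
maximum-entropy engine relies on its L1 penalty for sparsity.

GAM smooth terms are cubic splines with exactly four degrees of freedom per
continuous predictor, realized as a truncated-power basis
``[z, z^2, z^3, (z - k)^3_+]`` on standardized values with the interior knot
at the calibration median — a basis that stays defined under climate-shift
extrapolation beyond the calibration hull.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from sklearn.ensemble import RandomForestClassifier

from .errors import ConfigurationError, DataError, NumericalError, ValidationError
from .tables import PredictorTable

__all__ = [
    "FittedSDM",
    "ProbabilityMap",
    "fit_glm",
    "fit_gam",
    "fit_rf",
    "fit_maxent",
    "predict_probabilities",
]

ENGINES = ("GLM", "GAM", "RF", "ME")


@dataclass
class FittedSDM:
    """One fitted engine for one species and repetition."""

    engine: str
    species_code: str
    selected_predictors: list[str]
    parameters: dict
    threshold: float | None
    repetition_id: int
    seed: int
    calibration_ranges: dict[str, tuple[float, float]]
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def to_dict(self) -> dict:
        return {
            "engine": self.engine,
            "species_code": self.species_code,
            "selected_predictors": list(self.selected_predictors),
            "parameters": self.parameters,
            "threshold": self.threshold,
            "repetition_id": self.repetition_id,
            "seed": self.seed,
            "calibration_ranges": {k: list(v) for k, v in self.calibration_ranges.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FittedSDM":
        return cls(
            engine=d["engine"],
            species_code=d["species_code"],
            selected_predictors=list(d["selected_predictors"]),
            parameters=dict(d["parameters"]),
            threshold=d.get("threshold"),
            repetition_id=int(d.get("repetition_id", 0)),
            seed=int(d.get("seed", 0)),
            calibration_ranges={k: tuple(v) for k, v in d.get("calibration_ranges", {}).items()},
        )


@dataclass
class ProbabilityMap:
    """Per-cell occurrence scores aligned with a predictor table."""

    cell_id: np.ndarray
    p: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.cell_id = np.asarray(self.cell_id)
        self.p = np.asarray(self.p, dtype=float)
        if self.cell_id.shape != self.p.shape:
            raise ValidationError("cell_id and p must have equal length")
        if not np.isfinite(self.p).all():
            raise NumericalError("non-finite probabilities in map")


# ----------------------------------------------------------------- term encoding
def _term_columns(term: Mapping, preds: PredictorTable) -> np.ndarray:
    """Design columns of one term on an arbitrary aligned table."""
    name = term["name"]
    if name not in preds.meta:
        raise ValidationError(f"predictor {name!r} missing from table")
    v = preds.values(name)
    kind = term["type"]
    if kind == "linear":
        return v.astype(float)[:, None]
    if kind == "spline":
        z = (v.astype(float) - term["mean"]) / term["sd"]
        k = term["knot"]
        return np.column_stack([z, z**2, z**3, np.clip(z - k, 0.0, None) ** 3])
    if kind == "onehot":
        levels = term["levels"]
        unseen = set(np.unique(v).tolist()) - set(levels)
        if unseen:
            raise ValidationError(f"{name}: unseen categorical level(s) {sorted(unseen)}")
        return np.column_stack([(v == lv).astype(float) for lv in levels[1:]])  # first level = reference
    raise ValidationError(f"unknown term type {kind!r}")


def _make_term(name: str, preds: PredictorTable, smooth: bool) -> dict:
    meta = preds.meta[name]
    v = preds.values(name)
    if meta.kind == "categorical":
        return {"type": "onehot", "name": name, "levels": list(meta.levels)}
    if smooth and meta.kind == "continuous":
        if len(np.unique(v)) < 8:
            warnings.warn(f"{name}: too few distinct values for a spline; demoted to linear", RuntimeWarning)
            return {"type": "linear", "name": name}
        mu, sd = float(v.mean()), float(v.std())
        if sd == 0:
            raise DataError(f"{name}: constant column")
        z = (v - mu) / sd
        return {"type": "spline", "name": name, "mean": mu, "sd": sd, "knot": float(np.median(z))}
    return {"type": "linear", "name": name}


def _calibration_ranges(preds: PredictorTable, names: Sequence[str]) -> dict[str, tuple[float, float]]:
    out = {}
    for n in names:
        v = preds.values(n)
        if preds.meta[n].kind == "categorical":
            continue  # ranges are meaningful for numeric predictors only
        out[n] = (float(np.min(v)), float(np.max(v)))
    return out


# ------------------------------------------------------------------ binomial fit
def _binomial_llf(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _fit_binomial(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """Binomial GLM coefficients, log-likelihood and a separation-fallback flag."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100)
            params = np.asarray(res.params)
            llf = _binomial_llf(y, expit(X @ params))
            # a log-likelihood at (numerically) zero means the classes are
            # completely separated and the MLE does not exist
            if np.isfinite(params).all() and np.abs(params).max() < 1e4 and llf < -1e-6:
                return params, llf, False
        except Exception:
            pass
    # complete separation (or a failed IRLS): ridge-penalized fit on the
    # standardized scale, penalty 1e-4, coefficients mapped back
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    is_intercept = np.all(X == X[0, :], axis=0)
    Z = (X - mu) / sd
    Z[:, is_intercept] = X[:, is_intercept]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, Z, family=sm.families.Binomial()).fit_regularized(alpha=1e-4, L1_wt=0.0)
    beta_z = np.asarray(res.params)
    beta = beta_z / sd
    beta[is_intercept] = beta_z[is_intercept]
    # restore the intercept shift absorbed by centering
    inter_idx = np.nonzero(is_intercept)[0]
    if inter_idx.size:
        beta[inter_idx[0]] -= np.sum((beta_z * mu / sd)[~is_intercept])
    warnings.warn("complete separation: ridge-penalized fallback fit used", RuntimeWarning, stacklevel=3)
    return beta, _binomial_llf(y, expit(X @ beta)), True


def _stepwise_additive(
    calib: PredictorTable,
    occ: np.ndarray,
    offered: Sequence[str],
    smooth: bool,
) -> tuple[list[str], dict]:
    """Bidirectional stepwise AIC over whole-term blocks from the intercept start."""
    y = np.asarray(occ).astype(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise DataError("calibration set must contain both classes")
    terms = {n: _make_term(n, calib, smooth) for n in offered}
    blocks = {n: _term_columns(terms[n], calib) for n in offered}
    n = len(y)
    intercept = np.ones((n, 1))

    def design(names):
        cols = [intercept] + [blocks[m] for m in names]
        return np.concatenate(cols, axis=1)

    def fit(names):
        X = design(names)
        params, llf, fallback = _fit_binomial(X, y)
        aic = 2 * X.shape[1] - 2 * llf
        return aic, params, fallback

    selected: list[str] = []
    current_aic, current_params, current_fb = fit(selected)
    improved = True
    while improved:
        improved = False
        best = (current_aic, None, None, None)
        for name in offered:
            trial = selected + [name] if name not in selected else [m for m in selected if m != name]
            aic, params, fb = fit(trial)
            if aic < best[0] - 1e-9:
                best = (aic, trial, params, fb)
        if best[1] is not None:
            current_aic, selected, current_params, current_fb = best[0], best[1], best[2], best[3]
            improved = True
    params = {
        "terms": [terms[m] for m in selected],
        "coef": [float(c) for c in current_params],
        "aic": float(current_aic),
        "ridge_fallback": bool(current_fb),
    }
    return selected, params


def fit_glm(calib: PredictorTable, occ: np.ndarray, offered: Sequence[str], seed: int = 0,
            species_code: str = "", repetition_id: int = 0) -> FittedSDM:
    """Binomial additive-linear model with bidirectional stepwise AIC selection."""
    selected, params = _stepwise_additive(calib, occ, offered, smooth=False)
    return FittedSDM("GLM", species_code, selected, params, None, repetition_id, seed,
                     _calibration_ranges(calib, selected))


def fit_gam(calib: PredictorTable, occ: np.ndarray, offered: Sequence[str], seed: int = 0,
            species_code: str = "", repetition_id: int = 0) -> FittedSDM:
    """Binomial additive model with 4-df cubic-spline smooths per continuous term."""
    selected, params = _stepwise_additive(calib, occ, offered, smooth=True)
    return FittedSDM("GAM", species_code, selected, params, None, repetition_id, seed,
                     _calibration_ranges(calib, selected))


# -------------------------------------------------------------------- random forest
def _rf_matrix(preds: PredictorTable, names: Sequence[str]) -> np.ndarray:
    cols = []
    for n in names:
        if preds.meta[n].kind == "categorical":
            for lv in preds.meta[n].levels:
                cols.append((preds.values(n) == lv).astype(float))
        else:
            cols.append(preds.values(n).astype(float))
    return np.column_stack(cols)


def _rf_oob_error(X: np.ndarray, y: np.ndarray, n_trees: int, seed: int) -> float:
    # light ensemble for candidate screening; leaf size 5 trades a little
    # OOB-error resolution for a large constant-factor speedup
    rf = RandomForestClassifier(n_estimators=n_trees, oob_score=True, random_state=seed,
                                n_jobs=1, min_samples_leaf=5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rf.fit(X, y)
    dec = rf.oob_decision_function_
    ok = ~np.isnan(dec[:, 0])
    pred = (dec[ok, 1] > 0.5).astype(int)
    return float(np.mean(pred != y[ok]))


def fit_rf(calib: PredictorTable, occ: np.ndarray, offered: Sequence[str], seed: int = 0,
           n_trees: int = 500, species_code: str = "", repetition_id: int = 0,
           n_trees_screen: int = 50) -> FittedSDM:
    """Bagged classification-tree ensemble (500 trees by default).

    Predictors enter by forward selection on out-of-bag misclassification
    with a one-standard-error stopping rule; screening fits use a reduced
    ensemble, the final model the full one.  Probabilities are the fraction
    of trees voting presence.
    """
    if n_trees < 1:
        raise ConfigurationError("n_trees must be >= 1")
    y = np.asarray(occ).astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise DataError("calibration set must contain both classes")
    n = len(y)
    prevalence = y.mean()
    current_err = float(min(prevalence, 1 - prevalence))  # majority-class baseline
    selected: list[str] = []
    remaining = list(offered)
    screen = min(n_trees, n_trees_screen)
    while remaining:
        errs = {}
        for name in remaining:
            errs[name] = _rf_oob_error(_rf_matrix(calib, selected + [name]), y, screen, seed)
        best_name = min(errs, key=lambda k: (errs[k], k))
        best_err = errs[best_name]
        se = float(np.sqrt(max(best_err * (1 - best_err), 1e-12) / n))
        if best_err >= current_err - se:
            break
        selected.append(best_name)
        remaining.remove(best_name)
        current_err = best_err
    params = {"n_trees": n_trees, "oob_error": current_err, "feature_order": list(selected)}
    model = FittedSDM("RF", species_code, selected, params, None, repetition_id, seed,
                      _calibration_ranges(calib, selected))
    if selected:
        rf = RandomForestClassifier(n_estimators=n_trees, oob_score=False, random_state=seed, n_jobs=1)
        rf.fit(_rf_matrix(calib, selected), y)
        model._cache["rf"] = rf
    else:
        model._cache["constant"] = float(prevalence)
    return model


# ------------------------------------------------------------------ maximum entropy
def _me_features(preds: PredictorTable, names: Sequence[str], spec: Mapping | None = None):
    """Standardized linear+quadratic continuous features, linear ordinal, level dummies."""
    if spec is None:
        spec = {}
        for n in names:
            meta = preds.meta[n]
            if meta.kind == "categorical":
                spec[n] = {"kind": "categorical", "levels": list(meta.levels)}
            else:
                v = preds.values(n).astype(float)
                sd = float(v.std())
                if sd == 0:
                    raise DataError(f"{n}: constant column")
                spec[n] = {"kind": meta.kind, "mean": float(v.mean()), "sd": sd}
    cols, labels = [], []
    for n in names:
        s = spec[n]
        if s["kind"] == "categorical":
            v = preds.values(n)
            unseen = set(np.unique(v).tolist()) - set(s["levels"])
            if unseen:
                raise ValidationError(f"{n}: unseen categorical level(s) {sorted(unseen)}")
            for lv in s["levels"][1:]:
                cols.append((v == lv).astype(float))
                labels.append(f"{n}=={lv}")
        else:
            z = (preds.values(n).astype(float) - s["mean"]) / s["sd"]
            cols.append(z)
            labels.append(n)
            if s["kind"] == "continuous":
                cols.append(z**2)
                labels.append(f"{n}^2")
    F = np.column_stack(cols) if cols else np.empty((preds.n_cells, 0))
    return F, labels, spec


def fit_maxent(calib: PredictorTable, occ: np.ndarray, offered: Sequence[str], seed: int = 0,
               reg: float = 1.0, species_code: str = "", repetition_id: int = 0) -> FittedSDM:
    """Maximum-entropy (Gibbs) suitability model from presence cells only.

    The distribution over the background (all calibration cells) maximizes
    entropy subject to soft feature constraints: weights are found by
    maximizing the presence log-likelihood under an L1 penalty ``reg·|λ|``;
    at the optimum each fitted feature expectation matches the presence
    sample mean to within ``reg / n_presences``.
    """
    y = np.asarray(occ).astype(int)
    n_pres = int(y.sum())
    if n_pres < 10:
        raise DataError("maximum-entropy fit needs at least 10 presence cells")
    pres_idx = np.nonzero(y == 1)[0]
    if len(calib.df.iloc[pres_idx][list(offered)].drop_duplicates()) == 1:
        raise DataError("degenerate support: all presences share one predictor profile")
    F, labels, spec = _me_features(calib, list(offered))
    Fp = F[pres_idx]
    sp = Fp.sum(axis=0)
    d = F.shape[1]

    # split-variable L1: lambda = a - b with a, b >= 0 and penalty reg*(a + b)
    def objective(x):
        lam = x[:d] - x[d:]
        eta = F @ lam
        lz = logsumexp(eta)
        w = np.exp(eta - lz)
        nll = -float(sp @ lam) + n_pres * lz
        g = -sp + n_pres * (F.T @ w)
        grad = np.concatenate([g + reg, -g + reg])
        return nll + reg * float(x.sum()), grad

    if d == 0 or not np.isfinite(reg):
        lam = np.zeros(d)
    else:
        x0 = np.zeros(2 * d)
        res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                       bounds=[(0, None)] * (2 * d), options={"maxiter": 500, "ftol": 1e-12})
        lam = res.x[:d] - res.x[d:]
    params = {
        "weights": [float(v) for v in lam],
        "labels": labels,
        "feature_spec": spec,
        "offered": list(offered),
        "reg": float(reg),
    }
    used = sorted({lbl.split("==")[0].split("^")[0] for lbl, w in zip(labels, lam) if w != 0.0})
    selected = used if used else list(offered)
    return FittedSDM("ME", species_code, selected, params, None, repetition_id, seed,
                     _calibration_ranges(calib, selected))


# ---------------------------------------------------------------------- prediction
def predict_probabilities(model: FittedSDM, preds: PredictorTable) -> ProbabilityMap:
    """Per-cell occurrence scores of a fitted model on any aligned table.

    A pure function of (model, table): no refitting.  Extrapolation beyond
    the stored calibration ranges is permitted (the mismatch-accounting
    module quantifies it).  Missing predictor columns or undeclared
    categorical levels raise.
    """
    missing = set(model.selected_predictors) - set(preds.predictors)
    if missing:
        raise ValidationError(f"table lacks selected predictors: {sorted(missing)}")
    prov = {"engine": model.engine, "species": model.species_code, "repetition": model.repetition_id}
    if model.engine in ("GLM", "GAM"):
        terms = model.parameters["terms"]
        cols = [np.ones((preds.n_cells, 1))] + [_term_columns(t, preds) for t in terms]
        X = np.concatenate(cols, axis=1)
        p = expit(X @ np.asarray(model.parameters["coef"]))
        return ProbabilityMap(preds.cell_ids, p, prov)
    if model.engine == "RF":
        if "constant" in model._cache:
            return ProbabilityMap(preds.cell_ids, np.full(preds.n_cells, model._cache["constant"]), prov)
        rf = model._cache.get("rf")
        if rf is None:
            raise NumericalError("RF model has no live ensemble; regrow it from the stored seed and data")
        X = _rf_matrix(preds, model.parameters["feature_order"])
        p = rf.predict_proba(X)[:, 1]  # per-tree vote share (trees are fully grown)
        return ProbabilityMap(preds.cell_ids, p, prov)
    if model.engine == "ME":
        names = model.parameters["offered"]
        F, _, _ = _me_features(preds, names, model.parameters["feature_spec"])
        eta = F @ np.asarray(model.parameters["weights"])
        s = np.exp(eta - eta.max())  # rescaled so the most suitable cell scores 1
        return ProbabilityMap(preds.cell_ids, s, prov)
    raise ValidationError(f"unknown engine {model.engine!r}")
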