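"""Environmental-response profiles and fuzzy c-means species grouping.

Each species' fitted models yield permutation-importance percentages per
predictor; summing these within the predictor groups climate (C), altitude
(H) and hydromorphology (HY) and dividing by the overall sum gives a
3-share response profile on the simplex.  Species are then grouped by fuzzy
c-means (Bezdek's alternating updates, fuzzifier m = 2, Euclidean distance),
which assigns each species graded memberships summing to one; the reported
cluster id (Fc) is the argmax membership and the membership grade (MG) its
value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, DataError
from .evaluation import ImportanceProfile
from .tables import PredictorTable

__all__ = ["ResponseProfile", "ClusterResult", "group_response_profile", "grouping_from_metadata", "fuzzy_cmeans"]

RESPONSE_GROUPS = ("C", "H", "HY")

_CATEGORY_TO_GROUP = {"climate": "C", "topography": "H", "hydromorphology": "HY"}


def grouping_from_metadata(preds: PredictorTable) -> dict[str, str]:
    """Map each non-anthropogenic predictor to its response group C/H/HY."""
    return {
        name: _CATEGORY_TO_GROUP[m.category]
        for name, m in preds.meta.items()
        if m.category in _CATEGORY_TO_GROUP
    }


@dataclass
class ResponseProfile:
    """(C, H, HY) importance shares for one species under one engine."""

    species: str
    engine: str
    c_share: float
    h_share: float
    hy_share: float
    grouping: Mapping[str, str] = field(default_factory=dict)

    def as_array(self) -> np.ndarray:
        return np.array([self.c_share, self.h_share, self.hy_share])


def group_response_profile(pi: ImportanceProfile, grouping: Mapping[str, str]) -> ResponseProfile:
    """Shares = group-wise PI sums over the total PI sum."""
    unknown = set(pi.pi) - set(grouping)
    if unknown:
        raise DataError(f"predictors without a response group: {sorted(unknown)}")
    total = sum(pi.pi.values())
    if total <= 0:
        raise DataError("all-zero importance profile: response shares undefined")
    sums = {g: 0.0 for g in RESPONSE_GROUPS}
    for name, value in pi.pi.items():
        sums[grouping[name]] += value
    return ResponseProfile(
        species=pi.species,
        engine=pi.engine,
        c_share=sums["C"] / total,
        h_share=sums["H"] / total,
        hy_share=sums["HY"] / total,
        grouping=dict(grouping),
    )


@dataclass
class ClusterResult:
    """Fuzzy c-means output on item x feature data."""

    memberships: np.ndarray  # items x clusters, rows sum to 1
    centers: np.ndarray  # clusters x features
    objective_trace: np.ndarray  # J_m per iteration (best restart)
    seed: int
    fuzzifier: float

    @property
    def cluster_id(self) -> np.ndarray:
        """Fc: hard assignment by maximal membership."""
        return self.memberships.argmax(axis=1)

    @property
    def membership_grade(self) -> np.ndarray:
        """MG: the maximal membership per item."""
        return self.memberships.max(axis=1)


def _memberships(X: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    zero = d2 <= 1e-300
    u = np.zeros((X.shape[0], centers.shape[0]))
    coincident = zero.any(axis=1)
    if coincident.any():
        # limit convention: an item on a center belongs fully to it
        rows = np.nonzero(coincident)[0]
        u[rows, d2[rows].argmin(axis=1)] = 1.0
    rest = ~coincident
    if rest.any():
        power = d2[rest] ** (-1.0 / (m - 1.0))
        u[rest] = power / power.sum(axis=1, keepdims=True)
    return u


def fuzzy_cmeans(
    profiles: np.ndarray,
    c: int = 4,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    restarts: int = 20,
    seed: int = 0,
) -> ClusterResult:
    """Fuzzy c-means with random restarts; deterministic given seed.

    Alternates the standard updates (memberships proportional to
    ``distance^(-2/(m-1))``; centers as membership^m-weighted means) until
    the maximal membership change falls below ``tol``; the best of
    ``restarts`` random initializations by the objective
    ``J_m = sum u^m d^2`` is returned.
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2:
        raise DataError("profiles must be a 2-D items x features array")
    n = X.shape[0]
    if c < 1:
        raise ConfigurationError("c must be >= 1")
    if n < c:
        raise DataError(f"need at least c={c} items, got {n}")
    if m <= 1:
        raise ConfigurationError("fuzzifier m must be > 1")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, restarts)):
        u = rng.dirichlet(np.ones(c), size=n)
        trace = []
        for _ in range(max_iter):
            um = u**m
            centers = (um.T @ X) / um.sum(axis=0)[:, None]
            u_new = _memberships(X, centers, m)
            d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            trace.append(float((u_new**m * d2).sum()))
            if np.abs(u_new - u).max() < tol:
                u = u_new
                break
            u = u_new
        objective = trace[-1] if trace else np.inf
        if best is None or objective < best[0]:
            best = (objective, u, centers, np.asarray(trace))
    _, u, centers, trace = best
    return ClusterResult(memberships=u, centers=centers, objective_trace=trace, seed=seed, fuzzifier=m)
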