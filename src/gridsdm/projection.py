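"""Scenario projection, range change, and extrapolation accounting.

Fitted ensembles are projected onto climate-shifted predictor tables: every
(model, scenario) pair yields a binary map through the model's stored
threshold, merged by majority vote per scenario and jointly over all pairs.
Range change is summarized as loss and gain — cells vacated or newly
occupied relative to the count of currently occupied cells — and projection
reliability is audited by the calibration-range mismatch: the percentage of
cells whose projected predictor values fall outside the range seen during
model calibration, where predictions are extrapolations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .consensus import BinaryMap, ConsensusMap, coincidence_rate, consensus_vote
from .engines import FittedSDM, predict_probabilities
from .errors import DataError, ValidationError
from .tables import PredictorTable

__all__ = ["ChangeSummary", "MismatchReport", "binary_map", "project_future", "loss_gain", "range_mismatch"]


@dataclass
class ChangeSummary:
    """Loss/gain/coincidence between a current and a future consensus map."""

    species: str
    comparison: str
    loss: float  # % of currently occupied cells vacated
    gain: float  # % of currently occupied cells newly occupied (can exceed 100)
    coincidence: float


@dataclass
class MismatchReport:
    """Percent of cells outside the calibration range, per predictor and in union."""

    scenario: str
    per_predictor: dict[str, float] = field(default_factory=dict)
    total: float = 0.0


def binary_map(model: FittedSDM, preds: PredictorTable, scenario: str | None = None) -> BinaryMap:
    """Threshold a model's probability map into presence/absence."""
    if model.threshold is None:
        raise ValidationError("model has no decision threshold; calibrate it first")
    pm = predict_probabilities(model, preds)
    prov = dict(pm.provenance)
    if scenario is not None:
        prov["scenario"] = scenario
    return BinaryMap(pm.cell_id, (pm.p >= model.threshold).astype(int), prov)


def project_future(
    models: Sequence[FittedSDM],
    scenario_tables: Mapping[str, PredictorTable],
) -> tuple[dict[str, ConsensusMap], ConsensusMap]:
    """Project a fitted ensemble onto shifted tables.

    Returns per-scenario consensus maps and the joint consensus over all
    (model, scenario) pairs, each by the strict majority rule.
    """
    if not models:
        raise ValidationError("need at least one fitted model")
    per_scenario: dict[str, ConsensusMap] = {}
    all_members: list[BinaryMap] = []
    for name, table in scenario_tables.items():
        members = [binary_map(m, table, scenario=name) for m in models]
        per_scenario[name] = consensus_vote(members)
        all_members.extend(members)
    joint = consensus_vote(all_members)
    return per_scenario, joint


def loss_gain(current: BinaryMap, future: BinaryMap, species: str = "", comparison: str = "") -> ChangeSummary:
    """Loss and gain as percentages of the currently occupied cell count."""
    n_current = int(current.presence.sum())
    if n_current == 0:
        raise DataError("loss/gain undefined: no currently occupied cells")
    lost = int(((current.presence == 1) & (future.presence == 0)).sum())
    gained = int(((current.presence == 0) & (future.presence == 1)).sum())
    return ChangeSummary(
        species=species,
        comparison=comparison,
        loss=100.0 * lost / n_current,
        gain=100.0 * gained / n_current,
        coincidence=coincidence_rate(current, future),
    )


def union_calibration_ranges(models: Sequence[FittedSDM]) -> dict[str, tuple[float, float]]:
    """Per predictor: min of mins, max of maxes over the ensemble's repetitions."""
    out: dict[str, tuple[float, float]] = {}
    for m in models:
        for name, (lo, hi) in m.calibration_ranges.items():
            if name in out:
                out[name] = (min(out[name][0], lo), max(out[name][1], hi))
            else:
                out[name] = (lo, hi)
    return out


def range_mismatch(models: Sequence[FittedSDM], scenario_table: PredictorTable, scenario: str = "") -> MismatchReport:
    """Extrapolation audit of a projection.

    For every numeric predictor used by the ensemble: the percentage of
    cells whose projected value falls below the stored calibration minimum
    or above the maximum; ``total`` is the percentage of cells failing for
    at least one used predictor (the union, hence >= every per-predictor
    value).
    """
    if not models:
        raise ValidationError("need at least one fitted model")
    ranges = union_calibration_ranges(models)
    missing = set(ranges) - set(scenario_table.predictors)
    if missing:
        raise ValidationError(f"scenario table lacks predictors: {sorted(missing)}")
    n = scenario_table.n_cells
    any_out = np.zeros(n, dtype=bool)
    per_predictor = {}
    for name, (lo, hi) in sorted(ranges.items()):
        v = scenario_table.values(name).astype(float)
        out = (v < lo) | (v > hi)
        per_predictor[name] = 100.0 * float(out.mean())
        any_out |= out
    return MismatchReport(scenario=scenario, per_predictor=per_predictor, total=100.0 * float(any_out.mean()))


def mismatch_table(reports: Sequence[MismatchReport]) -> pd.DataFrame:
    """Scenario x predictor table of mismatch percentages with a mean row."""
    rows = []
    for r in reports:
        rows.append({"scenario": r.scenario, **r.per_predictor, "total": r.total})
    df = pd.DataFrame(rows).set_index("scenario")
    df.loc["mean"] = df.mean()
    return df
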