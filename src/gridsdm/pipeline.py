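"""End-to-end study orchestration.

``run_pipeline`` executes the whole framework on synthetic (or loaded) grid
data: simulate -> species inclusion filter -> predictor screening ->
engine fits with repetition-based validation -> consensus mapping ->
response clustering -> scenario projection with loss/gain and
calibration-range mismatch reporting.  Every stage derives its seeds
deterministically from the master seed, so identical configurations yield
identical report bundles.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import ClusterResult, fuzzy_cmeans, group_response_profile, grouping_from_metadata
from .consensus import BinaryMap, ConsensusMap, coincidence_rate, consensus_vote
from .engines import FittedSDM, fit_gam, fit_glm, fit_maxent, fit_rf, predict_probabilities
from .errors import ConfigurationError, DataError
from .evaluation import (
    ImportanceProfile,
    binary_metrics,
    choose_threshold,
    classify_performance,
    make_splits,
    permutation_importance,
    roc_score,
)
from .projection import binary_map, loss_gain, mismatch_table, project_future, range_mismatch
from .selection import SelectionReport, correlation_filter, pca_representatives, select_relevant_predictors, univariate_auc
from .synthetic import (
    NicheSpec,
    ShiftSpec,
    apply_climate_shift,
    default_scenarios,
    default_species,
    generate_predictor_grid,
    simulate_species,
)
from .tables import OccurrenceTable, PredictorTable

__all__ = ["PipelineConfig", "PipelineResult", "filter_species", "run_pipeline", "compare_variants", "STAGES"]

STAGES = ("simulate", "filter", "select", "fit", "evaluate", "consensus", "cluster", "project", "report")

_ENGINE_FITTERS = {"GLM": fit_glm, "GAM": fit_gam, "RF": fit_rf, "ME": fit_maxent}


def _derive_seed(*parts) -> int:
    """Stable sub-seed from heterogeneous parts, kept below 2^31."""
    return zlib.crc32(":".join(str(p) for p in parts).encode()) % (2**31)


@dataclass
class PipelineConfig:
    """All knobs of a study run; defaults reproduce the atlas-scale setup."""

    seed: int = 7
    n_cells: int = 2935
    smoothness: float = 5.0
    predictor_csv: str | None = None
    occurrence_csv: str | None = None
    niches: list[NicheSpec] | None = None
    scenarios: dict[str, ShiftSpec] | None = None
    calib_frac: float = 0.7
    n_repetitions: int = 10
    engines: tuple[str, ...] = ("GLM", "GAM", "RF", "ME")
    consensus_engines: tuple[str, ...] = ("GLM", "GAM", "RF")
    rf_trees: int = 500
    me_reg: float = 1.0
    corr_cap: float = 0.75
    roc_min: float = 0.65
    pi_min: float = 5.0
    min_presences: int = 50
    projection_roc_gate: float = 0.8
    n_perm: int = 10
    pi_cells: int = 1000
    n_clusters: int = 4
    fuzzifier: float = 2.0
    restrict_predictors: tuple[str, ...] | None = None
    outdir: str | None = None

    def __post_init__(self):
        if not 0 < self.calib_frac < 1:
            raise ConfigurationError("calib_frac must lie in (0, 1)")
        if not 0 < self.corr_cap <= 1:
            raise ConfigurationError("corr_cap must lie in (0, 1]")
        if not self.engines:
            raise ConfigurationError("at least one engine must be enabled")
        unknown = set(self.engines) - set(_ENGINE_FITTERS)
        if unknown:
            raise ConfigurationError(f"unknown engines: {sorted(unknown)}")
        if not set(self.consensus_engines) <= set(self.engines):
            raise ConfigurationError("consensus_engines must be a subset of engines")
        if not 0 < self.projection_roc_gate <= 1:
            raise ConfigurationError("projection_roc_gate must lie in (0, 1]")
        if self.n_repetitions < 1 or self.min_presences < 0:
            raise ConfigurationError("n_repetitions must be >= 1 and min_presences >= 0")

    # ------------------------------------------------------------------- YAML
    def to_dict(self) -> dict:
        d = asdict(self)
        d["engines"] = list(self.engines)
        d["consensus_engines"] = list(self.consensus_engines)
        if self.restrict_predictors is not None:
            d["restrict_predictors"] = list(self.restrict_predictors)
        d["niches"] = [n.to_dict() for n in self.niches] if self.niches else None
        d["scenarios"] = {k: s.to_dict() for k, s in self.scenarios.items()} if self.scenarios else None
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if d.get("niches"):
            d["niches"] = [NicheSpec.from_dict(n) for n in d["niches"]]
        if d.get("scenarios"):
            d["scenarios"] = {k: ShiftSpec.from_dict(s) for k, s in d["scenarios"].items()}
        for key in ("engines", "consensus_engines", "restrict_predictors"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class PipelineResult:
    """Everything a run produced, stage by stage."""

    config: PipelineConfig
    preds: PredictorTable = None
    occ: OccurrenceTable = None
    truth: pd.DataFrame = None
    splits: object = None
    candidates: list[str] = field(default_factory=list)
    dropped_by_correlation: list = field(default_factory=list)
    pca_reps: dict = field(default_factory=dict)
    univariate_roc: pd.DataFrame = None
    models: dict = field(default_factory=dict)  # (species, engine, rep) -> FittedSDM
    records: pd.DataFrame = None  # per species x engine x repetition
    profiles: list[ImportanceProfile] = field(default_factory=list)
    selection_report: SelectionReport = None
    evaluation_summary: pd.DataFrame = None
    consensus_current: dict[str, ConsensusMap] = field(default_factory=dict)
    consensus_stats: pd.DataFrame = None
    response_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    cluster_results: dict[str, ClusterResult] = field(default_factory=dict)
    projected_species: list[str] = field(default_factory=list)
    scenario_consensus: dict = field(default_factory=dict)  # species -> {scenario: map}
    joint_consensus: dict[str, ConsensusMap] = field(default_factory=dict)
    change_table: pd.DataFrame = None
    mismatch: dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def filter_species(occ: OccurrenceTable, min_presences: int = 50) -> OccurrenceTable:
    """Retain species with strictly more than ``min_presences`` presence cells."""
    counts = occ.presence_counts()
    keep = [s for s in occ.species if counts[s] > min_presences]
    if not keep:
        raise DataError(f"no species with more than {min_presences} presences; nothing to model")
    return occ.select_species(keep)


# ----------------------------------------------------------------------- stages
def _stage_simulate(cfg: PipelineConfig, res: PipelineResult) -> None:
    if cfg.predictor_csv and cfg.occurrence_csv:
        res.preds = PredictorTable.read_csv(cfg.predictor_csv)
        res.occ = OccurrenceTable.read_csv(cfg.occurrence_csv)
        res.occ.check_aligned(res.preds)
        res.truth = None
        return
    res.preds = generate_predictor_grid(
        n_cells=cfg.n_cells, corr_cap=cfg.corr_cap, smoothness=cfg.smoothness,
        seed=_derive_seed(cfg.seed, "grid"),
    )
    niches = cfg.niches if cfg.niches is not None else default_species()
    res.occ, res.truth = simulate_species(res.preds, niches, seed=_derive_seed(cfg.seed, "species"))


def _stage_filter(cfg: PipelineConfig, res: PipelineResult) -> None:
    res.occ = filter_species(res.occ, cfg.min_presences)


def _level_frequency_score(values: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Numeric surrogate for a categorical predictor: per-level presence rate."""
    score = np.zeros(len(values), dtype=float)
    for lv in np.unique(values):
        mask = values == lv
        score[mask] = truth[mask].mean()
    return score


def _stage_select(cfg: PipelineConfig, res: PipelineResult) -> None:
    preds, occ = res.preds, res.occ
    rows = {}
    for name in preds.predictors:
        aucs = []
        for sp in occ.species:
            y = occ.presence(sp)
            v = preds.values(name)
            if preds.meta[name].kind == "categorical":
                v = _level_frequency_score(v, y)
            aucs.append(univariate_auc(v, y))
        rows[name] = float(np.mean(aucs))
    res.univariate_roc = pd.DataFrame({"roc": rows})
    pool = list(cfg.restrict_predictors) if cfg.restrict_predictors else preds.predictors
    kept, dropped = correlation_filter(preds, rows, cap=cfg.corr_cap, names=pool)
    res.candidates = kept
    res.dropped_by_correlation = dropped
    # PCA representatives inside each thematic group of continuous predictors
    res.pca_reps = {}
    for category in ("climate", "topography", "hydromorphology", "anthropogenic"):
        group = [n for n in pool if preds.meta[n].category == category and preds.meta[n].kind == "continuous"]
        if len(group) >= 2:
            reps, frac = pca_representatives(preds, group)
            res.pca_reps[category] = {"representatives": reps, "variance_fractions": frac}


def _stage_fit(cfg: PipelineConfig, res: PipelineResult) -> None:
    preds, occ = res.preds, res.occ
    res.splits = make_splits(preds.cell_ids, frac=cfg.calib_frac, reps=cfg.n_repetitions,
                             seed=_derive_seed(cfg.seed, "splits"))
    offered = res.candidates
    records = []
    rng_pi = np.random.default_rng(_derive_seed(cfg.seed, "pi-cells"))
    for sp in occ.species:
        for rep, (cal_ids, val_ids) in enumerate(res.splits):
            cal = preds.subset_cells(cal_ids)
            val = preds.subset_cells(val_ids)
            ycal = occ.subset_cells(cal_ids).presence(sp)
            yval = occ.subset_cells(val_ids).presence(sp)
            # permutation importance on a fixed-size calibration subsample
            n_pi = min(cfg.pi_cells, len(cal_ids))
            pi_ids = rng_pi.choice(np.asarray(cal_ids), size=n_pi, replace=False)
            pi_table = preds.subset_cells(pi_ids)
            for engine in cfg.engines:
                seed = _derive_seed(cfg.seed, engine, sp, rep)
                kwargs = {"species_code": sp, "repetition_id": rep, "seed": seed}
                if engine == "RF":
                    kwargs["n_trees"] = cfg.rf_trees
                if engine == "ME":
                    kwargs["reg"] = cfg.me_reg
                model = _ENGINE_FITTERS[engine](cal, ycal, offered, **kwargs)
                p_cal = predict_probabilities(model, cal).p
                thr, sens_cal, spec_cal = choose_threshold(p_cal, ycal)
                model.threshold = thr
                p_val = predict_probabilities(model, val).p
                pred_val = (p_val >= thr).astype(int)
                sens, spec = binary_metrics(pred_val, yval)
                roc_cal = roc_score(p_cal, ycal)
                roc_val = roc_score(p_val, yval)
                profile = permutation_importance(model, pi_table, n_perm=cfg.n_perm,
                                                 seed=_derive_seed(cfg.seed, "pi", engine, sp, rep),
                                                 predictors=offered)
                res.profiles.append(profile)
                res.models[(sp, engine, rep)] = model
                records.append({
                    "species": sp, "engine": engine, "repetition": rep,
                    "roc_calibration": roc_cal, "roc_validation": roc_val,
                    "sensitivity": sens, "specificity": spec,
                    "coincidence": float(np.mean(pred_val == yval)),
                    "band": classify_performance(max(0.0, min(1.0, roc_val))),
                    "n_selected": len(model.selected_predictors),
                })
    res.records = pd.DataFrame(records)


def _stage_evaluate(cfg: PipelineConfig, res: PipelineResult) -> None:
    rec = res.records
    summary = rec.groupby(["species", "engine"]).agg(
        roc_calibration=("roc_calibration", "mean"),
        roc_calibration_sd=("roc_calibration", "std"),
        roc_validation=("roc_validation", "mean"),
        roc_validation_sd=("roc_validation", "std"),
        sensitivity=("sensitivity", "mean"),
        specificity=("specificity", "mean"),
        coincidence=("coincidence", "mean"),
    ).reset_index()
    summary["band"] = summary["roc_validation"].map(lambda r: classify_performance(max(0.0, min(1.0, r))))
    res.evaluation_summary = summary

    # selection report: mean univariate ROC, mean PI, species retention counts
    n_species = len(res.occ.species)
    pi_rows = []
    for prof in res.profiles:
        for name, v in prof.pi.items():
            pi_rows.append({"species": prof.species, "engine": prof.engine,
                            "repetition": prof.repetition, "predictor": name, "pi": v})
    pi_df = pd.DataFrame(pi_rows)
    mean_pi = pi_df.groupby("predictor")["pi"].mean() if len(pi_rows) else pd.Series(dtype=float)
    n_models_per_species = len(cfg.engines) * cfg.n_repetitions
    counts = {}
    for name in res.candidates:
        n_sel = 0
        for sp in res.occ.species:
            used = sum(1 for (s, e, r), m in res.models.items() if s == sp and name in m.selected_predictors)
            if used >= n_models_per_species / 2.0:  # retained by at least half the species' models
                n_sel += 1
        counts[name] = n_sel
    rows = pd.DataFrame({
        "roc": res.univariate_roc["roc"].reindex(res.candidates),
        "pi": mean_pi.reindex(res.candidates).fillna(0.0),
        "n_selected": pd.Series(counts),
    })
    verdicts = select_relevant_predictors(rows, n_species, roc_min=cfg.roc_min, pi_min=cfg.pi_min)
    res.selection_report = SelectionReport(
        per_predictor=verdicts,
        dropped_by_correlation=res.dropped_by_correlation,
        pca_representatives=res.pca_reps,
    )


def _stage_consensus(cfg: PipelineConfig, res: PipelineResult) -> None:
    stats = []
    for sp in res.occ.species:
        members = [binary_map(res.models[(sp, e, r)], res.preds)
                   for e in cfg.consensus_engines for r in range(cfg.n_repetitions)]
        cm = consensus_vote(members)
        res.consensus_current[sp] = cm
        y = res.occ.presence(sp)
        sens, spec = binary_metrics(cm.presence, y)
        stats.append({
            "species": sp,
            "roc_consensus": roc_score(cm.vote_fraction, y),
            "sensitivity": sens, "specificity": spec,
            "coincidence": float(np.mean(cm.presence == y)),
            "occupied_cells": int(cm.presence.sum()),
        })
    res.consensus_stats = pd.DataFrame(stats)


def _stage_cluster(cfg: PipelineConfig, res: PipelineResult) -> None:
    grouping = grouping_from_metadata(res.preds)
    by_key: dict[tuple[str, str], list[ImportanceProfile]] = {}
    for prof in res.profiles:
        by_key.setdefault((prof.species, prof.engine), []).append(prof)
    for engine in cfg.engines:
        rows = []
        for sp in res.occ.species:
            profs = [p for p in by_key.get((sp, engine), []) if p.defined]
            if not profs:
                continue
            mean_pi = {}
            for p in profs:
                for name, v in p.pi.items():
                    if name in grouping:  # anthropogenic predictors carry no response group
                        mean_pi[name] = mean_pi.get(name, 0.0) + v / len(profs)
            if sum(mean_pi.values()) <= 0:
                continue  # importance fell entirely on ungrouped (anthropogenic) predictors
            merged = ImportanceProfile(sp, engine, -1, mean_pi, 0, 0)
            rp = group_response_profile(merged, grouping)
            rows.append({"species": sp, "C": rp.c_share, "H": rp.h_share, "HY": rp.hy_share})
        if not rows:
            continue
        df = pd.DataFrame(rows).set_index("species")
        c = min(cfg.n_clusters, len(df))
        cr = fuzzy_cmeans(df[["C", "H", "HY"]].to_numpy(), c=c, m=cfg.fuzzifier,
                          seed=_derive_seed(cfg.seed, "fcm", engine))
        # stable cluster numbering: order clusters by descending mean altitude share
        order = np.argsort(-cr.centers[:, 1])
        relabel = {int(old): new + 1 for new, old in enumerate(order)}
        df["Fc"] = [relabel[int(i)] for i in cr.cluster_id]
        df["MG"] = cr.membership_grade
        res.cluster_results[engine] = cr
        res.response_tables[engine] = df


def _stage_project(cfg: PipelineConfig, res: PipelineResult) -> None:
    scenarios = cfg.scenarios if cfg.scenarios is not None else default_scenarios()
    tables = {name: apply_climate_shift(res.preds, spec) for name, spec in scenarios.items()}
    gate = cfg.projection_roc_gate
    summary = res.evaluation_summary
    changes = []
    for sp in res.occ.species:
        mean_val_roc = summary[(summary.species == sp) & summary.engine.isin(cfg.consensus_engines)]["roc_validation"].mean()
        if mean_val_roc < gate:
            continue
        res.projected_species.append(sp)
        models = [res.models[(sp, e, r)] for e in cfg.consensus_engines for r in range(cfg.n_repetitions)]
        per_scenario, joint = project_future(models, tables)
        res.scenario_consensus[sp] = per_scenario
        res.joint_consensus[sp] = joint
        current = res.consensus_current[sp]
        # engine-specific marginals: one engine's repetitions across all scenarios
        for engine in cfg.consensus_engines:
            eng_models = [res.models[(sp, engine, r)] for r in range(cfg.n_repetitions)]
            _, eng_joint = project_future(eng_models, tables)
            cs = loss_gain(current, eng_joint, species=sp, comparison=engine)
            changes.append({"species": sp, "comparison": engine, "loss": cs.loss, "gain": cs.gain,
                            "coincidence": cs.coincidence})
        for name, cmap in per_scenario.items():
            cs = loss_gain(current, cmap, species=sp, comparison=name)
            changes.append({"species": sp, "comparison": name, "loss": cs.loss, "gain": cs.gain,
                            "coincidence": cs.coincidence})
        cs = loss_gain(current, joint, species=sp, comparison="Mean")
        changes.append({"species": sp, "comparison": "Mean", "loss": cs.loss, "gain": cs.gain,
                        "coincidence": cs.coincidence})
        reports = [range_mismatch(models, tables[name], scenario=name) for name in tables]
        res.mismatch[sp] = mismatch_table(reports)
    res.change_table = pd.DataFrame(changes)


def write_outputs(cfg: PipelineConfig, res: PipelineResult) -> None:
    """Write every artifact the run has produced so far to ``cfg.outdir``."""
    if cfg.outdir is None:
        return
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if res.preds is not None:
        res.preds.to_csv(out / "predictors.csv")
    if res.occ is not None:
        res.occ.to_csv(out / "occurrences.csv")
    if res.truth is not None:
        res.truth.to_csv(out / "truth_probabilities.csv", index=False)
    if res.selection_report is not None:
        res.selection_report.per_predictor.to_csv(out / "selection_report.csv", index_label="predictor")
        (out / "selection_summary.json").write_text(json.dumps({
            "relevant": res.selection_report.relevant,
            "dropped_by_correlation": [[a, b, r] for a, b, r in res.dropped_by_correlation],
            "pca_representatives": res.pca_reps,
        }, indent=1))
    if res.records is not None:
        res.records.to_csv(out / "evaluation_records.csv", index=False)
    if res.evaluation_summary is not None:
        res.evaluation_summary.to_csv(out / "evaluation_summary.csv", index=False)
    if res.consensus_stats is not None:
        res.consensus_stats.to_csv(out / "consensus_stats.csv", index=False)
    if res.profiles:
        pi_rows = [{"species": p.species, "engine": p.engine, "repetition": p.repetition,
                    "predictor": n, "pi": v} for p in res.profiles for n, v in p.pi.items()]
        pd.DataFrame(pi_rows).to_csv(out / "importance_profiles.csv", index=False)
    for engine, df in res.response_tables.items():
        df.to_csv(out / f"response_clusters_{engine}.csv")
    for sp, cm in res.consensus_current.items():
        pd.DataFrame({"cell_id": cm.cell_id, "presence": cm.presence,
                      "vote_fraction": cm.vote_fraction}).to_csv(out / f"consensus_current_{sp}.csv", index=False)
    for sp in res.projected_species:
        joint = res.joint_consensus[sp]
        pd.DataFrame({"cell_id": joint.cell_id, "presence": joint.presence,
                      "vote_fraction": joint.vote_fraction}).to_csv(out / f"consensus_future_{sp}.csv", index=False)
        res.mismatch[sp].to_csv(out / f"mismatch_{sp}.csv")
    if res.change_table is not None and len(res.change_table):
        res.change_table.to_csv(out / "change_summary.csv", index=False)
    if res.mismatch:
        mean_species_mismatch(res).to_csv(out / "mismatch_mean.csv")
    if res.manifest:
        (out / "manifest.json").write_text(json.dumps(res.manifest, indent=1, default=str))


def mean_species_mismatch(res: PipelineResult) -> pd.DataFrame:
    """Scenario x predictor mismatch averaged over projected species.

    Species' models use different predictor subsets, so each predictor
    column is averaged over the species whose models actually use it.
    """
    if not res.mismatch:
        raise DataError("no mismatch reports: nothing was projected")
    return pd.concat(res.mismatch.values()).groupby(level=0, sort=False).mean()


def _stage_report(cfg: PipelineConfig, res: PipelineResult) -> None:
    res.manifest = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "stage_seeds": {
            "grid": _derive_seed(cfg.seed, "grid"),
            "species": _derive_seed(cfg.seed, "species"),
            "splits": _derive_seed(cfg.seed, "splits"),
            "engine_seed_rule": "crc32(master:engine:species:repetition) % 2^31",
        },
        "species_modeled": list(res.occ.species),
        "species_projected": list(res.projected_species),
        "candidates": list(res.candidates),
        "relevant_predictors": res.selection_report.relevant if res.selection_report else None,
    }
    write_outputs(cfg, res)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "filter": _stage_filter,
    "select": _stage_select,
    "fit": _stage_fit,
    "evaluate": _stage_evaluate,
    "consensus": _stage_consensus,
    "cluster": _stage_cluster,
    "project": _stage_project,
    "report": _stage_report,
}


def run_pipeline(config: PipelineConfig, until: str = "report") -> PipelineResult:
    """Run the study through ``until`` (inclusive); deterministic given the seed."""
    if until not in STAGES:
        raise ConfigurationError(f"unknown stage {until!r}; expected one of {STAGES}")
    res = PipelineResult(config=config)
    for stage in STAGES:
        _STAGE_FUNCS[stage](config, res)
        if stage == until:
            break
    return res


def compare_variants(full: PipelineResult, restricted: PipelineResult, gate: float = 0.8) -> pd.DataFrame:
    """Validation-ROC change when predictors are restricted (e.g. climate only).

    Both runs must share the master seed and split scheme.  Returns one row
    per species x engine with the restricted and full mean validation ROC,
    their difference, and a climate-sensitivity flag (restricted mean over
    the consensus engines >= ``gate``).
    """
    if full.config.seed != restricted.config.seed or full.splits != restricted.splits:
        raise DataError("variant comparison refused: runs do not share splits and seed")
    f = full.evaluation_summary.set_index(["species", "engine"])["roc_validation"]
    r = restricted.evaluation_summary.set_index(["species", "engine"])["roc_validation"]
    joined = pd.DataFrame({"roc_full": f, "roc_restricted": r}).dropna()
    joined["delta"] = joined["roc_restricted"] - joined["roc_full"]
    cons = restricted.config.consensus_engines
    flags = (
        joined.reset_index()
        .query("engine in @cons")
        .groupby("species")["roc_restricted"].mean() >= gate
    )
    joined = joined.reset_index()
    joined["climate_sensitive"] = joined["species"].map(flags)
    return joined
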