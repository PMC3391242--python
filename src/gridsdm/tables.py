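"""Grid-cell data containers.

Atlas-style data live in two flat tables: a :class:`PredictorTable` holding
one row per grid cell with environmental predictors (continuous, ordinal and
categorical), and an :class:`OccurrenceTable` holding binary presence
indicators per species for the same cells.  Both are thin, validated wrappers
around :class:`pandas.DataFrame` with CSV round-tripping; predictor metadata
travels in a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, ValidationError

CATEGORIES = ("climate", "topography", "hydromorphology", "anthropogenic")
KINDS = ("continuous", "ordinal", "categorical")

#: Columns reserved for cell identity/geometry, never treated as predictors.
ID_COLUMNS = ("cell_id", "x", "y")


@dataclass(frozen=True)
class PredictorMeta:
    """Metadata for one predictor column."""

    name: str
    category: str
    kind: str
    units: str = ""
    levels: tuple | None = None  # declared finite level set (categorical only)
    core: bool = False  # member of the designated low-correlation core set

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown predictor category {self.category!r}")
        if self.kind not in KINDS:
            raise ValidationError(f"unknown predictor kind {self.kind!r}")
        if self.kind == "categorical" and not self.levels:
            raise ValidationError(f"categorical predictor {self.name!r} needs a declared level set")

    def to_dict(self) -> dict:
        d = {"name": self.name, "category": self.category, "kind": self.kind, "units": self.units, "core": self.core}
        if self.levels is not None:
            d["levels"] = list(self.levels)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PredictorMeta":
        levels = d.get("levels")
        return cls(
            name=d["name"],
            category=d["category"],
            kind=d["kind"],
            units=d.get("units", ""),
            levels=tuple(levels) if levels is not None else None,
            core=bool(d.get("core", False)),
        )


@dataclass
class PredictorTable:
    """Cells x environmental predictors, with per-predictor metadata.

    Invariants enforced on construction: unique ``cell_id``; no missing
    values in predictor columns (rows with missing data are dropped on load,
    mirroring the exclusion of incompletely mapped coastal cells); exactly
    one metadata record per predictor column; categorical values drawn from
    the declared level set.
    """

    df: pd.DataFrame
    meta: dict[str, PredictorMeta] = field(default_factory=dict)

    def __post_init__(self):
        if "cell_id" not in self.df.columns:
            raise ValidationError("predictor table needs a cell_id column")
        if self.df["cell_id"].duplicated().any():
            raise ValidationError("cell_id values must be unique")
        preds = [c for c in self.df.columns if c not in ID_COLUMNS]
        missing_meta = set(preds) - set(self.meta)
        if missing_meta:
            raise ValidationError(f"predictors without metadata: {sorted(missing_meta)}")
        extra_meta = set(self.meta) - set(preds)
        if extra_meta:
            raise ValidationError(f"metadata without matching column: {sorted(extra_meta)}")
        if self.df[preds].isna().any().any():
            raise ValidationError("missing values in predictor columns; drop incomplete cells on load")
        for name in preds:
            m = self.meta[name]
            if m.kind == "categorical":
                observed = set(self.df[name].unique().tolist())
                if not observed <= set(m.levels):
                    raise ValidationError(f"{name}: values outside declared levels: {sorted(observed - set(m.levels))}")
        self.df = self.df.reset_index(drop=True)

    # ------------------------------------------------------------------ views
    @property
    def cell_ids(self) -> np.ndarray:
        return self.df["cell_id"].to_numpy()

    @property
    def n_cells(self) -> int:
        return len(self.df)

    @property
    def predictors(self) -> list[str]:
        return [c for c in self.df.columns if c not in ID_COLUMNS]

    def names_of_kind(self, *kinds: str) -> list[str]:
        return [p for p in self.predictors if self.meta[p].kind in kinds]

    @property
    def continuous(self) -> list[str]:
        return self.names_of_kind("continuous")

    @property
    def ordinal(self) -> list[str]:
        return self.names_of_kind("ordinal")

    @property
    def categorical(self) -> list[str]:
        return self.names_of_kind("categorical")

    @property
    def core_predictors(self) -> list[str]:
        return [p for p in self.predictors if self.meta[p].core]

    def values(self, name: str) -> np.ndarray:
        if name not in self.meta:
            raise ValidationError(f"unknown predictor {name!r}")
        return self.df[name].to_numpy()

    def subset_cells(self, cell_ids: Iterable) -> "PredictorTable":
        """Rows restricted to ``cell_ids`` (in the given order)."""
        idx = pd.Index(self.df["cell_id"])
        locs = idx.get_indexer(list(cell_ids))
        if (locs < 0).any():
            raise AlignmentError("requested cell_ids not present in table")
        return PredictorTable(self.df.iloc[locs].reset_index(drop=True), dict(self.meta))

    def copy(self) -> "PredictorTable":
        return PredictorTable(self.df.copy(), dict(self.meta))

    # --------------------------------------------------------------------- IO
    def to_csv(self, path: str | Path) -> None:
        """Write values as CSV and metadata as a ``<path>.meta.json`` sidecar."""
        path = Path(path)
        self.df.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps([m.to_dict() for m in self.meta.values()], indent=1))

    @classmethod
    def read_csv(cls, path: str | Path) -> "PredictorTable":
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        meta = {d["name"]: PredictorMeta.from_dict(d) for d in json.loads(sidecar.read_text())}
        # drop cells with missing predictor values (coastal-cell convention)
        preds = [c for c in df.columns if c not in ID_COLUMNS]
        df = df.dropna(subset=preds)
        return cls(df, meta)


@dataclass
class OccurrenceTable:
    """Cells x species binary presence indicators (0/1)."""

    df: pd.DataFrame

    def __post_init__(self):
        if "cell_id" not in self.df.columns:
            raise ValidationError("occurrence table needs a cell_id column")
        if self.df["cell_id"].duplicated().any():
            raise ValidationError("cell_id values must be unique")
        vals = self.df[self.species].to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValidationError("occurrence indicators must be 0/1")
        self.df = self.df.reset_index(drop=True)

    @property
    def species(self) -> list[str]:
        return [c for c in self.df.columns if c != "cell_id"]

    @property
    def cell_ids(self) -> np.ndarray:
        return self.df["cell_id"].to_numpy()

    def presence(self, species_code: str) -> np.ndarray:
        if species_code not in self.species:
            raise ValidationError(f"unknown species {species_code!r}")
        return self.df[species_code].to_numpy().astype(int)

    def presence_counts(self) -> pd.Series:
        return self.df[self.species].sum().astype(int)

    def check_aligned(self, preds: PredictorTable) -> None:
        if len(self.df) != preds.n_cells or not np.array_equal(self.cell_ids, preds.cell_ids):
            raise AlignmentError("occurrence table not aligned with predictor table")

    def subset_cells(self, cell_ids: Iterable) -> "OccurrenceTable":
        idx = pd.Index(self.df["cell_id"])
        locs = idx.get_indexer(list(cell_ids))
        if (locs < 0).any():
            raise AlignmentError("requested cell_ids not present in table")
        return OccurrenceTable(self.df.iloc[locs].reset_index(drop=True))

    def select_species(self, codes: Sequence[str]) -> "OccurrenceTable":
        return OccurrenceTable(self.df[["cell_id", *codes]].copy())

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "OccurrenceTable":
        return cls(pd.read_csv(path))
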