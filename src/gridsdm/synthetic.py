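"""Synthetic atlas grids, virtual species, and climate-shift scenarios.

Everything downstream of this module is testable against known ground truth:
the generator produces an atlas-scale lattice of grid cells with spatially
smooth, partially correlated environmental fields (climate, topography,
hydromorphology, anthropogenic pressure), virtual species whose occupancy
follows a declared logistic niche, and additive/multiplicative climate-shift
scenarios parameterized from published mid-century GCM projections for
central Europe (ECHAM5, HadCM3 and IPSL-CM4 under the SRES A1b storyline).

Spatial fields are built as a low-order north-south trend plus
Gaussian-filtered noise; the field means and ranges are calibrated to the
published 20th-century baseline for the German grid (annual mean temperature
8.4 degC spanning roughly 2.5-10.4, annual precipitation 732 mm, etc.), so
scenario deltas act on realistic magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.special import expit
from scipy.stats import norm
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .tables import OccurrenceTable, PredictorMeta, PredictorTable

__all__ = [
    "NicheSpec",
    "ShiftSpec",
    "generate_predictor_grid",
    "simulate_species",
    "apply_climate_shift",
    "default_scenarios",
    "default_species",
    "gaussian_niche_terms",
]

RIVER_TYPES = tuple(range(1, 11))  # merged national typology, 10 substrate classes
LANDUSE_TYPES = tuple(range(1, 8))  # urban, agriculture, forest, grassland, freshwater, marine, other

#: Basic low-correlation core used for the pairwise-|r| guarantee.
CORE_PREDICTORS = ("AnnTMean", "Isotherm", "TSeason", "AnnPMean", "AltMean", "CumLenkm", "Strahler", "RtypMost")


# --------------------------------------------------------------------------- specs
@dataclass(frozen=True)
class NicheSpec:
    """Logistic niche of a virtual species.

    Occupancy probability is exactly
    ``logistic(intercept + sum linear + sum quadratic + sum categorical offsets)``
    evaluated on raw predictor values.
    """

    species_code: str
    intercept: float = 0.0
    linear_coefs: Mapping[str, float] = field(default_factory=dict)
    quadratic_coefs: Mapping[str, float] = field(default_factory=dict)
    categorical_prefs: Mapping[tuple[str, object], float] = field(default_factory=dict)

    def referenced_predictors(self) -> set[str]:
        names = set(self.linear_coefs) | set(self.quadratic_coefs)
        names |= {p for p, _ in self.categorical_prefs}
        return names

    def linear_predictor(self, preds: PredictorTable) -> np.ndarray:
        missing = self.referenced_predictors() - set(preds.predictors)
        if missing:
            raise ValidationError(f"niche {self.species_code!r} references unknown predictors: {sorted(missing)}")
        eta = np.full(preds.n_cells, float(self.intercept))
        for name, beta in self.linear_coefs.items():
            eta += beta * preds.values(name).astype(float)
        for name, beta in self.quadratic_coefs.items():
            eta += beta * preds.values(name).astype(float) ** 2
        for (name, level), offset in self.categorical_prefs.items():
            if preds.meta[name].kind != "categorical":
                raise ValidationError(f"categorical preference on non-categorical predictor {name!r}")
            eta += offset * (preds.values(name) == level)
        return eta

    def probability(self, preds: PredictorTable) -> np.ndarray:
        return expit(self.linear_predictor(preds))

    def to_dict(self) -> dict:
        return {
            "species_code": self.species_code,
            "intercept": self.intercept,
            "linear_coefs": dict(self.linear_coefs),
            "quadratic_coefs": dict(self.quadratic_coefs),
            "categorical_prefs": [
                {"predictor": p, "level": lv, "offset": o} for (p, lv), o in self.categorical_prefs.items()
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NicheSpec":
        prefs = {(e["predictor"], e["level"]): float(e["offset"]) for e in d.get("categorical_prefs", [])}
        return cls(
            species_code=d["species_code"],
            intercept=float(d.get("intercept", 0.0)),
            linear_coefs={k: float(v) for k, v in d.get("linear_coefs", {}).items()},
            quadratic_coefs={k: float(v) for k, v in d.get("quadratic_coefs", {}).items()},
            categorical_prefs=prefs,
        )


@dataclass(frozen=True)
class ShiftSpec:
    """A climate scenario as per-predictor affine shifts: value' = value*scale + delta."""

    scenario_name: str
    additive_delta: Mapping[str, float] = field(default_factory=dict)
    scale_factor: Mapping[str, float] = field(default_factory=dict)

    def touched(self) -> set[str]:
        return set(self.additive_delta) | set(self.scale_factor)

    def inverse(self) -> "ShiftSpec":
        """Scenario undoing this one (requires nonzero scale factors)."""
        names = self.touched()
        scale = {n: 1.0 / self.scale_factor.get(n, 1.0) for n in names}
        delta = {n: -self.additive_delta.get(n, 0.0) / self.scale_factor.get(n, 1.0) for n in names}
        return ShiftSpec(self.scenario_name + "-inverse", delta, scale)

    def to_dict(self) -> dict:
        return {
            "scenario_name": self.scenario_name,
            "additive_delta": dict(self.additive_delta),
            "scale_factor": dict(self.scale_factor),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ShiftSpec":
        return cls(
            scenario_name=d["scenario_name"],
            additive_delta={k: float(v) for k, v in d.get("additive_delta", {}).items()},
            scale_factor={k: float(v) for k, v in d.get("scale_factor", {}).items()},
        )


# --------------------------------------------------------------------- generator
def _smooth_field(ny: int, nx: int, rng: np.random.Generator, corr_len: float) -> np.ndarray:
    """Standardized Gaussian-filtered white-noise field on an ny x nx lattice."""
    raw = rng.standard_normal((ny, nx))
    sm = ndimage.gaussian_filter(raw, sigma=corr_len, mode="reflect")
    sm -= sm.mean()
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def _std(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def generate_predictor_grid(
    n_cells: int = 2935,
    layout: tuple[int, int] | None = None,
    corr_cap: float = 0.75,
    smoothness: float = 5.0,
    seed: int = 0,
) -> PredictorTable:
    """Generate a synthetic atlas predictor grid.

    Parameters
    ----------
    n_cells
        Number of grid cells (default matches the 2,935-cell national atlas).
    layout
        Lattice dimensions ``(ny, nx)`` with ``ny*nx >= n_cells``; by default a
        roughly square lattice is chosen and the first ``n_cells`` cells used.
    corr_cap
        Pairwise |association| bound the designated core predictors respect.
    smoothness
        Gaussian-filter length scale (in cells) of the noise component of the
        spatial fields; a free parameter of the generator, not an estimate of
        any real landscape.
    seed
        Seed for all randomness; identical inputs give identical tables.
    """
    if n_cells < 10:
        raise ConfigurationError("n_cells must be >= 10")
    if not 0 < corr_cap <= 1:
        raise ConfigurationError("corr_cap must lie in (0, 1]")
    if layout is None:
        ny = int(np.ceil(np.sqrt(n_cells)))
        nx = int(np.ceil(n_cells / ny))
        layout = (ny, nx)
    ny, nx = layout
    if ny < 2 or nx < 2 or ny * nx < n_cells:
        raise ConfigurationError(f"lattice {layout} cannot hold {n_cells} cells")

    rng = np.random.default_rng(seed)
    g = [_smooth_field(ny, nx, rng, smoothness) for _ in range(16)]

    rows, cols = np.divmod(np.arange(ny * nx), nx)
    southness = (rows / (ny - 1)) * 2.0 - 1.0  # -1 at the north edge, +1 south

    def flat(f2d):
        return f2d.ravel()[: n_cells]

    south = southness[:n_cells]
    G = [flat(f) for f in g]

    # Topography: lognormal-ish altitude rising to the south (alpine tail).
    alt_latent = _std(0.6 * south + 0.8 * G[0])
    AltMean = 60.0 + 170.0 * np.exp(0.9 * alt_latent)

    # Climate, calibrated to the published 20th-century baseline means/ranges.
    alt_anom = AltMean - AltMean.mean()
    AnnTMean = 8.4 - 0.0022 * alt_anom + 0.9 * G[1]
    zT = _std(AnnTMean)
    Isotherm = 3.1 + 0.15 * (0.4 * zT + 0.92 * G[2])
    TSeason = 63.7 + 3.6 * _std(0.45 * south + 0.9 * G[3])
    AnnPMean = 732.1 + 0.30 * alt_anom + 100.0 * G[4]
    Tmax = 22.7 + 1.05 * (AnnTMean - 8.4) + 0.45 * G[5]
    TWetQuar = 14.5 + 0.75 * (AnnTMean - 8.4) + 0.8 * G[6]
    TDryQuar = 1.5 + 0.55 * (AnnTMean - 8.4) + 1.0 * G[7]
    DiuTRange = 8.9 + 0.8 * (0.85 * _std(Isotherm) + 0.53 * G[8])
    pse_latent = 0.3 * G[4] + 0.95 * G[9]
    PSeason = 20.7 + 4.3 * pse_latent + 0.75 * (pse_latent**2 - 1.0)

    # Hydromorphology: heavy-tailed cumulative upstream length, an ordinal
    # Strahler order as a discretized monotone transform of it, and a
    # categorical river type tied to altitude and a substrate latent.
    len_latent = -0.35 * _std(alt_latent) + 0.94 * G[10]
    CumLenkm = np.exp(4.7 + 1.0 * len_latent)
    strahler_latent = 0.72 * _std(np.log(CumLenkm)) + 0.69 * G[11]
    strahler_probs = np.array([0.08, 0.15, 0.20, 0.20, 0.15, 0.10, 0.07, 0.03, 0.02])
    cuts = norm.ppf(np.cumsum(strahler_probs)[:-1])
    Strahler = np.searchsorted(cuts, strahler_latent) + 1

    zalt = _std(alt_latent)
    substrate = G[12]
    # river-type utilities: alpine classes load on altitude, lowland classes inversely
    base = np.array([-2.5, -1.5, 0.0, 0.0, 0.3, 0.4, -0.6, -0.4, -1.8, -1.2])
    alt_load = np.array([2.8, 1.8, 0.8, 0.6, 0.0, -0.8, -1.0, -0.6, -1.6, 0.0])
    sub_load = np.array([0.0, 0.4, 0.8, -0.8, 1.0, -1.0, -0.5, 0.5, 0.3, 0.0])
    util = base[None, :] + np.outer(zalt, alt_load) + np.outer(substrate, sub_load)
    util += rng.gumbel(size=util.shape)
    RtypMost = np.asarray(RIVER_TYPES)[np.argmax(util, axis=1)]

    # Anthropogenic pressure: dominant land use and population density.
    pop_latent = 0.85 * G[13] + 0.15 * G[14]
    Popmean = np.exp(4.5 + 1.0 * _std(pop_latent))
    lu_base = np.array([-1.2, 0.8, 0.5, -0.5, -1.5, -6.0, -2.0])
    lu_pop = np.array([1.8, 0.2, -0.6, -0.2, 0.0, 0.0, 0.0])
    lu_sub = np.array([0.0, -0.4, 0.8, 0.4, 0.3, 0.0, 0.2])
    lu_util = lu_base[None, :] + np.outer(_std(pop_latent), lu_pop) + np.outer(G[15], lu_sub)
    lu_util += rng.gumbel(size=lu_util.shape)
    Lusemax = np.asarray(LANDUSE_TYPES)[np.argmax(lu_util, axis=1)]

    df = pd.DataFrame(
        {
            "cell_id": np.arange(1, n_cells + 1),
            "x": cols[:n_cells],
            "y": rows[:n_cells],
            "AnnTMean": AnnTMean,
            "DiuTRange": DiuTRange,
            "Isotherm": Isotherm,
            "TSeason": TSeason,
            "Tmax": Tmax,
            "TWetQuar": TWetQuar,
            "TDryQuar": TDryQuar,
            "AnnPMean": AnnPMean,
            "PSeason": PSeason,
            "AltMean": AltMean,
            "CumLenkm": CumLenkm,
            "Strahler": Strahler,
            "RtypMost": RtypMost,
            "Lusemax": Lusemax,
            "Popmean": Popmean,
        }
    )

    core = set(CORE_PREDICTORS)
    meta = {}

    def add(name, category, kind, units="", levels=None):
        meta[name] = PredictorMeta(name, category, kind, units, levels, core=name in core)

    add("AnnTMean", "climate", "continuous", "degC")
    add("DiuTRange", "climate", "continuous", "degC")
    add("Isotherm", "climate", "continuous", "-")
    add("TSeason", "climate", "continuous", "degC^2")
    add("Tmax", "climate", "continuous", "degC")
    add("TWetQuar", "climate", "continuous", "degC")
    add("TDryQuar", "climate", "continuous", "degC")
    add("AnnPMean", "climate", "continuous", "mm")
    add("PSeason", "climate", "continuous", "-")
    add("AltMean", "topography", "continuous", "m")
    add("CumLenkm", "hydromorphology", "continuous", "km")
    add("Strahler", "hydromorphology", "ordinal", "-")
    add("RtypMost", "hydromorphology", "categorical", "-", RIVER_TYPES)
    add("Lusemax", "anthropogenic", "categorical", "-", LANDUSE_TYPES)
    add("Popmean", "anthropogenic", "continuous", "inhabitants/km^2")

    return PredictorTable(df, meta)


# --------------------------------------------------------------------- species
def simulate_species(
    preds: PredictorTable,
    niches: Sequence[NicheSpec],
    seed: int = 0,
) -> tuple[OccurrenceTable, pd.DataFrame]:
    """Draw Bernoulli occupancy for each virtual species.

    Returns the occurrence table and the exact per-cell truth probabilities
    (one column per species) for use as an oracle in downstream tests.
    """
    if not niches:
        raise ValidationError("need at least one niche spec")
    rng = np.random.default_rng(seed)
    occ = {"cell_id": preds.cell_ids}
    truth = {"cell_id": preds.cell_ids}
    for niche in niches:
        p = niche.probability(preds)
        occ[niche.species_code] = (rng.random(preds.n_cells) < p).astype(int)
        truth[niche.species_code] = p
    return OccurrenceTable(pd.DataFrame(occ)), pd.DataFrame(truth)


def apply_climate_shift(preds: PredictorTable, shift: ShiftSpec) -> PredictorTable:
    """Return a new table with ``value' = value*scale + delta`` per touched predictor.

    Predictors listed in the scenario but absent from the table are skipped,
    so a published scenario can be applied to restricted predictor sets.
    Shifting a categorical predictor is an error.
    """
    out = preds.df.copy()
    for name in sorted(shift.touched()):
        if name not in preds.meta:
            continue
        if preds.meta[name].kind == "categorical":
            raise ValidationError(f"cannot shift categorical predictor {name!r}")
        scale = float(shift.scale_factor.get(name, 1.0))
        delta = float(shift.additive_delta.get(name, 0.0))
        out[name] = out[name].astype(float) * scale + delta
    return PredictorTable(out, dict(preds.meta))


def default_scenarios() -> dict[str, ShiftSpec]:
    """Three 2050s (A1b) scenarios; deltas are published future-minus-baseline means."""
    return {
        "ECHAM5": ShiftSpec(
            "ECHAM5-A1b-2050s",
            {"AnnTMean": 2.4, "Isotherm": 0.1, "TSeason": -1.0, "AnnPMean": -15.8, "Tmax": 2.8, "PSeason": -5.7},
        ),
        "HADCM3": ShiftSpec(
            "HADCM3-A1b-2050s",
            {"AnnTMean": 2.7, "Isotherm": 0.0, "TSeason": 3.1, "AnnPMean": -16.8, "Tmax": 4.1, "PSeason": -3.5},
        ),
        "IPSL-CM4": ShiftSpec(
            "IPSL-CM4-A1b-2050s",
            {"AnnTMean": 2.7, "Isotherm": 0.0, "TSeason": 1.6, "AnnPMean": -18.7, "Tmax": 3.2, "PSeason": 1.8},
        ),
    }


def gaussian_niche_terms(predictor: str, optimum: float, tolerance: float, height: float) -> dict:
    """Coefficients of a unimodal (Gaussian-on-the-logit) response.

    ``logit contribution = height - (x - optimum)^2 / (2 tolerance^2)`` expanded
    into intercept/linear/quadratic terms on the raw predictor scale.
    """
    a = -1.0 / (2.0 * tolerance**2)
    return {
        "intercept": height - optimum**2 / (2.0 * tolerance**2),
        "linear": {predictor: optimum / tolerance**2},
        "quadratic": {predictor: a},
    }


def default_species() -> list[NicheSpec]:
    """Six virtual species: two cold-adapted, two warm-adapted, two climate-neutral.

    Niche strengths are set so each species is common (occurrence frequency
    roughly 0.2-0.5, the scale of the real atlas) and clearly predictable
    (validation discrimination in the good-to-excellent band), as required for
    a species to enter the projection stage at all.
    """
    species = []

    cold1 = gaussian_niche_terms("AnnTMean", optimum=6.0, tolerance=0.85, height=3.6)
    species.append(
        NicheSpec(
            "ColdSten1",
            intercept=cold1["intercept"],
            linear_coefs={**cold1["linear"], "Strahler": -0.2},
            quadratic_coefs=cold1["quadratic"],
        )
    )
    cold2 = gaussian_niche_terms("AnnTMean", optimum=6.4, tolerance=0.75, height=3.0)
    species.append(
        NicheSpec(
            "ColdSten2",
            intercept=cold2["intercept"] + 0.004 * 300.0,
            linear_coefs={**cold2["linear"], "AltMean": -0.004},
            quadratic_coefs=cold2["quadratic"],
        )
    )
    # warm-adapted: monotone increasing response to temperature
    species.append(
        NicheSpec(
            "WarmTher1",
            intercept=-1.2 - 2.1 * 8.4,
            linear_coefs={"AnnTMean": 2.1},
        )
    )
    species.append(
        NicheSpec(
            "WarmTher2",
            intercept=-1.0 - 1.7 * 8.4 + 0.006 * 732.1,
            linear_coefs={"AnnTMean": 1.7, "AnnPMean": -0.006},
        )
    )
    # climate-neutral: driven by hydromorphology only (never shifted)
    species.append(
        NicheSpec(
            "NeutHydr1",
            intercept=-5.8,
            linear_coefs={"Strahler": 1.3},
        )
    )
    species.append(
        NicheSpec(
            "NeutHydr2",
            intercept=-3.7,
            linear_coefs={"Strahler": 0.55},
            categorical_prefs={
                ("RtypMost", 1): -2.6,
                ("RtypMost", 2): -1.3,
                ("RtypMost", 3): 1.0,
                ("RtypMost", 4): 1.3,
                ("RtypMost", 5): 2.6,
                ("RtypMost", 6): 1.9,
                ("RtypMost", 7): -1.4,
                ("RtypMost", 8): 0.6,
                ("RtypMost", 9): -1.9,
            },
        )
    )
    return species
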