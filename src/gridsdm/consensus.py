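"""Majority-vote consensus over binary presence/absence maps.

An ensemble member is one binary map (an engine x repetition x scenario
combination).  A cell is assigned presence in the consensus only if strictly
more than 50% of the members predict presence; an exact tie in an even
ensemble therefore yields absence.  Map agreement is summarized by the
coincidence rate: the fraction of cells on which two maps agree, presences
and absences alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import AlignmentError, ValidationError

__all__ = ["BinaryMap", "ConsensusMap", "consensus_vote", "coincidence_rate"]


@dataclass
class BinaryMap:
    """Per-cell binary presence indicators with provenance."""

    cell_id: np.ndarray
    presence: np.ndarray
    provenance: Mapping = field(default_factory=dict)

    def __post_init__(self):
        self.cell_id = np.asarray(self.cell_id)
        self.presence = np.asarray(self.presence)
        if self.cell_id.shape != self.presence.shape:
            raise ValidationError("cell_id and presence must have equal length")
        if self.presence.size and not np.isin(self.presence, (0, 1)).all():
            raise ValidationError("presence values must be 0/1")
        self.presence = self.presence.astype(int)


@dataclass
class ConsensusMap(BinaryMap):
    """Majority-vote map retaining the per-cell vote fraction and members."""

    vote_fraction: np.ndarray = None
    ensemble_members: list = field(default_factory=list)


def _check_aligned(maps: Sequence[BinaryMap]) -> np.ndarray:
    ref = maps[0].cell_id
    for m in maps[1:]:
        if m.cell_id.shape != ref.shape or not np.array_equal(m.cell_id, ref):
            raise AlignmentError("maps are not aligned to the same cell set")
    return ref


def consensus_vote(maps: Sequence[BinaryMap]) -> ConsensusMap:
    """Per-cell presence iff strictly more than half the members vote presence."""
    if not maps:
        raise ValidationError("need at least one map")
    cell_id = _check_aligned(maps)
    votes = np.stack([m.presence for m in maps])
    counts = votes.sum(axis=0)
    n = len(maps)
    presence = (2 * counts > n).astype(int)  # integer compare: exact ties -> absence
    return ConsensusMap(
        cell_id=cell_id.copy(),
        presence=presence,
        provenance={"rule": "majority>0.5", "n_members": n},
        vote_fraction=counts / n,
        ensemble_members=[dict(m.provenance) for m in maps],
    )


def coincidence_rate(a: BinaryMap, b: BinaryMap) -> float:
    """Fraction of cells on which two binary maps agree."""
    _check_aligned([a, b])
    return float(np.mean(a.presence == b.presence))
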