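"""Proton-transfer order parameter and state classification.

The collective variable s(r) tracks proton transfer from a carboxylic
acid to a surrounding water cluster.  While any acid oxygen has a
reactive hydrogen within the protonation threshold (1.4 Å by default)
the acid is considered protonated and s is simply that minimum O–H
distance.  Once the proton has left, each reactive hydrogen is assigned
to its nearest oxygen; a water oxygen holding exactly three hydrogens
marks the hydronium, and s becomes the minimum distance from the acid
oxygens to the hydrogens of any such triply coordinated oxygen.  A
change in the identity of the hydronium oxygen therefore produces a
discontinuous jump in s — deliberately so: the jump distinguishes
contact ion pairs from separated, Zundel-like product structures.

State A (protonated) is s below ``stateA_bound``; state B (charge
separated product) is s above ``stateB_bound``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .trajio import Frame, PathRecord

__all__ = [
    "ColvarConfig",
    "StateLabel",
    "ColvarError",
    "min_acid_OH_distance",
    "assign_hydrogens",
    "order_parameter",
    "classify_state",
    "segment_trajectory",
]

log = logging.getLogger(__name__)


class ColvarError(ValueError):
    """Configuration or geometry error in the collective variable."""


class StateLabel(str, Enum):
    A = "A"
    B = "B"
    INTERMEDIATE = "intermediate"


@dataclass
class ColvarConfig:
    """Atom-index sets and thresholds defining s(r).

    Parameters
    ----------
    acid_oxygen_indices
        Indices of the acid's two oxygens.
    reactive_hydrogen_indices
        Every hydrogen that can take part in the transfer — all H in the
        system except the acid's C-bound hydrogen.
    protonation_threshold
        O–H distance (Å) below which the acid counts as protonated;
        default 1.4.
    stateA_bound, stateB_bound
        s(r) bounds (Å) defining the initial state A and product state B.
    """

    acid_oxygen_indices: frozenset[int]
    reactive_hydrogen_indices: frozenset[int]
    protonation_threshold: float = 1.4
    stateA_bound: float = 1.05
    stateB_bound: float = 3.0

    def __post_init__(self) -> None:
        self.acid_oxygen_indices = frozenset(int(i) for i in self.acid_oxygen_indices)
        self.reactive_hydrogen_indices = frozenset(
            int(i) for i in self.reactive_hydrogen_indices
        )
        if not self.acid_oxygen_indices or not self.reactive_hydrogen_indices:
            raise ColvarError("acid oxygen and reactive hydrogen index sets must be nonempty")
        if self.acid_oxygen_indices & self.reactive_hydrogen_indices:
            raise ColvarError("acid oxygen and reactive hydrogen sets must be disjoint")
        if not (0 < self.stateA_bound < self.stateB_bound):
            raise ColvarError("need 0 < stateA_bound < stateB_bound")
        if not (self.stateA_bound < self.protonation_threshold < self.stateB_bound):
            raise ColvarError("protonation_threshold must lie between the state bounds")

    def validate_frame(self, frame: Frame) -> None:
        m = frame.n_atoms
        for i in self.acid_oxygen_indices | self.reactive_hydrogen_indices:
            if not 0 <= i < m:
                raise ColvarError(f"atom index {i} out of range for {m}-atom frame")


def _oxygen_indices(frame: Frame) -> np.ndarray:
    return np.flatnonzero(np.asarray(frame.elements) == np.array("O"))


def min_acid_OH_distance(frame: Frame, cfg: ColvarConfig) -> float:
    """Smallest acid-oxygen / reactive-hydrogen distance (Å)."""
    cfg.validate_frame(frame)
    o = sorted(cfg.acid_oxygen_indices)
    h = sorted(cfg.reactive_hydrogen_indices)
    return float(cdist(frame.coords[o], frame.coords[h]).min())


def assign_hydrogens(frame: Frame, cfg: ColvarConfig) -> dict[int, int]:
    """Map each reactive hydrogen to its nearest oxygen (acid or water).

    Exact distance ties go to the lowest oxygen atom index (argmin over
    oxygens enumerated in ascending index order).
    """
    cfg.validate_frame(frame)
    ox = _oxygen_indices(frame)
    if ox.size == 0:
        raise ColvarError("frame contains no oxygen")
    h = np.array(sorted(cfg.reactive_hydrogen_indices))
    d = cdist(frame.coords[h], frame.coords[ox])  # (n_h, n_o), oxygens ascending
    nearest = ox[np.argmin(d, axis=1)]  # argmin returns first minimum -> lowest index
    return {int(hi): int(oi) for hi, oi in zip(h, nearest)}


def order_parameter(frame: Frame, cfg: ColvarConfig) -> float:
    """Evaluate s(r) for one frame (Å).

    Falls back to the plain minimum O–H distance when no oxygen is
    triply coordinated (geometry between the protonated and separated
    regimes); this keeps the series defined and conservative.
    """
    r_min = min_acid_OH_distance(frame, cfg)
    if r_min < cfg.protonation_threshold:
        return r_min
    assignment = assign_hydrogens(frame, cfg)
    counts: dict[int, list[int]] = {}
    for hi, oi in assignment.items():
        counts.setdefault(oi, []).append(hi)
    acid_o = sorted(cfg.acid_oxygen_indices)
    hydronium_h: list[int] = []
    for oi, his in counts.items():
        if oi in cfg.acid_oxygen_indices:
            continue  # only *water* oxygens can mark the hydronium
        if len(his) == 3:
            hydronium_h.extend(his)
    if not hydronium_h:
        log.debug("no triply coordinated water oxygen; falling back to r_min=%.3f", r_min)
        return r_min
    d = cdist(frame.coords[acid_o], frame.coords[sorted(hydronium_h)])
    return float(d.min())


def classify_state(s: float, cfg: ColvarConfig) -> StateLabel:
    """A if s < stateA_bound, B if s > stateB_bound, else intermediate."""
    if s < 0:
        raise ColvarError(f"order parameter must be nonnegative, got {s}")
    if s < cfg.stateA_bound:
        return StateLabel.A
    if s > cfg.stateB_bound:
        return StateLabel.B
    return StateLabel.INTERMEDIATE


def segment_trajectory(
    frames: Sequence[Frame],
    cfg: ColvarConfig,
    mode: str = "AB",
    path_id_prefix: str = "seg",
) -> list[PathRecord]:
    """Cut a long trajectory into reactive / unreactive excursions.

    An excursion starts at the last frame inside the origin state before
    the trajectory leaves it and ends at the first frame inside whichever
    state is touched next.  Excursions that reach the far state are
    reactive; those that return to the origin state are unreactive.
    Leading or trailing stretches that never complete an excursion are
    dropped.

    ``mode`` selects the origin state: "AB" (default, excursions out of
    A) or "BA" (the symmetric study).
    """
    if mode not in ("AB", "BA"):
        raise ValueError("mode must be 'AB' or 'BA'")
    origin = StateLabel.A if mode == "AB" else StateLabel.B
    target = StateLabel.B if mode == "AB" else StateLabel.A
    states = [classify_state(order_parameter(f, cfg), cfg) for f in frames]
    if origin not in states:
        log.warning("trajectory never enters state %s: no segments", origin.value)
        return []
    records: list[PathRecord] = []
    start: int | None = None  # index of last origin-state frame seen
    for i, st in enumerate(states):
        if st == origin:
            if start is not None and i > start + 1:
                # excursion returned to origin without touching target
                records.append(_make_segment(frames, start, i, "unreactive",
                                             path_id_prefix, len(records)))
            start = i
        elif st == target and start is not None:
            records.append(_make_segment(frames, start, i, "reactive",
                                         path_id_prefix, len(records)))
            start = None  # wait until the trajectory re-enters the origin state
    return records


def _make_segment(frames, start, end, label, prefix, order) -> PathRecord:
    seg = [
        Frame(f.elements, f.coords.copy(),
              None if f.velocities is None else f.velocities.copy(), k)
        for k, f in enumerate(frames[start : end + 1])
    ]
    return PathRecord(
        frames=seg,
        label=label,
        path_id=f"{prefix}{order:04d}",
        generation_order=order,
    )
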