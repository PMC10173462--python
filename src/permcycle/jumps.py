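"""Net ion-jump bookkeeping, permeation events, and current.

The pore axis is partitioned into eight compartments indexed by *level*:

    0 intracellular  1 Scav  2 S4  3 S3  4 S2  5 S1  6 S0  7 extracellular

A complete inward->outward traversal crosses N_b = 7 boundaries.  For each
ion and each pair of adjacent frames the signed level difference is added
to a cumulative jump count J(t); forward and backward crossings cancel, so
J = 7 x (number of completed permeations) on purely forward traffic.  The
single-channel current follows as

    I = e * J / (N_b * T)

with e the elementary charge and T the trajectory duration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .occupancy import StateTrajectory

__all__ = [
    "N_BOUNDARIES",
    "ELEMENTARY_CHARGE",
    "JumpTrace",
    "PermeationEvent",
    "levels_from_z",
    "site_to_level",
    "count_jumps",
    "compute_current",
    "detect_permeation_events",
    "events_from_jumps",
    "count_crossings",
]

N_BOUNDARIES = 7  # boundary crossings per complete permeation
ELEMENTARY_CHARGE = 1.602176634e-19  # C

_LEVEL_IC = 0
_LEVEL_EC = 7


def site_to_level(site: int) -> int:
    """Map a site index (0=S0 .. 5=Scav) to its compartment level."""
    return 6 - site


def levels_from_z(z, planes) -> np.ndarray:
    """Compartment levels from z alone (1-D bookkeeping, no radial cutoff).

    ``planes`` are the 7 boundary z-levels in decreasing order (S0 upper
    first).  z above the top plane -> 7 (extracellular); z at or below the
    bottom plane -> 0 (intracellular); otherwise the enclosing site's
    level.  Binning by z only avoids spurious jump resets when an ion
    grazes the radial cutoff wall.
    """
    z = np.atleast_1d(np.asarray(z, dtype=float))
    planes = np.asarray(planes, dtype=float)
    # planes descend; count planes at or above z (upper-inclusive convention)
    above = np.searchsorted(-planes, -z, side="right")
    return (_LEVEL_EC - above).astype(float)


@dataclass
class JumpTrace:
    """Cumulative net ion-jump trace of one trajectory."""

    cumulative_jumps: np.ndarray  # (n_frames,) int
    total_time: float  # ns
    boundaries_per_permeation: int = N_BOUNDARIES

    def __post_init__(self) -> None:
        self.cumulative_jumps = np.asarray(self.cumulative_jumps, dtype=int)

    @property
    def total_jumps(self) -> int:
        return int(self.cumulative_jumps[-1]) if len(self.cumulative_jumps) else 0

    @property
    def permeation_count(self) -> int:
        """Completed forward permeations (floor; only defined for J >= 0)."""
        if self.total_jumps < 0:
            raise ValueError("permeation_count undefined for net-backward traffic")
        return self.total_jumps // self.boundaries_per_permeation


@dataclass
class PermeationEvent:
    """One ion crossing to the extracellular side.

    ``start_frame``/``end_frame`` span the anchored cycle once
    :func:`permcycle.cycles.extract_cycles` has run; before that they hold
    the ion's filter-entry frame and the crossing frame.
    """

    ion_id: int | None
    crossing_frame: int
    start_frame: int
    end_frame: int
    state_sequence: list[str] = field(default_factory=list)
    jump_offsets: np.ndarray | None = None
    traj: StateTrajectory | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "ion_id": self.ion_id,
            "start_frame": int(self.start_frame),
            "end_frame": int(self.end_frame),
            "crossing_frame": int(self.crossing_frame),
            "state_sequence": list(self.state_sequence),
        }


def count_jumps(levels, frame_interval: float) -> JumpTrace:
    """Cumulative net jump trace from per-ion compartment levels.

    ``levels`` is (n_frames, n_ions); NaN marks an ion absent from the
    frame (e.g. a periodic-image artifact).  A vanished ion's contribution
    is frozen until it is next seen in a bulk compartment (0 or 7).
    """
    lv = np.asarray(levels, dtype=float)
    if lv.ndim == 1:
        lv = lv[:, None]
    n_frames, n_ions = lv.shape
    cum = np.zeros(n_frames, dtype=int)
    if n_frames == 0:
        return JumpTrace(cum, 0.0)

    finite = np.isfinite(lv)
    if finite.all():
        diffs = np.diff(lv, axis=0).sum(axis=1)
        cum[1:] = np.cumsum(diffs).round().astype(int)
    else:
        warnings.warn("ion disappeared mid-trajectory; its jumps are frozen "
                      "until re-entry from a bulk compartment", stacklevel=2)
        last = lv[0].copy()
        valid = finite[0].copy()
        total = 0
        for t in range(1, n_frames):
            for i in range(n_ions):
                if not finite[t, i]:
                    valid[i] = False
                    continue
                if valid[i]:
                    total += int(lv[t, i] - last[i])
                    last[i] = lv[t, i]
                elif lv[t, i] in (_LEVEL_IC, _LEVEL_EC):
                    valid[i] = True  # re-entered from bulk; resume
                    last[i] = lv[t, i]
            cum[t] = total

    total_time_ns = (n_frames - 1) * frame_interval / 1000.0
    return JumpTrace(cum, total_time_ns)


def compute_current(trace: JumpTrace) -> float:
    """Single-channel current in pA: I = e * J / (N_b * T).

    Positive current is intracellular -> extracellular flux (the positive
    membrane-voltage convention).
    """
    if trace.total_time <= 0:
        raise ValueError("total_time must be positive")
    amps = ELEMENTARY_CHARGE * trace.total_jumps / (
        trace.boundaries_per_permeation * trace.total_time * 1e-9
    )
    return amps * 1e12


def _entry_sides(levels: np.ndarray) -> np.ndarray:
    """Initial bulk side per ion: 'EC' if starting extracellular, else 'IC'.

    Ions occupying the filter at frame 0 carry no history; under the
    positive-voltage assumption they are treated as having entered from
    the intracellular side.
    """
    first = levels[0]
    return np.where(first == _LEVEL_EC, "EC", "IC")


def detect_permeation_events(state_traj: StateTrajectory, levels,
                             ion_ids=None) -> list[PermeationEvent]:
    """Permeation events from per-ion compartment traces.

    An event fires when an ion arrives in the extracellular compartment
    having last come from the intracellular side (directly or through the
    filter).  Re-exits of ions that entered from the extracellular side do
    not count.  Events are non-overlapping in their defining ion.
    """
    lv = np.asarray(levels, dtype=float)
    if lv.ndim == 1:
        lv = lv[:, None]
    n_frames, n_ions = lv.shape
    if len(state_traj) != n_frames:
        raise ValueError("state trajectory and level traces are not aligned")
    if ion_ids is None:
        ion_ids = list(range(n_ions))

    events: list[PermeationEvent] = []
    sides = _entry_sides(lv)
    for i in range(n_ions):
        side = sides[i]
        entry_frame = 0
        in_filter = lv[0, i] not in (_LEVEL_IC, _LEVEL_EC)
        for t in range(1, n_frames):
            level = lv[t, i]
            if not np.isfinite(level):
                continue
            if level == _LEVEL_IC:
                side, in_filter = "IC", False
            elif level == _LEVEL_EC:
                if side == "IC" and in_filter:
                    events.append(PermeationEvent(
                        ion_id=ion_ids[i], crossing_frame=t,
                        start_frame=entry_frame, end_frame=t,
                        traj=state_traj))
                side, in_filter = "EC", False
            else:
                if not in_filter:
                    entry_frame = t
                in_filter = True
    events.sort(key=lambda e: e.crossing_frame)
    return events


def events_from_jumps(state_traj: StateTrajectory,
                      n_boundaries: int = N_BOUNDARIES) -> list[PermeationEvent]:
    """Permeation events from the cumulative jump trace alone.

    Used when only a state-sequence file (no per-ion coordinates) is
    available: one event is recorded each time the running maximum of the
    jump trace advances by another ``n_boundaries``, i.e. each time one
    full charge has effectively crossed the filter.
    """
    j = state_traj.jumps
    events: list[PermeationEvent] = []
    running_max = j[0]
    threshold = j[0] + n_boundaries
    last = 0
    for t in range(1, len(j)):
        if j[t] > running_max:
            running_max = j[t]
            while running_max >= threshold:
                events.append(PermeationEvent(
                    ion_id=None, crossing_frame=t, start_frame=last,
                    end_frame=t, traj=state_traj))
                last = t
                threshold += n_boundaries
    return events


def count_crossings(levels) -> int:
    """Number of particles reaching the extracellular side from within.

    Works for waters as well as ions (used for the water-copermeation
    ratio); the same entry-side convention as event detection applies.
    """
    lv = np.asarray(levels, dtype=float)
    if lv.ndim == 1:
        lv = lv[:, None]
    if lv.shape[0] == 0:
        return 0
    n = 0
    sides = _entry_sides(lv)
    for i in range(lv.shape[1]):
        side = sides[i]
        in_filter = lv[0, i] not in (_LEVEL_IC, _LEVEL_EC)
        for t in range(1, lv.shape[0]):
            level = lv[t, i]
            if not np.isfinite(level):
                continue
            if level == _LEVEL_IC:
                side, in_filter = "IC", False
            elif level == _LEVEL_EC:
                if side == "IC" and in_filter:
                    n += 1
                side, in_filter = "EC", False
            else:
                in_filter = True
    return n
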