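"""Six-character occupancy coding of selectivity-filter snapshots.

Each frame is summarized by one character per binding site, ordered
S0 S1 S2 S3 S4 Scav:

    K  at least one K+ ion in the site
    W  at least one water (oxygen) in the site
    C  co-occupation: ion(s) and water(s) simultaneously
    0  empty

A particle belongs to a site when its z lies between the site's boundary
planes (upper-inclusive, lower-exclusive) and it sits within a radial
cutoff (4 Å by default) of the site's local oxygen-ring axis.  Multiple
ions in one site still code 'K' — the alphabet carries no multiplicity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .filter_geometry import (
    SITE_NAMES,
    FilterDefinition,
    SiteBoundaries,
    compute_boundaries,
)

__all__ = [
    "CODE_RE",
    "StateTrajectory",
    "assign_site",
    "assign_sites",
    "encode_frame",
    "encode_trajectory",
    "occupancy_fractions",
    "validate_code",
]

CODE_RE = re.compile(r"^[KWC0]{6}$")

#: Default MDAnalysis selections for K+ ions and water oxygens.
ION_SELECTION = "resname K K+ POT KA"
WATER_O_SELECTION = "(resname SOL TIP3 TIP3P WAT HOH SPC) and (name OW OH2 O)"


def validate_code(code: str) -> str:
    if not CODE_RE.match(code):
        raise ValueError(f"invalid occupancy code {code!r}")
    return code


@dataclass
class StateTrajectory:
    """Timed occupancy-state sequence with the cumulative ion-jump trace.

    ``jumps[t]`` is the net number of ion boundary crossings accumulated up
    to frame ``t`` (it may decrease under backward motion).
    """

    states: list[str]
    frame_interval: float  # ps per frame
    jumps: np.ndarray = None
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        self.states = [validate_code(s) for s in self.states]
        if self.jumps is None:
            self.jumps = np.zeros(len(self.states), dtype=int)
        self.jumps = np.asarray(self.jumps, dtype=int)
        if len(self.states) != len(self.jumps):
            raise ValueError("states and jumps must have equal length")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def duration_ns(self) -> float:
        """Elapsed time between the first and last frame, in ns."""
        return (len(self.states) - 1) * self.frame_interval / 1000.0


def assign_site(position, boundaries: SiteBoundaries):
    """Site index in 0..5 (S0..Scav) for one particle, or None.

    Axial rule is half-open, upper-inclusive: ``z_lower < z <= z_upper``;
    a particle exactly on the S2/S3 divider therefore belongs to S3.
    """
    x, y, z = float(position[0]), float(position[1]), float(position[2])
    inside = (boundaries.z_lower < z) & (z <= boundaries.z_upper)
    for k in np.flatnonzero(inside):
        dx = x - boundaries.axis_center[k, 0]
        dy = y - boundaries.axis_center[k, 1]
        if dx * dx + dy * dy <= boundaries.radial_cutoff ** 2:
            return int(k)
    return None


def assign_sites(positions, boundaries: SiteBoundaries) -> np.ndarray:
    """Vectorized :func:`assign_site`: (n, 3) positions -> (n,) site or -1."""
    pos = np.asarray(positions, dtype=float).reshape(-1, 3)
    out = np.full(len(pos), -1, dtype=int)
    if len(pos) == 0:
        return out
    z = pos[:, 2]
    for k in range(6):
        mask = (boundaries.z_lower[k] < z) & (z <= boundaries.z_upper[k]) & (out < 0)
        if not mask.any():
            continue
        d2 = ((pos[mask, :2] - boundaries.axis_center[k]) ** 2).sum(axis=1)
        sel = np.flatnonzero(mask)[d2 <= boundaries.radial_cutoff ** 2]
        out[sel] = k
    return out


def encode_frame(ion_positions, water_positions, boundaries: SiteBoundaries) -> str:
    """Occupancy code for one frame from ion and water-oxygen positions."""
    ion_sites = assign_sites(ion_positions, boundaries)
    wat_sites = assign_sites(water_positions, boundaries)
    chars = []
    for k in range(6):
        has_ion = np.any(ion_sites == k)
        has_wat = np.any(wat_sites == k)
        chars.append("C" if (has_ion and has_wat) else "K" if has_ion else
                     "W" if has_wat else "0")
    return "".join(chars)


def encode_trajectory(universe, fdef: FilterDefinition, *,
                      ion_selection: str = ION_SELECTION,
                      water_selection: str = WATER_O_SELECTION,
                      frame_interval: float | None = None,
                      radial_cutoff: float = 4.0,
                      source_id: str = "",
                      return_levels: bool = False):
    """Encode every frame of a trajectory into a :class:`StateTrajectory`.

    Boundaries are recomputed per frame from the filter oxygens.  The
    cumulative ion-jump trace is attached from a 1-D compartment
    bookkeeping of every selected ion (see :mod:`permcycle.jumps`).

    With ``return_levels=True`` also returns the per-frame, per-ion
    compartment level matrix and the ion ids, plus the water level matrix
    (used for permeation-event detection and water-copermeation counts).
    """
    from . import jumps as _jumps

    ions = universe.select_atoms(ion_selection)
    waters = universe.select_atoms(water_selection)
    n_frames = len(universe.trajectory)
    if n_frames == 0:
        raise ValueError("trajectory has zero frames")

    if frame_interval is None:
        dt = getattr(universe.trajectory, "dt", None)
        frame_interval = float(dt) if dt else 1.0

    codes: list[str] = []
    ion_levels = np.empty((n_frames, len(ions)), dtype=float)
    wat_levels = np.empty((n_frames, len(waters)), dtype=float)
    for i, ts in enumerate(universe.trajectory):
        try:
            bnd = compute_boundaries(universe.atoms.positions, fdef,
                                     frame_index=i, radial_cutoff=radial_cutoff)
            codes.append(encode_frame(ions.positions, waters.positions, bnd))
        except Exception as exc:
            raise RuntimeError(f"failed to encode frame {i}: {exc}") from exc
        planes = bnd.planes
        ion_levels[i] = _jumps.levels_from_z(ions.positions[:, 2], planes)
        wat_levels[i] = _jumps.levels_from_z(waters.positions[:, 2], planes)

    trace = _jumps.count_jumps(ion_levels, frame_interval)
    traj = StateTrajectory(states=codes, frame_interval=frame_interval,
                           jumps=trace.cumulative_jumps, source_id=source_id)
    if return_levels:
        ion_ids = [int(a.ix) for a in ions]
        return traj, ion_levels, ion_ids, wat_levels
    return traj


def occupancy_fractions(traj: StateTrajectory):
    """Per-site ion and water occupancy fractions.

    The ion fraction of a site is the fraction of frames coded 'K' or 'C'
    there; the water fraction counts 'W' or 'C'.  These are the standard
    per-site occupancy summaries plotted for SF binding sites.
    """
    import pandas as pd

    n = len(traj.states)
    arr = np.array([list(s) for s in traj.states])
    rows = []
    for k, name in enumerate(SITE_NAMES):
        col = arr[:, k]
        rows.append(
            {
                "site": name,
                "ion_fraction": float(np.mean((col == "K") | (col == "C"))),
                "water_fraction": float(np.mean((col == "W") | (col == "C"))),
            }
        )
    return pd.DataFrame(rows).set_index("site")
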