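"""Ground-truth fixture factory: planted permeation trajectories.

Two mechanisms are emulated at the level of particle bookkeeping in a
rigid model filter (static boundary planes; no forces, no membrane):

* **direct knock-on** — the dominant dry-filter loop

      WKK0KW -> C0K0KW -> C0K0KC -> C0KKWC -> C0KK0C -> CK0KKW -> WKK0KW

  in which S2/S3 never hold water and each loop conducts exactly one ion
  (7 net boundary crossings), with no water copermeation;

* **soft knock-on** — an alternating ion/water column

      WKWKWK <-> KWKWKW

  shifting up one site at a time; every two shifts eject one ion *and*
  one water (1:1 copermeation), again 7 net ion jumps per permeation.

The generator returns per-frame coordinates of every ion and water oxygen
(reservoir particles included) together with the exact ground truth:
occupancy-state sequence, cumulative jump trace, and planted event list.
Positional jitter sigma is applied to particles only; the filter is kept
rigid so that analysis-code correctness is isolated from geometry noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .filter_geometry import SiteBoundaries
from .jumps import PermeationEvent, site_to_level
from .occupancy import StateTrajectory

__all__ = [
    "SyntheticConfig",
    "SyntheticTrajectory",
    "generate_markov_sequence",
    "generate_knockon_trajectory",
    "generate_filter_fixture",
    "DIRECT_KNOCKON_LOOP",
    "SOFT_KNOCKON_LOOP",
]

DIRECT_KNOCKON_LOOP = ("WKK0KW", "C0K0KW", "C0K0KC", "C0KKWC", "C0KK0C", "CK0KKW")
SOFT_KNOCKON_LOOP = ("WKWKWK", "KWKWKW")

#: Static boundary plane z-levels of the rigid model filter (Å), S0 upper
#: first; site heights of 3.1 Å matching typical carbonyl-ring spacings.
MODEL_PLANES = np.array([15.5, 12.4, 9.3, 6.2, 3.1, 0.0, -4.0])

_Z_IC = -10.0  # intracellular reservoir
_Z_EC = 20.0  # extracellular reservoir
_RING_RADIUS = 3.0  # oxygen ring radius of the model filter (Å)


@dataclass
class SyntheticConfig:
    """Study conditions of one synthetic run."""

    mechanism: str = "direct_knockon"  # or "soft_knockon"
    n_permeations: int = 50
    n_frames: int | None = None  # total frames; None -> 5 frames per state
    frame_interval: float = 20.0  # ps
    seed: int = 0
    anchor_state: str | None = None  # default: the loop's first state
    noise: float = 0.3  # positional jitter sigma (Å)
    water_copermeation: bool | None = None  # fixed by the mechanism

    def __post_init__(self) -> None:
        if self.mechanism not in ("direct_knockon", "soft_knockon"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.n_permeations < 0:
            raise ValueError("n_permeations must be >= 0")
        loop = DIRECT_KNOCKON_LOOP if self.mechanism == "direct_knockon" else SOFT_KNOCKON_LOOP
        if self.anchor_state is None:
            self.anchor_state = loop[0]
        coperm = self.mechanism == "soft_knockon"
        if self.water_copermeation is None:
            self.water_copermeation = coperm
        elif self.water_copermeation != coperm:
            raise ValueError("water_copermeation is fixed by the mechanism")

    @property
    def loop(self) -> tuple[str, ...]:
        loop = DIRECT_KNOCKON_LOOP if self.mechanism == "direct_knockon" else SOFT_KNOCKON_LOOP
        i = loop.index(self.anchor_state)
        return loop[i:] + loop[:i]


@dataclass
class SyntheticTrajectory:
    """Coordinates plus exact ground truth of one planted run."""

    config: SyntheticConfig
    state_traj: StateTrajectory  # ground-truth states + cumulative jumps
    events: list[PermeationEvent]
    ion_positions: np.ndarray  # (n_frames, n_ions, 3) Å
    water_positions: np.ndarray  # (n_frames, n_waters, 3) Å
    ion_ids: list[int]
    water_ids: list[int]
    boundaries: SiteBoundaries
    ion_levels: np.ndarray = field(repr=False, default=None)
    water_levels: np.ndarray = field(repr=False, default=None)

    @property
    def total_jumps(self) -> int:
        return int(self.state_traj.jumps[-1])

    def to_universe(self):
        """Merge the rigid filter fixture with the mobile particles into a
        single in-memory MDAnalysis Universe (one frame per generated frame)."""
        import MDAnalysis as mda
        from MDAnalysis.coordinates.memory import MemoryReader

        filt = generate_filter_fixture()
        n_f = len(filt.atoms)
        n_i = self.ion_positions.shape[1]
        n_w = self.water_positions.shape[1]
        n_frames = self.ion_positions.shape[0]

        ions = mda.Universe.empty(n_i, n_residues=n_i, atom_resindex=np.arange(n_i),
                                  residue_segindex=np.zeros(n_i, dtype=int),
                                  trajectory=True)
        ions.add_TopologyAttr("names", ["K"] * n_i)
        ions.add_TopologyAttr("resnames", ["K"] * n_i)
        ions.add_TopologyAttr("resids", np.arange(1, n_i + 1))
        ions.add_TopologyAttr("masses", [39.0983] * n_i)
        ions.add_TopologyAttr("segids", ["I"])

        wat = mda.Universe.empty(n_w, n_residues=n_w, atom_resindex=np.arange(n_w),
                                 residue_segindex=np.zeros(n_w, dtype=int),
                                 trajectory=True)
        wat.add_TopologyAttr("names", ["OW"] * n_w)
        wat.add_TopologyAttr("resnames", ["SOL"] * n_w)
        wat.add_TopologyAttr("resids", np.arange(1, n_w + 1))
        wat.add_TopologyAttr("masses", [15.999] * n_w)
        wat.add_TopologyAttr("segids", ["X"])

        merged = mda.Merge(filt.atoms, ions.atoms, wat.atoms)
        coords = np.empty((n_frames, n_f + n_i + n_w, 3), dtype=np.float32)
        coords[:, :n_f] = filt.atoms.positions[None, :, :]
        coords[:, n_f:n_f + n_i] = self.ion_positions
        coords[:, n_f + n_i:] = self.water_positions
        merged.load_new(coords, format=MemoryReader, dt=self.config.frame_interval)
        return merged

    def write_files(self, outdir):
        """Write topology.pdb + traj.xtc (plus ground-truth sidecars)."""
        import json
        import os

        from . import io as pio

        os.makedirs(outdir, exist_ok=True)
        u = self.to_universe()
        top = os.path.join(outdir, "topology.pdb")
        xtc = os.path.join(outdir, "traj.xtc")
        u.atoms.write(top)
        import MDAnalysis as mda

        with mda.Writer(xtc, n_atoms=len(u.atoms)) as w:
            for _ in u.trajectory:
                w.write(u.atoms)
        pio.write_states(os.path.join(outdir, "states.tsv"), self.state_traj)
        with open(os.path.join(outdir, "events.json"), "w") as fh:
            json.dump([e.to_dict() for e in self.events], fh, indent=2)
        return top, xtc


def generate_markov_sequence(T, n_steps: int, seed: int | None = None, *,
                             states: list[str] | None = None,
                             jump_map: dict | None = None,
                             frame_interval: float = 20.0,
                             start: int = 0,
                             source_id: str = "markov") -> StateTrajectory:
    """Sample a state sequence exactly from a row-stochastic matrix.

    ``jump_map`` optionally assigns a per-visit jump increment to each
    state (default 0 everywhere); the cumulative sum becomes the jump
    trace, letting tests plant arbitrary jump structure.
    """
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1] or np.any(T < 0) or \
            not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("matrix is not row-stochastic")
    n = T.shape[0]
    if states is None:
        # valid occupancy codes whose lexicographic order matches the
        # matrix index order (ASCII: '0' < 'C' < 'K' < 'W')
        alphabet = "0CKW"
        states = []
        for a in alphabet:
            for b in alphabet:
                states.append(a + b + "K0KW")
                if len(states) == n:
                    break
            if len(states) == n:
                break
        if len(states) < n:
            raise ValueError("too many states for the default code pool")
    rng = np.random.default_rng(seed)
    cdf = np.cumsum(T, axis=1)
    seq = np.empty(n_steps, dtype=np.int64)
    u = rng.random(n_steps)
    s = start
    for t in range(n_steps):
        seq[t] = s
        s = int(np.searchsorted(cdf[s], u[t], side="right"))
        s = min(s, n - 1)
    codes = [states[k] for k in seq]
    jumps = None
    if jump_map:
        inc = np.array([jump_map.get(states[k], 0) for k in seq])
        jumps = np.cumsum(inc)
    return StateTrajectory(states=codes, frame_interval=frame_interval,
                           jumps=jumps, source_id=source_id)


class _Particles:
    """Mutable site bookkeeping for the scripted mechanisms."""

    def __init__(self, n_ions: int, n_waters: int):
        self.ion_site: list = ["IC"] * n_ions  # 'IC', 'EC', or site 0..5
        self.wat_site: list = ["IC"] * n_waters
        self.ion_pool = list(range(n_ions))  # IC queue, FIFO
        self.wat_pool = list(range(n_waters))

    def place_ion(self, ion, site):
        self.ion_site[ion] = site

    def ions_at(self, site):
        return [i for i, s in enumerate(self.ion_site) if s == site]

    def waters_at(self, site):
        return [i for i, s in enumerate(self.wat_site) if s == site]

    def next_ion(self):
        return self.ion_pool.pop(0)

    def next_water(self):
        return self.wat_pool.pop(0)


def _positions(site, idx, queue_rank, rng, sigma):
    """Coordinates for one particle given its compartment."""
    if site == "IC":
        base = np.array([0.0, 0.0, _Z_IC - 2.0 * queue_rank])
    elif site == "EC":
        base = np.array([0.0, 0.0, _Z_EC + 2.0 * queue_rank])
    else:
        centers_z = (MODEL_PLANES[site] + MODEL_PLANES[site + 1]) / 2.0
        angle = 2.094395 * idx  # spread co-occupants azimuthally
        base = np.array([0.5 * np.cos(angle), 0.5 * np.sin(angle), centers_z])
    if sigma > 0:
        return base + rng.normal(0.0, sigma, 3)
    return base


def _code_from_sites(p: _Particles) -> str:
    chars = []
    for k in range(6):
        has_i = bool(p.ions_at(k))
        has_w = bool(p.waters_at(k))
        chars.append("C" if has_i and has_w else "K" if has_i else
                     "W" if has_w else "0")
    return "".join(chars)


def _direct_step(p: _Particles, step: int):
    """Apply one transition of the direct knock-on loop; return moved ions
    as (ion, old_site, new_site) plus any water moves."""
    moves = []
    if step == 0:  # WKK0KW -> C0K0KW: ion S1 -> S0
        ion = p.ions_at(1)[0]
        moves.append((ion, 1, 0))
    elif step == 1:  # -> C0K0KC: new ion IC -> Scav
        ion = p.next_ion()
        moves.append((ion, "IC", 5))
    elif step == 2:  # -> C0KKWC: ion S4 -> S3; one Scav water -> S4
        ion = p.ions_at(4)[0]
        moves.append((ion, 4, 3))
        w = p.waters_at(5)[0]
        p.wat_site[w] = 4
    elif step == 3:  # -> C0KK0C: water S4 -> Scav
        w = p.waters_at(4)[0]
        p.wat_site[w] = 5
    elif step == 4:  # -> CK0KKW: ion S2 -> S1; ion Scav -> S4
        moves.append((p.ions_at(2)[0], 2, 1))
        moves.append((p.ions_at(5)[0], 5, 4))
    elif step == 5:  # -> WKK0KW: ion S0 -> EC; ion S3 -> S2
        moves.append((p.ions_at(0)[0], 0, "EC"))
        moves.append((p.ions_at(3)[0], 3, 2))
    for ion, _old, new in moves:
        p.ion_site[ion] = new
    return moves


def _soft_step(p: _Particles, step: int):
    """One concerted column shift of the soft knock-on mechanism."""
    moves, wmoves = [], []
    # every filter occupant moves up one site; the S0 occupant exits
    for k in (0, 1, 2, 3, 4, 5):
        for ion in p.ions_at(k):
            moves.append((ion, k, "EC" if k == 0 else k - 1))
        for w in p.waters_at(k):
            wmoves.append((w, "EC" if k == 0 else k - 1))
    # the entering particle alternates: water on even shifts, ion on odd
    if step % 2 == 0:
        wmoves.append((p.next_water(), 5))
    else:
        moves.append((p.next_ion(), "IC", 5))
    for ion, _old, new in moves:
        p.ion_site[ion] = new
    for w, new in wmoves:
        p.wat_site[w] = new
    return moves


def generate_knockon_trajectory(config: SyntheticConfig) -> SyntheticTrajectory:
    """Scripted particle trajectory with exact planted ground truth.

    Each occupancy state of the mechanism's loop is held for a fixed dwell
    (derived from ``n_frames``); particle moves happen between dwell
    blocks.  Jump counts, events, and the state sequence are recorded from
    the script itself, not re-measured, so they are exact by construction.
    """
    rng = np.random.default_rng(config.seed)
    direct = config.mechanism == "direct_knockon"
    steps_per_loop = 6 if direct else 2
    n_blocks = steps_per_loop * config.n_permeations + 1
    dwell = max(1, (config.n_frames or 5 * n_blocks) // n_blocks)
    n_frames = dwell * n_blocks

    if direct:
        n_ions = 3 + config.n_permeations
        n_waters = 3
    else:
        n_ions = 3 + config.n_permeations
        n_waters = 3 + config.n_permeations

    p = _Particles(n_ions, n_waters)
    if direct:
        # initial state WKK0KW: ions S1,S2,S4; waters S0 + 2x Scav
        for site in (1, 2, 4):
            p.ion_site[p.next_ion()] = site
        p.wat_site[p.next_water()] = 0
        p.wat_site[p.next_water()] = 5
        p.wat_site[p.next_water()] = 5
        loop_states = list(DIRECT_KNOCKON_LOOP)
        stepper = _direct_step
    else:
        # initial state WKWKWK: ions S1,S3,Scav; waters S0,S2,S4
        for site in (1, 3, 5):
            p.ion_site[p.next_ion()] = site
        for site in (0, 2, 4):
            p.wat_site[p.next_water()] = site
        loop_states = list(SOFT_KNOCKON_LOOP)
        stepper = _soft_step

    codes: list[str] = []
    jumps = np.zeros(n_frames, dtype=int)
    ion_pos = np.empty((n_frames, n_ions, 3))
    wat_pos = np.empty((n_frames, n_waters, 3))
    events: list[PermeationEvent] = []

    def _compartment_level(site):
        if site == "IC":
            return 0
        if site == "EC":
            return 7
        return site_to_level(site)

    def render(frame):
        ic_rank_i = ec_rank_i = 0
        for i, site in enumerate(p.ion_site):
            rank = 0
            if site == "IC":
                rank, ic_rank_i = ic_rank_i, ic_rank_i + 1
            elif site == "EC":
                rank, ec_rank_i = ec_rank_i, ec_rank_i + 1
            ion_pos[frame, i] = _positions(site, i, rank, rng, config.noise)
        ic_rank_w = ec_rank_w = 0
        for i, site in enumerate(p.wat_site):
            rank = 0
            if site == "IC":
                rank, ic_rank_w = ic_rank_w, ic_rank_w + 1
            elif site == "EC":
                rank, ec_rank_w = ec_rank_w, ec_rank_w + 1
            wat_pos[frame, i] = _positions(site, i, rank, rng, config.noise)

    frame = 0
    total_jumps = 0
    for block in range(n_blocks):
        state = loop_states[block % steps_per_loop]
        assert _code_from_sites(p) == state, "generator bookkeeping out of sync"
        for _ in range(dwell):
            codes.append(state)
            jumps[frame] = total_jumps
            render(frame)
            frame += 1
        if block == n_blocks - 1:
            break
        moves = stepper(p, block % steps_per_loop)
        for ion, old, new in moves:
            total_jumps += _compartment_level(new) - _compartment_level(old)
            if new == "EC":
                events.append(PermeationEvent(ion_id=ion, crossing_frame=frame,
                                              start_frame=0, end_frame=frame))

    state_traj = StateTrajectory(states=codes, frame_interval=config.frame_interval,
                                 jumps=jumps, source_id=f"synthetic-{config.mechanism}")
    for e in events:
        e.traj = state_traj

    boundaries = SiteBoundaries(
        frame_index=0,
        z_upper=MODEL_PLANES[:6],
        z_lower=MODEL_PLANES[1:],
        axis_center=np.zeros((6, 2)),
    )
    ion_levels = np.empty((n_frames, n_ions))
    wat_levels = np.empty((n_frames, n_waters))
    from .jumps import levels_from_z

    for t in range(n_frames):
        ion_levels[t] = levels_from_z(ion_pos[t, :, 2], MODEL_PLANES)
        wat_levels[t] = levels_from_z(wat_pos[t, :, 2], MODEL_PLANES)

    return SyntheticTrajectory(
        config=config, state_traj=state_traj, events=events,
        ion_positions=ion_pos, water_positions=wat_pos,
        ion_ids=list(range(n_ions)), water_ids=list(range(n_waters)),
        boundaries=boundaries, ion_levels=ion_levels, water_levels=wat_levels,
    )


def generate_filter_fixture(ring_radius: float = _RING_RADIUS):
    """Minimal rigid 4-chain TVGYG pseudo-filter as an MDAnalysis Universe.

    Each chain contributes one carbonyl O per motif residue plus the
    threonine hydroxyl O, placed on rings whose CoM z-levels equal the
    model boundary planes (site heights 3.1 Å).
    """
    import MDAnalysis as mda

    resnames = ["THR", "VAL", "GLY", "TYR", "GLY"]
    # carbonyl z per residue (T,V,G,Y,G bottom->top), then OG1 on THR
    carbonyl_z = {0: MODEL_PLANES[4], 1: MODEL_PLANES[3], 2: MODEL_PLANES[2],
                  3: MODEL_PLANES[1], 4: MODEL_PLANES[0]}
    hydroxyl_z = MODEL_PLANES[5]
    chain_xy = [(ring_radius, 0.0), (0.0, ring_radius),
                (-ring_radius, 0.0), (0.0, -ring_radius)]

    names, rnames, resids, segidx, residx, coords, masses = [], [], [], [], [], [], []
    n_res_total = 0
    for chain in range(4):
        x, y = chain_xy[chain]
        for r, resname in enumerate(resnames):
            atom_names = ["O"] + (["OG1"] if r == 0 else [])
            for an in atom_names:
                names.append(an)
                z = hydroxyl_z if an == "OG1" else carbonyl_z[r]
                coords.append([x, y, z])
                masses.append(15.999)
                residx.append(n_res_total)
            rnames.append(resname)
            resids.append(r + 1)
            segidx.append(chain)
            n_res_total += 1

    u = mda.Universe.empty(len(names), n_residues=n_res_total,
                           atom_resindex=np.array(residx),
                           residue_segindex=np.array(segidx),
                           n_segments=4, trajectory=True)
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames", rnames)
    u.add_TopologyAttr("resids", resids)
    u.add_TopologyAttr("masses", masses)
    u.add_TopologyAttr("segids", ["A", "B", "C", "D"])
    u.atoms.positions = np.array(coords, dtype=np.float32)
    return u
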