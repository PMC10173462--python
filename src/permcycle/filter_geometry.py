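"""Locate the selectivity filter and compute per-frame binding-site boundaries.

A K+ channel selectivity filter (SF) is formed by four (or two, in two-pore
channels) copies of a signature motif, canonically TVGYG, whose backbone
carbonyl oxygens and the threonine hydroxyl oxygens stack into rings along
the pore axis.  The z-coordinates of the centers of mass (CoM) of these
oxygen rings define seven boundaries enclosing six axial binding sites,
ordered extracellular to intracellular:

    S0, S1, S2, S3, S4, Scav

Boundaries 0-5 are oxygen-ring CoMs (carbonyl O of the 5th, 4th, 3rd, 2nd
and 1st motif residue, then the threonine hydroxyl O); boundary 6, the
bottom of the cavity site Scav, is a synthetic plane a fixed depth (4 Å by
default) below the hydroxyl ring.  Boundaries are recomputed every frame —
the filter breathes and no time-averaging is applied.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SITE_NAMES",
    "FilterDefinition",
    "SiteBoundaries",
    "locate_filter",
    "compute_boundaries",
    "export_selection",
]

#: Site labels ordered extracellular -> intracellular.
SITE_NAMES = ("S0", "S1", "S2", "S3", "S4", "Scav")

N_SITES = 6
N_BOUNDARY_PLANES = 7

DEFAULT_MOTIFS = ("TVGYG", "TIGYG", "TVGFG")
DEFAULT_SCAV_DEPTH = 4.0  # Å below the threonine hydroxyl ring
DEFAULT_RADIAL_CUTOFF = 4.0  # Å from the local oxygen-ring axis

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "HSD": "H",
    "HSE": "H", "HSP": "H", "HID": "H", "HIE": "H", "HIP": "H",
    "ILE": "I", "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F",
    "PRO": "P", "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y",
    "VAL": "V",
}

# Hydroxyl-oxygen atom names by residue type (threonine in all known motifs).
_HYDROXYL_NAMES = ("OG1", "OG")
_CARBONYL_NAME = "O"


@dataclass
class FilterDefinition:
    """Which atoms define each binding-site boundary.

    ``boundary_atoms[b]`` holds the integer atom indices (into the source
    topology) of the oxygen ring defining boundary plane ``b`` (0 = S0 upper,
    5 = S4/Scav divider).  Boundary 6 (Scav bottom) has no atoms; it is an
    offset plane ``scav_depth`` below boundary 5.
    """

    chains: list[str]
    filter_residues: dict[str, list[int]]  # segment label -> resids (one entry per matched segment)
    boundary_atoms: list[np.ndarray]  # length 7; last entry empty
    boundary_masses: list[np.ndarray]
    boundary_meta: list[list[dict]] = field(default_factory=list, repr=False)
    n_sites: int = N_SITES
    axis: str = "z"
    scav_depth: float = DEFAULT_SCAV_DEPTH
    s0_mode: str = "carbonyl"  # or "offset": S0 upper = S0/S1 divider + scav_depth

    def __post_init__(self) -> None:
        if len(self.boundary_atoms) != N_BOUNDARY_PLANES:
            raise ValueError(
                f"expected {N_BOUNDARY_PLANES} boundaries, got {len(self.boundary_atoms)}"
            )
        if len(self.boundary_atoms[-1]) != 0:
            raise ValueError("the Scav lower boundary must not reference atoms")

    @property
    def n_segments(self) -> int:
        """Number of matched motif copies (4 for a tetramer)."""
        return len(self.boundary_atoms[5])


@dataclass
class SiteBoundaries:
    """Per-frame axial boundaries and ring centers of the six sites.

    ``z_upper[k]``/``z_lower[k]`` bound site ``k`` (0 = S0 ... 5 = Scav);
    ``axis_center[k]`` is the (x, y) CoM of the oxygen atoms bounding the
    site, used as the local symmetry axis for the radial cutoff.
    """

    frame_index: int
    z_upper: np.ndarray  # (6,)
    z_lower: np.ndarray  # (6,)
    axis_center: np.ndarray  # (6, 2)
    radial_cutoff: float = DEFAULT_RADIAL_CUTOFF

    def __post_init__(self) -> None:
        self.z_upper = np.asarray(self.z_upper, dtype=float)
        self.z_lower = np.asarray(self.z_lower, dtype=float)
        self.axis_center = np.asarray(self.axis_center, dtype=float)
        if not np.all(self.z_upper > self.z_lower):
            raise ValueError("z_upper must exceed z_lower for every site")

    @property
    def planes(self) -> np.ndarray:
        """The 7 boundary z-levels, decreasing from S0 upper to Scav lower."""
        return np.concatenate([self.z_upper, self.z_lower[-1:]])


def _segment_sequences(universe):
    """Yield (segment_label, residues) with residues sorted by resid."""
    for seg in universe.segments:
        res = seg.residues
        order = np.argsort(res.resids, kind="stable")
        yield str(seg.segid), res[order]


def _one_letter(resname: str) -> str:
    return _THREE_TO_ONE.get(resname.upper().strip(), "X")


def _find_motif_matches(residues, patterns):
    """All non-overlapping motif matches in a residue run (by sequence)."""
    seq = "".join(_one_letter(r) for r in residues.resnames)
    hits = []
    for pat in patterns:
        start = 0
        while True:
            i = seq.find(pat, start)
            if i < 0:
                break
            hits.append((i, i + len(pat)))
            start = i + len(pat)
    # de-duplicate / drop overlapping hits from different patterns
    hits.sort()
    kept = []
    last_end = -1
    for i, j in hits:
        if i >= last_end:
            kept.append((i, j))
            last_end = j
    return kept


def locate_filter(universe, motifs=DEFAULT_MOTIFS, *, extra_motifs=(),
                  scav_depth: float = DEFAULT_SCAV_DEPTH,
                  s0_mode: str = "carbonyl") -> FilterDefinition:
    """Find the SF motif in every chain and resolve its boundary oxygens.

    Parameters
    ----------
    universe : MDAnalysis.Universe
        Topology (coordinates not required here).
    motifs : sequence of str
        One-letter residue patterns to search, first residue must be a
        threonine (its hydroxyl forms the S4/Scav divider).
    extra_motifs : sequence of str
        User-supplied patterns appended to the defaults.
    s0_mode : {"carbonyl", "offset"}
        How the S0 upper boundary is built: from the top motif residue's
        carbonyl ring (default) or as an offset plane ``scav_depth`` above
        the S0/S1 divider.

    Raises
    ------
    ValueError
        "filter not found" if fewer than two motif matches exist;
        "inconsistent filter" if matches have differing residue counts.
    """
    patterns = tuple(motifs) + tuple(extra_motifs)
    if s0_mode not in ("carbonyl", "offset"):
        raise ValueError("s0_mode must be 'carbonyl' or 'offset'")

    segments = []  # (segid, residue group of one motif match)
    filter_residues: dict[str, list[int]] = {}
    chains: list[str] = []
    for segid, residues in _segment_sequences(universe):
        for i, j in _find_motif_matches(residues, patterns):
            match = residues[i:j]
            segments.append((segid, match))
            filter_residues.setdefault(segid, []).extend(int(r) for r in match.resids)
            if segid not in chains:
                chains.append(segid)

    if len(segments) < 2:
        raise ValueError("filter not found: no selectivity-filter motif match")
    lengths = {len(match) for _, match in segments}
    if len(lengths) != 1:
        raise ValueError(f"inconsistent filter: matched segments of lengths {sorted(lengths)}")
    n_res = lengths.pop()

    # Boundary planes, extracellular -> intracellular:
    #   b0..b4: carbonyl O of residue n_res-1 .. 0 (top residue first)
    #   b5:     hydroxyl O of residue 0 (the threonine)
    #   b6:     synthetic (no atoms)
    boundary_atoms: list[list[int]] = [[] for _ in range(N_BOUNDARY_PLANES)]
    boundary_masses: list[list[float]] = [[] for _ in range(N_BOUNDARY_PLANES)]
    boundary_meta: list[list[dict]] = [[] for _ in range(N_BOUNDARY_PLANES)]

    for segid, match in segments:
        first = match[0]
        if _one_letter(first.resname) != "T":
            raise ValueError(
                "inconsistent filter: motif must start with a threonine "
                f"(got {first.resname} in segment {segid})"
            )
        for b in range(5):
            res = match[n_res - 1 - b]
            atoms = res.atoms.select_atoms(f"name {_CARBONYL_NAME}")
            if len(atoms) != 1:
                raise ValueError(
                    f"incomplete boundary: no carbonyl O in {res.resname}{res.resid} ({segid})"
                )
            _append_atom(boundary_atoms, boundary_masses, boundary_meta, b, atoms[0], segid)
        hyd = first.atoms.select_atoms("name " + " ".join(_HYDROXYL_NAMES))
        if len(hyd) != 1:
            raise ValueError(
                f"incomplete boundary: no hydroxyl O in {first.resname}{first.resid} ({segid})"
            )
        _append_atom(boundary_atoms, boundary_masses, boundary_meta, 5, hyd[0], segid)

    return FilterDefinition(
        chains=chains,
        filter_residues=filter_residues,
        boundary_atoms=[np.asarray(a, dtype=int) for a in boundary_atoms],
        boundary_masses=[np.asarray(m, dtype=float) for m in boundary_masses],
        boundary_meta=boundary_meta,
        scav_depth=scav_depth,
        s0_mode=s0_mode,
    )


def _append_atom(atoms, masses, meta, b, atom, segid):
    atoms[b].append(int(atom.ix))
    try:
        mass = float(atom.mass)
        if not np.isfinite(mass) or mass <= 0:
            mass = 15.999
    except Exception:
        mass = 15.999
    masses[b].append(mass)
    meta[b].append(
        {
            "chain": segid,
            "resname": str(atom.resname),
            "resid": int(atom.resid),
            "atom": str(atom.name),
        }
    )


def compute_boundaries(positions, fdef: FilterDefinition, *, frame_index: int = 0,
                       radial_cutoff: float = DEFAULT_RADIAL_CUTOFF) -> SiteBoundaries:
    """Boundary planes and ring centers for one frame.

    ``positions`` is the full (n_atoms, 3) coordinate array of the system
    (Å); boundary atoms are picked out by the indices stored in ``fdef``.
    Each plane's z is the mass-weighted CoM z of its oxygen ring.
    """
    positions = np.asarray(positions, dtype=float)
    n_atoms = positions.shape[0]

    plane_z = np.empty(N_BOUNDARY_PLANES)
    plane_xy = np.empty((N_BOUNDARY_PLANES, 2))
    for b in range(6):
        idx = fdef.boundary_atoms[b]
        if len(idx) == 0 and b == 0 and fdef.s0_mode == "offset":
            continue  # filled below
        if len(idx) == 0 or idx.max() >= n_atoms:
            raise ValueError(f"incomplete boundary: boundary {b} atoms missing from frame")
        coords = positions[idx]
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"incomplete boundary: non-finite coordinates at boundary {b}")
        w = fdef.boundary_masses[b]
        w = w / w.sum()
        com = w @ coords
        plane_z[b] = com[2]
        plane_xy[b] = com[:2]

    if fdef.s0_mode == "offset":
        plane_z[0] = plane_z[1] + fdef.scav_depth
        plane_xy[0] = plane_xy[1]
    plane_z[6] = plane_z[5] - fdef.scav_depth
    plane_xy[6] = plane_xy[5]

    z_upper = plane_z[:6]
    z_lower = plane_z[1:]
    # local axis of each site: CoM (x, y) of the atoms bounding it
    axis_center = np.empty((N_SITES, 2))
    for k in range(N_SITES):
        upper = fdef.boundary_atoms[k]
        lower = fdef.boundary_atoms[k + 1] if k + 1 < 6 else np.empty(0, dtype=int)
        idx = np.concatenate([upper, lower]).astype(int)
        if len(idx) == 0:
            axis_center[k] = plane_xy[k]
            continue
        w = np.concatenate(
            [fdef.boundary_masses[k],
             fdef.boundary_masses[k + 1] if k + 1 < 6 else np.empty(0)]
        )
        w = w / w.sum()
        axis_center[k] = w @ positions[idx, :2]

    if not np.all(np.diff(plane_z) < 0):
        warnings.warn(
            f"boundary planes not strictly decreasing in z at frame {frame_index}",
            stacklevel=2,
        )
    return SiteBoundaries(
        frame_index=frame_index,
        z_upper=z_upper,
        z_lower=z_lower,
        axis_center=axis_center,
        radial_cutoff=radial_cutoff,
    )


def export_selection(fdef: FilterDefinition, path) -> None:
    """Write a JSON sidecar listing chain/residue/atom per boundary."""
    doc = {
        "chains": fdef.chains,
        "n_sites": fdef.n_sites,
        "axis": fdef.axis,
        "scav_depth_A": fdef.scav_depth,
        "s0_mode": fdef.s0_mode,
        "boundaries": [
            {"index": b, "site_above": SITE_NAMES[b - 1] if b > 0 else None,
             "site_below": SITE_NAMES[b] if b < 6 else None,
             "atoms": fdef.boundary_meta[b] if fdef.boundary_meta else []}
            for b in range(N_BOUNDARY_PLANES)
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
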