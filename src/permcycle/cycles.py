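"""Permeation-cycle extraction, reduction, edge statistics, and MFPTs.

A permeation cycle is the stretch of the occupancy-state sequence between
the last visit to an anchor state before an ion's extracellular arrival
and the first visit after it: the filter leaves its reference occupancy,
conducts one ion, and returns.  Raw cycles are then *reduced* so that only
the nonrepeating, first-arrived states remain:

* a recurrence of an already-kept state with **no net ion-jump advance**
  since its first arrival is a trivial oscillation — the intervening
  excursion is deleted;
* a recurrence **with** jump advance is kept only when it is the terminal
  anchor closing the cycle; otherwise the first arrival stands.

Edge probabilities are cycle-conditioned — the fraction of reduced cycles
containing an ordered edge — and are distinct from MSM transition
probabilities.  Mean first passage times (MFPTs) between states are
estimated from every arrival at the source state, restricted to passages
accruing fewer than N_b net jumps (i.e. within one permeation cycle), with
BCa bootstrap confidence intervals.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .jumps import N_BOUNDARIES, PermeationEvent
from .occupancy import StateTrajectory

__all__ = [
    "RawCycle",
    "ReducedCycle",
    "MFPTResult",
    "select_anchor",
    "extract_cycles",
    "reduce_cycle",
    "reduce_cycles",
    "cycle_edge_probabilities",
    "compute_mfpt",
    "edge_table",
]

DEFAULT_ANCHOR = "WKK0KW"


@dataclass
class RawCycle:
    """Un-reduced anchored state sequence around one permeation event."""

    states: list[str]
    jumps: np.ndarray
    start_frame: int
    end_frame: int
    event: PermeationEvent | None = field(default=None, repr=False)


@dataclass
class ReducedCycle:
    """Anchored, nonrepeating state path representing permeation events."""

    path: list[str]
    multiplicity: int = 1
    jump_offsets: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        interior = self.path[1:-1]
        if len(set(interior)) != len(interior):
            raise ValueError("reduced cycle has repeated interior states")
        for a, b in zip(self.path, self.path[1:]):
            if a == b:
                raise ValueError("reduced cycle has consecutive duplicates")

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(zip(self.path, self.path[1:]))


def select_anchor(events: list[PermeationEvent] | None = None,
                  state_traj: StateTrajectory | None = None,
                  override: str | None = None) -> str:
    """Choose the cycle anchor state S_c.

    The anchor is the state most often visited both before and after an
    ion's crossing (within the window delimited by neighboring crossings),
    i.e. the state through which the largest fraction of permeation events
    can be expressed as closed cycles.  Ties prefer the canonical
    ``WKK0KW`` when it is among the maximizers, then the lexicographically
    smaller code (with a warning).  ``override`` short-circuits.
    """
    if override is not None:
        return override
    if events:
        scores: Counter[str] = Counter()
        crossings = sorted(e.crossing_frame for e in events)
        for e in events:
            traj = e.traj
            if traj is None:
                continue
            c = e.crossing_frame
            i = crossings.index(c)
            lo = crossings[i - 1] if i > 0 else 0
            hi = crossings[i + 1] if i + 1 < len(crossings) else len(traj) - 1
            before = set(traj.states[lo:c + 1])
            after = set(traj.states[c:hi + 1])
            for s in before & after:
                scores[s] += 1
        if not scores:
            raise ValueError("no candidate anchor state surrounds any event")
        best = max(scores.values())
        candidates = sorted(s for s, v in scores.items() if v == best)
        if DEFAULT_ANCHOR in candidates:
            return DEFAULT_ANCHOR
        if len(candidates) > 1:
            warnings.warn(
                f"anchor tie between {candidates}; choosing {candidates[0]}",
                stacklevel=2)
        return candidates[0]
    if state_traj is not None:
        counts = Counter(state_traj.states)
        if DEFAULT_ANCHOR in counts and counts[DEFAULT_ANCHOR] == max(counts.values()):
            return DEFAULT_ANCHOR
        best = max(counts.values())
        return sorted(s for s, v in counts.items() if v == best)[0]
    raise ValueError("provide events or a state trajectory")


def extract_cycles(events: list[PermeationEvent], anchor: str):
    """Anchored raw cycles and the coverage fraction.

    For each event the cycle spans from the last anchor visit at or before
    the crossing to the first anchor visit after it.  Events with no such
    bracketing pair are uncovered; coverage = covered / total.
    """
    if not events:
        raise ValueError("no permeation events")
    raw: list[RawCycle] = []
    covered = 0
    for e in events:
        traj = e.traj
        if traj is None:
            continue
        c = e.crossing_frame
        states = traj.states
        # strictly before the crossing: the SF may re-reach the anchor at
        # the crossing frame itself, which is the cycle's *end*, not start
        a = next((t for t in range(min(c, len(states)) - 1, -1, -1)
                  if states[t] == anchor), None)
        b = next((t for t in range(c, len(states))
                  if states[t] == anchor), None)
        if a is None or b is None:
            continue
        covered += 1
        raw.append(RawCycle(states=states[a:b + 1], jumps=traj.jumps[a:b + 1],
                            start_frame=a, end_frame=b, event=e))
        e.start_frame, e.end_frame = a, b
        e.state_sequence = states[a:b + 1]
        e.jump_offsets = traj.jumps[a:b + 1]
    coverage = covered / len(events)
    return raw, coverage


def reduce_cycle(states, jumps=None, anchor: str | None = None) -> ReducedCycle:
    """Reduce a raw anchored cycle to its nonrepeating first-arrival path.

    Accepts a :class:`RawCycle` or a state list plus per-state cumulative
    jump counts.  Scan forward keeping each state's first arrival; a
    recurrence with zero net jump advance since that first arrival deletes
    the intervening excursion, a recurrence with jump advance is dropped
    unless it is the terminal anchor.  Idempotent.
    """
    if isinstance(states, RawCycle):
        raw, j = states.states, states.jumps
    else:
        raw, j = list(states), jumps
    if j is None:
        j = np.zeros(len(raw), dtype=int)
    j = np.asarray(j)
    if len(raw) != len(j):
        raise ValueError("states and jumps must have equal length")
    if len(raw) == 0:
        raise ValueError("empty cycle")
    if anchor is None:
        anchor = raw[0]
    if raw[0] != anchor or raw[-1] != anchor:
        raise ValueError("cycle is not anchored")

    kept_states: list[str] = []
    kept_jumps: list[int] = []
    pos: dict[str, int] = {}
    for t, s in enumerate(raw):
        terminal = t == len(raw) - 1
        if kept_states and s == kept_states[-1]:
            continue  # merge consecutive duplicates
        if s in pos:
            first = pos[s]
            if j[t] - kept_jumps[first] == 0:
                # trivial oscillation: delete the excursion after s's first arrival
                for dead in kept_states[first + 1:]:
                    del pos[dead]
                del kept_states[first + 1:]
                del kept_jumps[first + 1:]
            elif terminal and s == anchor:
                kept_states.append(s)
                kept_jumps.append(int(j[t]))
            # else: repeat with jump advance — first arrival stands
        else:
            pos[s] = len(kept_states)
            kept_states.append(s)
            kept_jumps.append(int(j[t]))
    return ReducedCycle(path=kept_states, multiplicity=1,
                        jump_offsets=np.asarray(kept_jumps))


def reduce_cycles(raw_cycles, anchor: str | None = None) -> list[ReducedCycle]:
    """Reduce all raw cycles and aggregate identical paths."""
    tally: Counter[tuple[str, ...]] = Counter()
    for rc in raw_cycles:
        red = reduce_cycle(rc, anchor=anchor)
        tally[tuple(red.path)] += 1
    out = [ReducedCycle(path=list(p), multiplicity=m)
           for p, m in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))]
    return out


def cycle_edge_probabilities(reduced: list[ReducedCycle]):
    """Cycle-conditioned edge probabilities with binomial 95% CIs.

    P(edge) = (number of reduced cycles containing the ordered edge) /
    (number of reduced cycles).  Because interior states are unique after
    reduction, the outgoing probabilities of any state sum to at most 1.
    """
    import pandas as pd

    if not reduced:
        raise ValueError("no reduced cycles")
    n = sum(rc.multiplicity for rc in reduced)
    counts: Counter[tuple[str, str]] = Counter()
    for rc in reduced:
        for edge in set(rc.edges):
            counts[edge] += rc.multiplicity
    rows = []
    for (a, b), c in sorted(counts.items()):
        p = c / n
        half = 1.959963984540054 * np.sqrt(p * (1 - p) / n)
        rows.append({"from_state": a, "to_state": b, "probability": p,
                     "ci_low": max(0.0, p - half), "ci_high": min(1.0, p + half),
                     "n_cycles": n})
    df = pd.DataFrame(rows, columns=["from_state", "to_state", "probability",
                                     "ci_low", "ci_high", "n_cycles"])
    if len(df):
        sums = df.groupby("from_state")["probability"].sum()
        if (sums > 1 + 1e-9).any():
            raise AssertionError("outgoing cycle-edge probabilities exceed 1")
    return df


@dataclass
class MFPTResult:
    mfpt_ns: float | None
    ci_low: float | None
    ci_high: float | None
    n_passages: int
    passage_times_ns: np.ndarray


def _arrivals(codes: np.ndarray, target: int) -> np.ndarray:
    hit = codes == target
    first = np.flatnonzero(hit[1:] & ~hit[:-1]) + 1
    if hit[0]:
        first = np.concatenate([[0], first])
    return first


def compute_mfpt(state_trajs, i: str, j: str, *,
                 n_boundaries: int | None = N_BOUNDARIES,
                 n_resamples: int = 10000,
                 seed: int | None = None) -> MFPTResult:
    """MFPT (ns) from state ``i`` to state ``j`` with a BCa interval.

    A passage opens at an arrival in ``i`` and ends at the next occurrence
    of ``j``; the following passage starts at the first ``i`` arrival
    after that, so passages never overlap and are independent draws of
    the first passage time (the BCa bootstrap and the standard error are
    then valid).  A passage counts only if fewer than ``n_boundaries``
    net ion jumps accrued in between, restricting it to a single
    permeation cycle (pass ``n_boundaries=None`` to disable).  Passages
    are pooled across trajectories.  ``n_resamples=0`` skips the
    bootstrap.
    """
    from .msm import _as_traj_list

    if i == j:
        return MFPTResult(0.0, 0.0, 0.0, 0, np.empty(0))
    times: list[float] = []
    for tr in _as_traj_list(state_trajs):
        labels = {s: k for k, s in enumerate(dict.fromkeys(tr.states))}
        if i not in labels or j not in labels:
            continue
        codes = np.fromiter((labels[s] for s in tr.states), dtype=np.int64,
                            count=len(tr))
        arr_i = _arrivals(codes, labels[i])
        j_idx = np.flatnonzero(codes == labels[j])
        if len(arr_i) == 0 or len(j_idx) == 0:
            continue
        starts_list, ends_list = [], []
        cursor = 0
        while True:
            a = np.searchsorted(arr_i, cursor, side="left")
            if a >= len(arr_i):
                break
            start = arr_i[a]
            b = np.searchsorted(j_idx, start, side="left")
            if b >= len(j_idx):
                break
            end = j_idx[b]
            starts_list.append(start)
            ends_list.append(end)
            cursor = end + 1
        starts = np.asarray(starts_list, dtype=np.int64)
        ends = np.asarray(ends_list, dtype=np.int64)
        if len(starts) == 0:
            continue
        if n_boundaries is not None:
            within = (tr.jumps[ends] - tr.jumps[starts]) < n_boundaries
            starts, ends = starts[within], ends[within]
        times.extend(((ends - starts) * tr.frame_interval / 1000.0).tolist())
    if not times:
        return MFPTResult(None, None, None, 0, np.empty(0))
    arr = np.asarray(times)
    mean = float(arr.mean())
    lo = hi = None
    if n_resamples > 0 and len(arr) > 1 and arr.std() > 0:
        from scipy.stats import bootstrap

        rng = np.random.default_rng(seed)
        res = bootstrap((arr,), np.mean, method="BCa",
                        n_resamples=n_resamples, confidence_level=0.95,
                        random_state=rng)
        lo, hi = float(res.confidence_interval.low), float(res.confidence_interval.high)
    elif n_resamples > 0:
        lo = hi = mean
    return MFPTResult(mean, lo, hi, len(arr), arr)


def edge_table(reduced: list[ReducedCycle], state_trajs, *,
               n_boundaries: int | None = N_BOUNDARIES,
               n_resamples: int = 10000, seed: int | None = None):
    """Cycle-edge probabilities joined with per-edge MFPTs.

    One row per ordered edge observed in the reduced cycles:
    probability + binomial CI, MFPT (ns) + BCa bootstrap interval.
    """
    df = cycle_edge_probabilities(reduced)
    mfpt, lo, hi = [], [], []
    for _, row in df.iterrows():
        res = compute_mfpt(state_trajs, row["from_state"], row["to_state"],
                           n_boundaries=n_boundaries,
                           n_resamples=n_resamples, seed=seed)
        mfpt.append(res.mfpt_ns)
        lo.append(res.ci_low)
        hi.append(res.ci_high)
    df["mfpt_ns"] = mfpt
    df["mfpt_lo"] = lo
    df["mfpt_hi"] = hi
    return df


def export_reduced_cycles(reduced: list[ReducedCycle], path) -> None:
    """JSON-lines export: one {path, multiplicity} object per line."""
    with open(path, "w") as fh:
        for rc in reduced:
            fh.write(json.dumps({"path": rc.path, "multiplicity": rc.multiplicity}) + "\n")
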