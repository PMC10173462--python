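"""End-to-end analysis pipeline and report bundle.

Takes a set of inputs (MD topology+trajectories, precomputed state files,
or a synthetic-run block), encodes them, builds the pooled MSM, runs the
Chapman-Kolmogorov check, extracts and reduces permeation cycles, computes
edge statistics and MFPTs, currents with cross-trajectory t-intervals, and
writes the whole bundle with provenance (versions, config hash, input
checksums).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from . import __version__, cycles as cyc, graphs, io as pio, jumps as jmp, msm
from .occupancy import StateTrajectory, encode_trajectory, occupancy_fractions
from .synthetic import SyntheticConfig, generate_knockon_trajectory

log = logging.getLogger("permcycle")

__all__ = ["PipelineResult", "run_pipeline", "load_config", "pooled_current"]


@dataclass
class PipelineResult:
    trajectories: list[StateTrajectory]
    model: msm.TransitionModel
    ck: msm.CKResult | None
    anchor: str
    coverage: float
    reduced: list
    edge_table: object
    currents_pA: list[float]
    current_mean_pA: float | None
    current_ci_pA: tuple | None
    water_permeations: int | None = None
    summary: str = ""
    extra: dict = field(default_factory=dict)


def pooled_current(currents, confidence: float = 0.95):
    """Mean current with a t-distribution CI; n = number of independent
    trajectories (the standard convention for pooled channel recordings)."""
    from scipy import stats

    arr = np.asarray(list(currents), dtype=float)
    if arr.size == 0:
        return None, None
    mean = float(arr.mean())
    if arr.size == 1:
        return mean, (mean, mean)
    se = arr.std(ddof=1) / np.sqrt(arr.size)
    if se == 0:
        return mean, (mean, mean)
    tcrit = stats.t.ppf(0.5 + confidence / 2, df=arr.size - 1)
    return mean, (mean - tcrit * se, mean + tcrit * se)


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _collect_inputs(config, outdir):
    """Yield (StateTrajectory, events or None, water crossings or None)."""
    results = []
    checksums = {}
    seed = int(config.get("seed", 0))

    for path in config.get("state_files", []):
        checksums[path] = _sha256(path)
        traj = pio.read_states(path)
        results.append((traj, None, None))

    if "synthetic" in config:
        syn = dict(config["synthetic"])
        syn.setdefault("seed", seed)
        strj = generate_knockon_trajectory(SyntheticConfig(**syn))
        events = jmp.detect_permeation_events(strj.state_traj, strj.ion_levels,
                                              strj.ion_ids)
        water = jmp.count_crossings(strj.water_levels)
        results.append((strj.state_traj, events, water))

    if "topology" in config:
        import MDAnalysis as mda

        from .filter_geometry import locate_filter

        top = config["topology"]
        checksums[top] = _sha256(top)
        for trj in config.get("trajectories", []):
            checksums[trj] = _sha256(trj)
            try:
                u = mda.Universe(top, trj)
                fdef = locate_filter(u, extra_motifs=tuple(config.get("motifs", [])))
                traj, levels, ion_ids, wlevels = encode_trajectory(
                    u, fdef, source_id=os.path.basename(trj),
                    frame_interval=config.get("frame_interval"),
                    return_levels=True)
                events = jmp.detect_permeation_events(traj, levels, ion_ids)
                water = jmp.count_crossings(wlevels)
                results.append((traj, events, water))
            except Exception:
                log.exception("failed to process %s; continuing", trj)
    return results, checksums


def run_pipeline(config: dict, outdir) -> PipelineResult:
    os.makedirs(outdir, exist_ok=True)
    lag = float(config.get("lag", msm.DEFAULT_LAG_PS))
    seed = int(config.get("seed", 0))
    bootstrap_B = int(config.get("bootstrap_B", 10000))
    node_threshold = float(config.get("node_threshold", 0.10))
    flux_threshold = float(config.get("flux_threshold", 0.15))

    inputs, checksums = _collect_inputs(config, outdir)
    if not inputs:
        raise ValueError("no inputs produced a state trajectory")
    trajs = [t for t, _, _ in inputs]

    for i, traj in enumerate(trajs):
        pio.write_states(os.path.join(outdir, f"states_{i}.tsv"), traj)

    model = msm.build_msm(trajs, lag)
    model.to_json(os.path.join(outdir, "model.json"))

    ck = None
    ck_ks = config.get("ck_k_values", [2, 3, 5])
    try:
        ck = msm.chapman_kolmogorov(trajs, lag, ck_ks,
                                    count_floor=config.get("ck_count_floor", 100))
        ck.to_csv(os.path.join(outdir, "ck.csv"))
    except ValueError as exc:
        log.warning("Chapman-Kolmogorov test skipped: %s", exc)

    all_events = []
    currents = []
    water_total = 0
    water_known = False
    for traj, events, water in inputs:
        if events is None:
            events = jmp.events_from_jumps(traj)
        all_events.extend(events)
        trace = jmp.JumpTrace(traj.jumps, traj.duration_ns)
        currents.append(jmp.compute_current(trace))
        if water is not None:
            water_known = True
            water_total += water

    anchor = config.get("anchor") or cyc.select_anchor(
        all_events if all_events else None,
        state_traj=trajs[0] if not all_events else None)
    raw, coverage = (cyc.extract_cycles(all_events, anchor)
                     if all_events else ([], 0.0))
    reduced = cyc.reduce_cycles(raw) if raw else []

    with open(os.path.join(outdir, "events.json"), "w") as fh:
        json.dump([e.to_dict() for e in all_events], fh, indent=2)
    if reduced:
        cyc.export_reduced_cycles(reduced, os.path.join(outdir, "reduced_cycles.jsonl"))

    table = None
    if reduced:
        table = cyc.edge_table(reduced, trajs, n_resamples=bootstrap_B, seed=seed)
        table.to_csv(os.path.join(outdir, "edges.csv"), index=False)

    stationary = dict(zip(model.states, model.stationary))
    participation = graphs.cycle_participation(reduced) if reduced else {}
    if table is not None:
        Gc = graphs.build_cycle_graph(edge_table=table, stationary=stationary,
                                      participation=participation,
                                      node_threshold=node_threshold)
        graphs.write_graph(Gc, os.path.join(outdir, "cycle_graph.graphml"))
        graphs.write_graph(Gc, os.path.join(outdir, "cycle_graph.dot"))
        graphs.write_graph(Gc, os.path.join(outdir, "cycle_graph.json"))
    F = msm.net_fluxes(model.transition_matrix, model.stationary)
    Gf = graphs.build_cycle_graph(flux_matrix=F, states=model.states,
                                  stationary=stationary,
                                  participation=participation,
                                  node_threshold=0.0,
                                  edge_threshold=flux_threshold)
    graphs.write_graph(Gf, os.path.join(outdir, "flux_graph.graphml"))

    mean_i, ci = pooled_current(currents)
    occ = occupancy_fractions(trajs[0]) if trajs else None

    lines = [
        f"permcycle {__version__} report",
        f"config sha256: {hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]}",
        f"inputs: {len(trajs)} trajectories, "
        f"{sum(len(t) for t in trajs)} frames, lag {lag} ps, seed {seed}",
        "input checksums: " + (", ".join(f"{os.path.basename(k)}={v[:12]}"
                                         for k, v in checksums.items()) or "(generated)"),
        f"states in model: {len(model.states)}",
        f"permeation events: {len(all_events)}",
        f"anchor state: {anchor}  coverage: {coverage:.3f}",
        f"current: {mean_i:.3f} pA" + (f" (95% CI {ci[0]:.3f}..{ci[1]:.3f}, "
                                       f"n={len(currents)})" if ci else ""),
    ]
    if water_known:
        lines.append(f"water permeations: {water_total}")
    if ck is not None:
        dev = ", ".join(f"k={k}: {d:.4f}" for k, d in zip(ck.k_values, ck.deviations))
        lines.append(f"Chapman-Kolmogorov deviation: {dev}")
    if reduced:
        lines.append("top reduced cycles:")
        for rc in reduced[:5]:
            lines.append(f"  x{rc.multiplicity}  " + " -> ".join(rc.path))
    if occ is not None:
        lines.append("site occupancy (first trajectory):")
        for site, row in occ.iterrows():
            lines.append(f"  {site}: ion {row.ion_fraction:.3f}  "
                         f"water {row.water_fraction:.3f}")
    summary = "\n".join(lines) + "\n"
    with open(os.path.join(outdir, "summary.txt"), "w") as fh:
        fh.write(summary)
    log.info("%s", summary)

    return PipelineResult(
        trajectories=trajs, model=model, ck=ck, anchor=anchor,
        coverage=coverage, reduced=reduced, edge_table=table,
        currents_pA=currents, current_mean_pA=mean_i, current_ci_pA=ci,
        water_permeations=water_total if water_known else None,
        summary=summary,
    )
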