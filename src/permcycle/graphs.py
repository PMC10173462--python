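"""Permeation-cycle graph construction and export.

Two edge-weight conventions mirror the two ways cycles are summarized:

* **cycle mode** — edges carry the cycle-conditioned transition
  probability and MFPT from the reduced-cycle edge table;
* **flux mode** — edges carry the net stationary flux f_ij from the full
  MSM (only the positive direction of each antisymmetric pair is drawn).

Display filters follow the field's plotting conventions: nodes must take
part in more than a given fraction of the observed permeation cycles, and
flux edges must exceed a given fraction of the maximum net flux.
"""

from __future__ import annotations

import json

import networkx as nx
import numpy as np

__all__ = ["build_cycle_graph", "cycle_participation", "write_graph", "read_graph"]


def cycle_participation(reduced) -> dict[str, float]:
    """Fraction of reduced cycles each state takes part in."""
    total = sum(rc.multiplicity for rc in reduced)
    part: dict[str, float] = {}
    for rc in reduced:
        for s in set(rc.path):
            part[s] = part.get(s, 0.0) + rc.multiplicity
    return {s: v / total for s, v in part.items()}


def build_cycle_graph(edge_table=None, flux_matrix=None, states=None,
                      stationary=None, participation=None,
                      node_threshold: float = 0.10,
                      edge_threshold: float = 0.0) -> nx.DiGraph:
    """Directed, annotated graph of permeation-cycle structure.

    Provide ``edge_table`` (cycle mode) or ``flux_matrix`` + ``states``
    (flux mode).  Nodes whose cycle participation does not exceed
    ``node_threshold`` are removed (a threshold of 0 disables the
    filter); in flux mode edges with f <= edge_threshold * max(f) are
    removed.  Filtering is monotone in both thresholds.
    """
    if not 0 <= node_threshold <= 1 or not 0 <= edge_threshold <= 1:
        raise ValueError("thresholds must lie in [0, 1]")
    G = nx.DiGraph()
    stationary = stationary or {}
    participation = participation or {}

    if edge_table is not None:
        G.graph["mode"] = "cycles"
        for _, row in edge_table.iterrows():
            G.add_edge(row["from_state"], row["to_state"],
                       probability=float(row["probability"]),
                       ci_low=float(row["ci_low"]), ci_high=float(row["ci_high"]),
                       mfpt_ns=float(row["mfpt_ns"]) if row.get("mfpt_ns") is not None
                       and np.isfinite(row.get("mfpt_ns", np.nan)) else None)
    elif flux_matrix is not None:
        if states is None:
            raise ValueError("flux mode needs the state list")
        F = np.asarray(flux_matrix, dtype=float)
        if F.shape != (len(states), len(states)):
            raise ValueError("flux matrix does not match the state list")
        G.graph["mode"] = "flux"
        fmax = np.abs(F).max() if F.size else 0.0
        cut = edge_threshold * fmax
        for i, a in enumerate(states):
            for j, b in enumerate(states):
                if F[i, j] > 0 and F[i, j] > cut:
                    G.add_edge(a, b, flux=float(F[i, j]))
        for s in states:
            if s not in G:
                G.add_node(s)
    else:
        raise ValueError("provide an edge table or a flux matrix")

    for s in list(G.nodes):
        if s in stationary:
            G.nodes[s]["stationary"] = float(stationary[s])
        G.nodes[s]["participation"] = float(participation.get(s, 0.0))

    if node_threshold > 0:
        drop = [s for s in G.nodes
                if G.nodes[s]["participation"] <= node_threshold]
        G.remove_nodes_from(drop)
    if len(G) == 0:
        import warnings

        warnings.warn("graph is empty after filtering", stacklevel=2)
    return G


def write_graph(G: nx.DiGraph, path, fmt: str | None = None) -> None:
    """Write GraphML, DOT, or a JSON node-link twin (by extension)."""
    path = str(path)
    fmt = fmt or path.rsplit(".", 1)[-1].lower()
    if fmt == "graphml":
        H = _stringify_none(G)
        nx.write_graphml(H, path)
    elif fmt in ("dot", "gv"):
        _write_dot(G, path)
    elif fmt == "json":
        doc = nx.node_link_data(G, edges="edges")
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)
    else:
        raise ValueError(f"unknown graph format {fmt!r}")


def read_graph(path, fmt: str | None = None) -> nx.DiGraph:
    path = str(path)
    fmt = fmt or path.rsplit(".", 1)[-1].lower()
    if fmt == "graphml":
        return _destringify_none(nx.read_graphml(path))
    if fmt == "json":
        with open(path) as fh:
            return nx.node_link_graph(json.load(fh), directed=True, edges="edges")
    raise ValueError(f"cannot read graph format {fmt!r}")


def _stringify_none(G: nx.DiGraph) -> nx.DiGraph:
    H = G.copy()
    for _, d in H.nodes(data=True):
        for k, v in list(d.items()):
            if v is None:
                del d[k]
    for _, _, d in H.edges(data=True):
        for k, v in list(d.items()):
            if v is None:
                del d[k]
    return H


def _destringify_none(G) -> nx.DiGraph:
    return nx.DiGraph(G)


def _dot_quote(s) -> str:
    return '"' + str(s).replace('"', r"\"") + '"'


def _write_dot(G: nx.DiGraph, path) -> None:
    # minimal hand-rolled DOT emitter (no pydot/pygraphviz dependency)
    lines = ["digraph permeation_cycles {"]
    for n, d in G.nodes(data=True):
        attrs = []
        if d.get("stationary") is not None:
            attrs.append(f'stationary={d["stationary"]:.6g}')
        if "participation" in d:
            attrs.append(f'participation={d["participation"]:.6g}')
        label = f' [{", ".join(attrs)}]' if attrs else ""
        lines.append(f"  {_dot_quote(n)}{label};")
    for a, b, d in G.edges(data=True):
        attrs = []
        for key in ("probability", "mfpt_ns", "flux"):
            if d.get(key) is not None:
                attrs.append(f"{key}={d[key]:.6g}")
        joined = ", ".join(attrs)
        label = f' [label="{joined}"]' if attrs else ""
        lines.append(f"  {_dot_quote(a)} -> {_dot_quote(b)}{label};")
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
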