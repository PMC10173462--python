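"""Plain-text state-sequence interchange format.

One line per frame: ``frame_index<TAB>code<TAB>cumulative_jumps``, with
header comments ``#frame_interval_ps=<float>`` and ``#source=<id>``.
This file is the interchange between the encoder and all downstream
modules (MSM, cycles, MFPTs), so precomputed sequences from other tools
can enter the pipeline here.
"""

from __future__ import annotations

import numpy as np

from .occupancy import StateTrajectory

__all__ = ["read_states", "write_states"]


def write_states(path, traj: StateTrajectory) -> None:
    with open(path, "w") as fh:
        fh.write(f"#frame_interval_ps={traj.frame_interval}\n")
        fh.write(f"#source={traj.source_id}\n")
        for t, (code, j) in enumerate(zip(traj.states, traj.jumps)):
            fh.write(f"{t}\t{code}\t{int(j)}\n")


def read_states(path) -> StateTrajectory:
    frame_interval = None
    source = ""
    codes: list[str] = []
    jumps: list[int] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#frame_interval_ps="):
                    frame_interval = float(line.split("=", 1)[1])
                elif line.startswith("#source="):
                    source = line.split("=", 1)[1]
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"malformed state line: {line!r}")
            codes.append(parts[1])
            jumps.append(int(parts[2]))
    if frame_interval is None:
        raise ValueError(f"{path}: missing #frame_interval_ps header")
    if not codes:
        raise ValueError(f"{path}: no frames")
    return StateTrajectory(states=codes, frame_interval=frame_interval,
                           jumps=np.asarray(jumps), source_id=source)
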