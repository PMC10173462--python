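"""Markov state models over selectivity-filter occupancy states.

The model is estimated at a lag time tau by sliding-window transition
counting; the transition matrix is the row-normalized count matrix

    T_ij(tau) = C_ij(tau) / sum_j C_ij(tau).

Because the permeating system is driven (nonequilibrium), no reversibility
constraint is imposed and eigenvalues may be complex; relaxation times use
the eigenvalue modulus,

    t_m = -tau / ln |lambda_m|,   m > 1.

Markovianity at the chosen lag is checked with the Chapman-Kolmogorov
test, comparing T(k*tau) estimated directly from data against T(tau)^k.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

from .occupancy import StateTrajectory

__all__ = [
    "DEFAULT_LAG_PS",
    "TransitionModel",
    "CKResult",
    "count_transitions",
    "transition_matrix",
    "spectral_analysis",
    "stationary_distribution",
    "net_fluxes",
    "chapman_kolmogorov",
    "build_msm",
]

DEFAULT_LAG_PS = 20.0


@dataclass
class TransitionModel:
    states: list[str]
    count_matrix: np.ndarray
    transition_matrix: np.ndarray
    lag: float = DEFAULT_LAG_PS  # ps
    stationary: np.ndarray | None = None
    eigenvalues: np.ndarray | None = None
    relaxation_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        T = np.asarray(self.transition_matrix, dtype=float)
        if T.size and not np.allclose(T.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(np.asarray(self.count_matrix) < 0):
            raise ValueError("count matrix must be nonnegative")
        if len(set(self.states)) != len(self.states):
            raise ValueError("duplicate states")

    def index(self, state: str) -> int:
        return self.states.index(state)

    def to_json(self, path) -> None:
        lam = self.eigenvalues
        doc = {
            "states": self.states,
            "lag_ps": self.lag,
            "count_matrix": np.asarray(self.count_matrix).tolist(),
            "transition_matrix": np.asarray(self.transition_matrix).tolist(),
            "stationary": None if self.stationary is None else self.stationary.tolist(),
            "eigenvalues": None if lam is None else
                [{"re": float(v.real), "im": float(v.imag)} for v in lam],
            "relaxation_times_ps": None if self.relaxation_times is None else
                [None if not np.isfinite(t) else float(t) for t in self.relaxation_times],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TransitionModel":
        with open(path) as fh:
            doc = json.load(fh)
        lam = doc.get("eigenvalues")
        rt = doc.get("relaxation_times_ps")
        return cls(
            states=doc["states"],
            count_matrix=np.asarray(doc["count_matrix"]),
            transition_matrix=np.asarray(doc["transition_matrix"]),
            lag=doc["lag_ps"],
            stationary=None if doc.get("stationary") is None else np.asarray(doc["stationary"]),
            eigenvalues=None if lam is None else
                np.array([complex(e["re"], e["im"]) for e in lam]),
            relaxation_times=None if rt is None else
                np.array([np.inf if t is None else t for t in rt]),
        )


def _as_traj_list(state_trajs) -> list[StateTrajectory]:
    if isinstance(state_trajs, StateTrajectory):
        return [state_trajs]
    return list(state_trajs)


def _lag_frames(traj: StateTrajectory, lag: float) -> int:
    ratio = lag / traj.frame_interval
    n = round(ratio)
    if n < 1 or abs(ratio - n) > 1e-9:
        raise ValueError(
            f"lag {lag} ps is not a positive integer multiple of the "
            f"frame interval {traj.frame_interval} ps"
        )
    return n


def count_transitions(state_trajs, lag: float = DEFAULT_LAG_PS,
                      states: list[str] | None = None):
    """Sliding-window transition counts pooled over trajectories.

    Every frame pair (t, t + tau) contributes one count.  Returns
    ``(C, states)`` with states sorted lexicographically unless an
    explicit ordering is given.
    """
    trajs = _as_traj_list(state_trajs)
    if states is None:
        seen = set()
        for tr in trajs:
            seen.update(tr.states)
        states = sorted(seen)
    idx = {s: i for i, s in enumerate(states)}
    n = len(states)
    C = np.zeros((n, n), dtype=np.int64)
    for tr in trajs:
        k = _lag_frames(tr, lag)
        if len(tr) <= k:
            warnings.warn(
                f"trajectory {tr.source_id!r} shorter than the lag; "
                "contributes no counts", stacklevel=2)
            continue
        a = np.fromiter((idx[s] for s in tr.states), dtype=np.int64, count=len(tr))
        np.add.at(C, (a[:-k], a[k:]), 1)
    return C, states


def transition_matrix(count_matrix, states, lag: float = DEFAULT_LAG_PS) -> TransitionModel:
    """Row-normalize counts; prune states left without outgoing counts.

    Pruning iterates because removing a state's incoming counts can empty
    another state's row.  Zero-outflow states are dropped rather than
    given self-loops: a probability-1 self-loop would fabricate an
    absorbing state and poison the stationary distribution.
    """
    C = np.asarray(count_matrix, dtype=np.int64).copy()
    states = list(states)
    while True:
        rowsum = C.sum(axis=1)
        dead = np.flatnonzero(rowsum == 0)
        if len(dead) == 0:
            break
        warnings.warn(
            f"pruning {len(dead)} state(s) with no outgoing transitions: "
            f"{[states[i] for i in dead]}", stacklevel=2)
        keep = np.flatnonzero(rowsum > 0)
        C = C[np.ix_(keep, keep)]
        states = [states[i] for i in keep]
    if C.size == 0:
        raise ValueError("no states left after pruning")
    T = C / C.sum(axis=1, keepdims=True)
    return TransitionModel(states=states, count_matrix=C, transition_matrix=T, lag=lag)


def _check_stochastic(T) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(T < -1e-12) or not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("matrix is not row-stochastic")
    return T


def spectral_analysis(T, lag: float = DEFAULT_LAG_PS):
    """Eigenvalues (descending modulus) and relaxation times in ps.

    t_m = -lag / ln|lambda_m| for m > 1; t_1 and any mode with
    |lambda| ~ 1 are reported as +inf (stationary / non-decaying modes).
    """
    T = _check_stochastic(T)
    lam = np.linalg.eigvals(T)
    order = np.argsort(-np.abs(lam), kind="stable")
    lam = lam[order]
    mod = np.abs(lam)
    times = np.empty(len(lam))
    times[0] = np.inf
    with np.errstate(divide="ignore"):
        for m in range(1, len(lam)):
            times[m] = np.inf if mod[m] >= 1 - 1e-12 else -lag / np.log(mod[m])
    return lam, times


def stationary_distribution(T) -> np.ndarray:
    """Steady-state distribution: the left eigenvector at lambda = 1.

    Requires T irreducible on its retained states; a reducible matrix has
    no unique steady state and raises with the communicating classes.
    """
    T = _check_stochastic(T)
    n_comp, labels = connected_components(T > 0, directed=True, connection="strong")
    if n_comp > 1:
        classes = [list(np.flatnonzero(labels == c)) for c in range(n_comp)]
        raise ValueError(f"transition matrix is reducible; communicating classes: {classes}")
    w, v = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    rho = np.real(v[:, i])
    rho = rho / rho.sum()
    if np.any(rho < -1e-12):
        raise ValueError("stationary distribution has negative entries")
    rho = np.clip(rho, 0.0, None)
    return rho / rho.sum()


def net_fluxes(T, rho) -> np.ndarray:
    """Net probability fluxes f_ij = T_ij rho_i - T_ji rho_j.

    Antisymmetric by construction; identically zero under detailed
    balance.  Computed from the pooled model (full trajectories), not
    from reduced cycles.
    """
    T = _check_stochastic(T)
    rho = np.asarray(rho, dtype=float)
    if rho.shape != (T.shape[0],):
        raise ValueError("stationary vector does not match the transition matrix")
    F = T * rho[:, None]
    return F - F.T


@dataclass
class CKResult:
    """Chapman-Kolmogorov test summary."""

    k_values: list[int]
    deviations: list[float]  # sup-norm over retained entries, per k
    retained_states: list[str]
    curves: dict = field(default_factory=dict)  # state -> {"k", "direct", "model"}

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"k": self.k_values, "deviation": self.deviations}).to_csv(
            path, index=False)


def chapman_kolmogorov(state_trajs, lag: float = DEFAULT_LAG_PS,
                       k_values=(2, 3, 5), count_floor: int = 100) -> CKResult:
    """Compare T(k*tau) estimated from data with T(tau)^k.

    The deviation for each k is the maximum absolute entrywise difference,
    restricted to rows/columns of states visited at least ``count_floor``
    times (poorly sampled states carry no evidence either way).  Self-
    transition curves per retained state are returned for plotting.
    """
    k_values = sorted(int(k) for k in k_values)
    if k_values and k_values[0] < 2:
        raise ValueError("k must be >= 2")
    trajs = _as_traj_list(state_trajs)

    C1, states = count_transitions(trajs, lag)
    model = transition_matrix(C1, states, lag)
    states = model.states
    T1 = model.transition_matrix

    visits = np.zeros(len(states))
    index = {s: i for i, s in enumerate(states)}
    for tr in trajs:
        for s in tr.states:
            if s in index:
                visits[index[s]] += 1
    retained = np.flatnonzero(visits >= count_floor)
    retained_states = [states[i] for i in retained]

    deviations = []
    curves = {s: {"k": [], "direct": [], "model": []} for s in retained_states}
    Tk_model = T1.copy()
    prev_k = 1
    for k in k_values:
        Tk_model = Tk_model @ np.linalg.matrix_power(T1, k - prev_k)
        prev_k = k
        Ck, _ = count_transitions(trajs, lag * k, states=states)
        rows = Ck.sum(axis=1)
        Tk_direct = np.divide(Ck, rows[:, None], where=rows[:, None] > 0,
                              out=np.zeros_like(Ck, dtype=float))
        ok_rows = np.array([i for i in retained if rows[i] > 0], dtype=int)
        if len(ok_rows) == 0:
            deviations.append(np.nan)
            continue
        sub = np.ix_(ok_rows, retained)
        deviations.append(float(np.max(np.abs(Tk_direct[sub] - Tk_model[sub]))))
        for i in ok_rows:
            s = states[i]
            curves[s]["k"].append(k)
            curves[s]["direct"].append(float(Tk_direct[i, i]))
            curves[s]["model"].append(float(Tk_model[i, i]))
    return CKResult(k_values=list(k_values), deviations=deviations,
                    retained_states=retained_states, curves=curves)


def build_msm(state_trajs, lag: float = DEFAULT_LAG_PS) -> TransitionModel:
    """Full model: counts, T, stationary distribution, spectrum."""
    C, states = count_transitions(state_trajs, lag)
    model = transition_matrix(C, states, lag)
    model.stationary = stationary_distribution(model.transition_matrix)
    model.eigenvalues, model.relaxation_times = spectral_analysis(
        model.transition_matrix, lag)
    return model
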