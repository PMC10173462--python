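"""Independent oracles used by the test suite.

These deliberately take different computational routes from the library
code they check: linear solves instead of passage sampling, and iterated
rewriting instead of a single forward scan.
"""

from __future__ import annotations

import numpy as np


def mfpt_linear_solve(T: np.ndarray, target: int) -> np.ndarray:
    """Exact DTMC mean first passage times to ``target`` (in steps).

    Solves (I - Q) m = 1 on the non-target states, where Q is T with the
    target row/column removed; m[target] = 0.
    """
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    others = [i for i in range(n) if i != target]
    Q = T[np.ix_(others, others)]
    m_others = np.linalg.solve(np.eye(n - 1) - Q, np.ones(n - 1))
    m = np.zeros(n)
    for k, i in enumerate(others):
        m[i] = m_others[k]
    return m


def reduce_by_rewriting(states, jumps, anchor):
    """Brute-force cycle reduction: apply the two reduction rules as list
    rewrites, earliest applicable position first, until a fixed point.

    At the leftmost position k where a rule applies (restarting after
    every rewrite):
      * s_k equal to its predecessor: delete position k (a dwell frame);
      * s_k a recurrence of an earlier state (first occurrence i):
        zero net jump change since i deletes the excursion i+1..k
        (a trivial oscillation); otherwise position k is deleted unless
        it is the terminal anchor closing the cycle.
    """
    seq = list(zip(list(states), [int(j) for j in jumps]))
    if not seq or seq[0][0] != anchor or seq[-1][0] != anchor:
        raise ValueError("not anchored")
    while True:
        first_pos: dict[str, int] = {}
        acted = False
        for k, (s, j) in enumerate(seq):
            if k > 0 and s == seq[k - 1][0]:
                del seq[k]
                acted = True
                break
            if s not in first_pos:
                first_pos[s] = k
                continue
            i = first_pos[s]
            if j - seq[i][1] == 0:
                del seq[i + 1:k + 1]
            elif k == len(seq) - 1 and s == anchor:
                continue  # terminal anchor with jump advance: allowed
            else:
                del seq[k]
            acted = True
            break
        if not acted:
            return [s for s, _ in seq]


def enumerate_anchored_sequences(n_states: int, max_len: int, anchor="A"):
    """All sequences over ``n_states`` symbols starting/ending at the anchor."""
    import itertools

    symbols = [anchor] + [chr(ord("B") + i) for i in range(n_states - 1)]
    for length in range(2, max_len + 1):
        for interior in itertools.product(symbols, repeat=length - 2):
            yield [anchor, *interior, anchor]
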