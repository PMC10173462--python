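import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helpers_oracles import mfpt_linear_solve, reduce_by_rewriting

from permcycle.cycles import (
    ReducedCycle,
    compute_mfpt,
    cycle_edge_probabilities,
    edge_table,
    extract_cycles,
    reduce_cycle,
    reduce_cycles,
    select_anchor,
)
from permcycle.jumps import detect_permeation_events
from permcycle.occupancy import StateTrajectory
from permcycle.synthetic import generate_markov_sequence

# short synthetic codes for chain tests ('0' < 'C' < 'K' < 'W' sorts in order)
S = ["00K0KW", "0CK0KW", "0KK0KW", "0WK0KW", "C0K0KW"]


class TestSelectAnchor:
    def test_direct_knockon_prefers_canonical(self, direct_run):
        events = detect_permeation_events(direct_run.state_traj,
                                          direct_run.ion_levels)
        assert select_anchor(events) == "WKK0KW"

    def test_override_wins(self, direct_run):
        events = detect_permeation_events(direct_run.state_traj,
                                          direct_run.ion_levels)
        assert select_anchor(events, override="C0K0KW") == "C0K0KW"

    def test_trajectory_fallback_most_frequent(self):
        traj = StateTrajectory([S[0]] * 3 + [S[1]], 20.0)
        assert select_anchor(state_traj=traj) == S[0]

    def test_no_input_raises(self):
        with pytest.raises(ValueError):
            select_anchor()


class TestExtractCycles:
    def test_full_coverage_on_planted_data(self, direct_run):
        events = detect_permeation_events(direct_run.state_traj,
                                          direct_run.ion_levels)
        raw, coverage = extract_cycles(events, "WKK0KW")
        assert coverage == 1.0
        assert len(raw) == direct_run.config.n_permeations
        for rc in raw:
            assert rc.states[0] == rc.states[-1] == "WKK0KW"

    def test_uncovered_event_lowers_coverage(self, direct_run):
        events = detect_permeation_events(direct_run.state_traj,
                                          direct_run.ion_levels)
        # an anchor that never occurs leaves every event uncovered
        raw, coverage = extract_cycles(events, "KKKKKK")
        assert raw == [] and coverage == 0.0

    def test_events_annotated_with_spans(self, direct_run):
        events = detect_permeation_events(direct_run.state_traj,
                                          direct_run.ion_levels)
        extract_cycles(events, "WKK0KW")
        for e in events:
            assert e.state_sequence[0] == e.state_sequence[-1] == "WKK0KW"
            assert e.end_frame > e.start_frame


class TestReduceCycle:
    def test_oscillation_removed(self):
        # B -> A -> B with no net jumps is a trivial oscillation
        red = reduce_cycle(list("ABABCA"), jumps=[0, 0, 0, 0, 0, 7], anchor="A")
        assert red.path == list("ABCA")

    def test_excursion_removed_not_reordered(self):
        # C's excursion (B..C..B, no jumps) disappears entirely
        red = reduce_cycle(list("ABCBDA"), jumps=[0, 1, 1, 1, 2, 7], anchor="A")
        assert red.path == list("ABDA")

    def test_repeat_with_jump_advance_keeps_first_arrival(self):
        red = reduce_cycle(list("ABCBDA"), jumps=[0, 1, 2, 5, 6, 7], anchor="A")
        assert red.path == list("ABCDA")

    def test_idempotent(self):
        red = reduce_cycle(list("ABACBDA"), jumps=[0, 1, 2, 3, 5, 6, 7], anchor="A")
        again = reduce_cycle(red.path, jumps=red.jump_offsets, anchor="A")
        assert again.path == red.path

    def test_unanchored_raises(self):
        with pytest.raises(ValueError, match="anchored"):
            reduce_cycle(list("ABC"), jumps=[0, 0, 0], anchor="A")

    def test_interior_uniqueness_enforced(self):
        with pytest.raises(ValueError, match="interior"):
            ReducedCycle(path=list("ABCBA"))

    @given(st.lists(st.sampled_from("ABCD"), min_size=0, max_size=12),
           st.integers(0, 3))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_rewriting_oracle(self, interior, jump_style):
        seq = ["A", *interior, "A"]
        rng = np.random.default_rng(len(interior) * 7 + jump_style)
        if jump_style == 0:
            jumps = np.zeros(len(seq), dtype=int)
        elif jump_style == 1:
            jumps = np.arange(len(seq))
        else:
            jumps = np.cumsum(rng.integers(-1, 3, size=len(seq)))
        got = reduce_cycle(seq, jumps=jumps, anchor="A").path
        expect = reduce_by_rewriting(seq, jumps, "A")
        assert got == expect
        # interior states unique, no consecutive duplicates
        assert len(set(got[1:-1])) == len(got[1:-1])
        assert all(a != b for a, b in zip(got, got[1:]))


class TestEdgeProbabilities:
    def test_single_loop_probability_one(self, direct_run):
        events = detect_permeation_events(direct_run.state_traj,
                                          direct_run.ion_levels)
        raw, _ = extract_cycles(events, "WKK0KW")
        reduced = reduce_cycles(raw)
        df = cycle_edge_probabilities(reduced)
        assert (df["probability"] == 1.0).all()
        assert set(zip(df.from_state, df.to_state)) == set(reduced[0].edges)

    def test_fraction_of_cycles(self):
        reduced = [ReducedCycle(list("ABCA"), multiplicity=48),
                   ReducedCycle(list("ABDA"), multiplicity=52)]
        df = cycle_edge_probabilities(reduced).set_index(["from_state", "to_state"])
        assert df.loc[("B", "C"), "probability"] == pytest.approx(0.48)
        assert df.loc[("A", "B"), "probability"] == 1.0

    def test_outgoing_sums_bounded(self):
        reduced = [ReducedCycle(list("ABCA")), ReducedCycle(list("ACBA"))]
        df = cycle_edge_probabilities(reduced)
        sums = df.groupby("from_state")["probability"].sum()
        assert (sums <= 1 + 1e-9).all()


class TestMFPT:
    def test_degenerate_same_state(self):
        traj = StateTrajectory([S[0], S[1]], 20.0)
        assert compute_mfpt(traj, S[0], S[0]).mfpt_ns == 0.0

    def test_geometric_two_state(self):
        # A -> B with probability 0.25 per 20 ps step: MFPT = 80 ps
        T = [[0.75, 0.25], [0.5, 0.5]]
        traj = generate_markov_sequence(T, 200_000, seed=8, states=S[:2])
        res = compute_mfpt(traj, S[0], S[1], n_boundaries=None, n_resamples=0)
        se = res.passage_times_ns.std(ddof=1) / np.sqrt(res.n_passages)
        assert res.mfpt_ns == pytest.approx(0.080, abs=3 * se)

    def test_missing_passage_reported_as_none(self):
        traj = StateTrajectory([S[0], S[1]], 20.0)
        res = compute_mfpt(traj, S[1], S[0])
        assert res.mfpt_ns is None and res.n_passages == 0

    def test_jump_condition_excludes_cross_cycle_passages(self):
        # i..j passage accruing >= 7 jumps is not within one cycle
        states = [S[0], S[1], S[2], S[1], S[0]]
        jumps = [0, 1, 2, 9, 10]
        traj = StateTrajectory(states, 20.0, jumps=np.array(jumps))
        incl = compute_mfpt(traj, S[2], S[0], n_boundaries=None, n_resamples=0)
        excl = compute_mfpt(traj, S[2], S[0], n_boundaries=7, n_resamples=0)
        assert incl.n_passages == 1
        assert excl.n_passages == 0

    def test_agrees_with_fundamental_matrix(self, rng):
        from conftest import random_stochastic

        T = random_stochastic(rng, 5)
        traj = generate_markov_sequence(T, 100_000, seed=21, states=S)
        oracle_steps = mfpt_linear_solve(T, target=3)
        res = compute_mfpt(traj, S[0], S[3], n_boundaries=None, n_resamples=0)
        se = res.passage_times_ns.std(ddof=1) / np.sqrt(res.n_passages)
        expect_ns = oracle_steps[0] * 20.0 / 1000.0
        assert abs(res.mfpt_ns - expect_ns) < 3 * se + 1e-9

    def test_bca_interval_covers_mean(self, direct_run):
        res = compute_mfpt(direct_run.state_traj, "WKK0KW", "C0KKWC",
                           n_resamples=200, seed=4)
        assert res.ci_low <= res.mfpt_ns <= res.ci_high


def test_edge_table_joins_probability_and_mfpt(direct_run):
    events = detect_permeation_events(direct_run.state_traj,
                                      direct_run.ion_levels)
    raw, _ = extract_cycles(events, "WKK0KW")
    reduced = reduce_cycles(raw)
    df = edge_table(reduced, direct_run.state_traj, n_resamples=100, seed=0)
    assert {"probability", "mfpt_ns", "mfpt_lo", "mfpt_hi"} <= set(df.columns)
    assert df["mfpt_ns"].notna().all()
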