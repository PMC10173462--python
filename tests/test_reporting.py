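import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from permcycle import graphs
from permcycle.cli import main
from permcycle.io import read_states, write_states
from permcycle.pipeline import pooled_current, run_pipeline


class TestStateFileFormat:
    def test_roundtrip(self, tmp_path, direct_run):
        path = tmp_path / "states.tsv"
        write_states(path, direct_run.state_traj)
        back = read_states(path)
        assert back.states == direct_run.state_traj.states
        assert np.array_equal(back.jumps, direct_run.state_traj.jumps)
        assert back.frame_interval == direct_run.state_traj.frame_interval

    def test_missing_header_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("0\tWKK0KW\t0\n")
        with pytest.raises(ValueError, match="frame_interval"):
            read_states(p)


class TestCycleGraph:
    def _edge_table(self):
        return pd.DataFrame([
            {"from_state": "A", "to_state": "B", "probability": 0.9,
             "ci_low": 0.8, "ci_high": 1.0, "mfpt_ns": 0.5},
            {"from_state": "B", "to_state": "A", "probability": 0.4,
             "ci_low": 0.3, "ci_high": 0.5, "mfpt_ns": 2.0},
        ])

    def test_node_threshold_removes_rare_states(self):
        part = {"A": 0.95, "B": 0.05}
        G = graphs.build_cycle_graph(edge_table=self._edge_table(),
                                     participation=part, node_threshold=0.10)
        assert "B" not in G and "A" in G

    def test_zero_threshold_is_identity(self):
        G = graphs.build_cycle_graph(edge_table=self._edge_table(),
                                     participation={}, node_threshold=0.0)
        assert set(G.nodes) == {"A", "B"}

    def test_flux_threshold(self):
        F = np.array([[0.0, 1.0, 0.1], [-1.0, 0.0, 0.05],
                      [-0.1, -0.05, 0.0]])
        G = graphs.build_cycle_graph(flux_matrix=F, states=["A", "B", "C"],
                                     node_threshold=0.0, edge_threshold=0.15)
        assert set(G.edges) == {("A", "B")}  # 0.1 and 0.05 fall below 0.15*max

    def test_filtering_monotone(self):
        part = {"A": 0.9, "B": 0.3}
        sizes = []
        for thr in (0.0, 0.2, 0.5, 0.95):
            G = graphs.build_cycle_graph(edge_table=self._edge_table(),
                                         participation=part, node_threshold=thr)
            sizes.append((G.number_of_nodes(), G.number_of_edges()))
        assert sizes == sorted(sizes, reverse=True)

    def test_graph_roundtrip(self, tmp_path):
        part = {"A": 0.9, "B": 0.9}
        G = graphs.build_cycle_graph(edge_table=self._edge_table(),
                                     stationary={"A": 0.6, "B": 0.4},
                                     participation=part, node_threshold=0.0)
        for fmt in ("graphml", "json"):
            p = tmp_path / f"g.{fmt}"
            graphs.write_graph(G, p)
            H = graphs.read_graph(p)
            assert set(H.nodes) == set(G.nodes)
            assert set(H.edges) == set(G.edges)
            for a, b in G.edges:
                assert H.edges[a, b]["probability"] == pytest.approx(
                    G.edges[a, b]["probability"])
        dot = tmp_path / "g.dot"
        graphs.write_graph(G, dot)
        assert "digraph" in dot.read_text()


def test_pooled_current_t_interval():
    mean, ci = pooled_current([10.0, 12.0, 14.0])
    assert mean == pytest.approx(12.0)
    # t(0.975, df=2) = 4.3027; SE = 2/sqrt(3)
    half = 4.302652729911275 * 2 / np.sqrt(3)
    assert ci[0] == pytest.approx(12 - half)
    assert ci[1] == pytest.approx(12 + half)


class TestPipeline:
    def test_synthetic_bundle(self, tmp_path):
        cfg = {"synthetic": {"mechanism": "direct_knockon", "n_permeations": 8,
                             "noise": 0.0},
               "seed": 3, "bootstrap_B": 50, "ck_count_floor": 10}
        res = run_pipeline(cfg, tmp_path / "out")
        assert res.coverage == 1.0
        assert res.water_permeations == 0
        assert "water permeations: 0" in res.summary
        for name in ("model.json", "events.json", "edges.csv", "summary.txt",
                     "reduced_cycles.jsonl", "cycle_graph.graphml",
                     "flux_graph.graphml", "states_0.tsv", "ck.csv"):
            assert (tmp_path / "out" / name).exists(), name
        events = json.loads((tmp_path / "out" / "events.json").read_text())
        assert len(events) == 8

    def test_state_file_inputs_pool(self, tmp_path, direct_run):
        p = tmp_path / "states.tsv"
        write_states(p, direct_run.state_traj)
        cfg = {"state_files": [str(p), str(p)], "bootstrap_B": 0,
               "ck_count_floor": 10}
        res = run_pipeline(cfg, tmp_path / "out")
        assert len(res.trajectories) == 2
        assert len(res.currents_pA) == 2
        assert res.current_ci_pA is not None

    def test_rerun_identical(self, tmp_path):
        cfg = {"synthetic": {"mechanism": "soft_knockon", "n_permeations": 5},
               "seed": 4, "bootstrap_B": 0, "ck_count_floor": 5}
        run_pipeline(cfg, tmp_path / "a")
        run_pipeline(cfg, tmp_path / "b")
        assert (tmp_path / "a" / "summary.txt").read_text() == \
            (tmp_path / "b" / "summary.txt").read_text()


class TestCLI:
    def test_simulate_then_analyze(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "sim"
        r = runner.invoke(main, ["simulate", "-o", str(out),
                                 "--n-permeations", "6", "--seed", "2"])
        assert r.exit_code == 0, r.output
        assert "6 planted events" in r.output

        r = runner.invoke(main, ["msm", str(out / "states.tsv"),
                                 "-o", str(out / "model.json")])
        assert r.exit_code == 0, r.output

        r = runner.invoke(main, ["cycles", str(out / "states.tsv"),
                                 "--edges-out", str(out / "edges.csv"),
                                 "--bootstrap", "50"])
        assert r.exit_code == 0, r.output
        assert "coverage 1.000" in r.output

        r = runner.invoke(main, ["current", str(out / "states.tsv")])
        assert r.exit_code == 0, r.output
        assert "J=42" in r.output

        r = runner.invoke(main, ["graph", "--model", str(out / "model.json"),
                                 "--node-threshold", "0",
                                 "-o", str(out / "flux.graphml")])
        assert r.exit_code == 0, r.output

        r = runner.invoke(main, ["mfpt", str(out / "states.tsv"),
                                 "--from", "WKK0KW", "--to", "C0KKWC",
                                 "--bootstrap", "50"])
        assert r.exit_code == 0, r.output
        assert "MFPT" in r.output

    def test_run_pipeline_from_yaml(self, tmp_path):
        import yaml

        cfgfile = tmp_path / "config.yaml"
        cfgfile.write_text(yaml.safe_dump({
            "synthetic": {"mechanism": "direct_knockon", "n_permeations": 5},
            "seed": 1, "bootstrap_B": 0, "ck_count_floor": 5}))
        runner = CliRunner()
        r = runner.invoke(main, ["run", str(cfgfile), "-o", str(tmp_path / "out")])
        assert r.exit_code == 0, r.output
        assert "permeation events: 5" in r.output
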