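"""Target-set connectivity statistics and the random-gene-set null."""

import math

import numpy as np
import pytest

from litdisc.network import (
    InteractionNetwork,
    NetworkStatsVector,
    compare_to_null,
    null_histogram_table,
    read_edge_list,
    sample_null_distribution,
    target_network_stats,
    write_edge_list,
)
from litdisc.simulate import generate_network
from litdisc.stats import StatsDomainError


class TestEdgeListIO:
    def test_canonicalization(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("A\tB\nB\tA\nC\tC\n")
        net = read_edge_list(path)
        assert net.edges == {frozenset({"A", "B"})}
        assert "C" not in net.nodes  # self-loop dropped entirely

    def test_empty_file(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("")
        net = read_edge_list(path)
        assert net.nodes == set() and net.edges == set()

    def test_round_trip(self, tmp_path):
        net = InteractionNetwork.from_edges(
            [("A", "B"), ("B", "C"), ("D", "E"), ("A", "E")]
        )
        path = tmp_path / "e.tsv"
        write_edge_list(net, path)
        assert read_edge_list(path) == net

    def test_bad_row(self, tmp_path):
        path = tmp_path / "e.tsv"
        path.write_text("A\tB\tC\n")
        with pytest.raises(ValueError, match=":1"):
            read_edge_list(path)


class TestTargetNetworkStats:
    def test_toy_graph_hand_enumeration(self):
        net = InteractionNetwork.from_edges([("A", "B"), ("B", "C"), ("D", "E")])
        stats = target_network_stats(net, {"A", "B", "D"})
        assert stats == NetworkStatsVector(
            n_any_interaction=3, n_interacting_within=2,
            n_edges_within=1, max_degree_within=1,
        )

    def test_empty_target_set(self):
        net = InteractionNetwork.from_edges([("A", "B")])
        assert target_network_stats(net, set()) == NetworkStatsVector(0, 0, 0, 0)

    def test_clique(self):
        nodes = ["A", "B", "C", "D"]
        edges = [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]]
        net = InteractionNetwork.from_edges(edges)
        stats = target_network_stats(net, set(nodes))
        assert stats.n_edges_within == 6 and stats.max_degree_within == 3

    def test_targets_absent_from_network_are_isolated(self):
        net = InteractionNetwork.from_edges([("A", "B")])
        stats = target_network_stats(net, {"A", "Z1", "Z2"})
        assert stats.n_any_interaction == 1
        assert stats.n_interacting_within == 0

    def test_invariant_chain(self):
        rng = np.random.default_rng(4)
        net = generate_network(80, 0.1, [f"G{i + 1:04d}" for i in range(8)], 0.5, seed=2)
        nodes = sorted(net.nodes)
        for _ in range(20):
            targets = {nodes[j] for j in rng.choice(len(nodes), size=15, replace=False)}
            s = target_network_stats(net, targets)
            assert s.n_interacting_within <= s.n_any_interaction <= len(targets)
            assert s.n_edges_within <= s.n_interacting_within * (s.n_interacting_within - 1) / 2
            assert s.max_degree_within <= max(s.n_interacting_within - 1, 0)


class TestNullDistribution:
    def test_edgeless_network_all_zero(self):
        net = InteractionNetwork.from_edges([], nodes=[f"N{i}" for i in range(50)])
        samples = sample_null_distribution(net, net.nodes, 10, n_iterations=20, seed=0)
        assert (samples.to_numpy() == 0).all()

    def test_deterministic(self):
        net = generate_network(100, 0.05, [], 0.0, seed=1)
        s1 = sample_null_distribution(net, net.nodes, 20, n_iterations=30, seed=5)
        s2 = sample_null_distribution(net, net.nodes, 20, n_iterations=30, seed=5)
        assert s1.equals(s2)

    def test_set_size_exceeds_universe(self):
        net = InteractionNetwork.from_edges([("A", "B")])
        with pytest.raises(StatsDomainError):
            sample_null_distribution(net, net.nodes, 5)

    def test_null_mean_matches_density_closed_form(self):
        # random k-sets see the graph's average pair density:
        # E[edges_within] = C(k,2) * [C(m,2) p_in + (C(n,2) - C(m,2)) p_out] / C(n,2)
        n, m, p_in, p_out, k = 600, 60, 0.3, 0.01, 60
        module = [f"G{i + 1:04d}" for i in range(m)]
        net = generate_network(n, p_out, module, p_in, seed=9)
        universe = {f"G{i + 1:04d}" for i in range(n)}
        samples = sample_null_distribution(net, universe, k, n_iterations=600, seed=3)
        pair_density = (
            math.comb(m, 2) * p_in + (math.comb(n, 2) - math.comb(m, 2)) * p_out
        ) / math.comb(n, 2)
        expected = math.comb(k, 2) * pair_density
        observed = samples["n_edges_within"].mean()
        se = samples["n_edges_within"].std(ddof=1) / math.sqrt(len(samples))
        assert abs(observed - expected) <= 3 * se + 0.05 * expected


class TestCompareToNull:
    def test_published_summary_statistics(self):
        # a null sample constructed to match the published mean/sd reproduces
        # the published z and t for the "targets interacting" column
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        x = (x - x.mean()) / x.std(ddof=1)
        import pandas as pd

        vals = 155.4 + 36.2 * x
        samples = pd.DataFrame({
            "n_any_interaction": vals, "n_interacting_within": vals,
            "n_edges_within": vals, "max_degree_within": vals,
        })
        observed = NetworkStatsVector(879, 879, 879, 879)
        comp = compare_to_null(observed, samples)
        assert comp.z["n_interacting_within"] == pytest.approx(20.0, rel=0.01)
        assert comp.t["n_interacting_within"] == pytest.approx(-200.0, rel=0.01)
        assert comp.empirical_p["n_interacting_within"] == pytest.approx(1 / 101)

    def test_observed_equal_to_samples(self):
        import pandas as pd

        samples = pd.DataFrame({k: [5.0] * 10 for k in (
            "n_any_interaction", "n_interacting_within",
            "n_edges_within", "max_degree_within")})
        comp = compare_to_null(NetworkStatsVector(5, 5, 5, 5), samples)
        assert comp.z["n_edges_within"] == 0.0
        assert comp.empirical_p["n_edges_within"] == 1.0

    def test_zero_sd_with_different_observed(self):
        import pandas as pd

        samples = pd.DataFrame({k: [5.0] * 10 for k in (
            "n_any_interaction", "n_interacting_within",
            "n_edges_within", "max_degree_within")})
        comp = compare_to_null(NetworkStatsVector(9, 9, 9, 9), samples)
        assert np.isinf(comp.z["n_edges_within"])
        assert comp.empirical_p["n_edges_within"] == pytest.approx(1 / 11)

    def test_t_sign_convention(self):
        # observed above the null mean -> negative t (null sample vs reference)
        rng = np.random.default_rng(1)
        import pandas as pd

        vals = rng.normal(10, 2, size=50)
        samples = pd.DataFrame({k: vals for k in (
            "n_any_interaction", "n_interacting_within",
            "n_edges_within", "max_degree_within")})
        comp = compare_to_null(NetworkStatsVector(100, 100, 100, 100), samples)
        assert comp.t["n_edges_within"] < 0

    def test_histogram_export_structure(self):
        net = generate_network(100, 0.05, [], 0.0, seed=2)
        samples = sample_null_distribution(net, net.nodes, 20, n_iterations=50, seed=1)
        observed = target_network_stats(net, set(sorted(net.nodes)[:20]))
        hist = null_histogram_table(samples, observed, bins=10)
        assert set(hist["statistic"]) == {
            "n_any_interaction", "n_interacting_within",
            "n_edges_within", "max_degree_within",
        }
        for _, grp in hist.groupby("statistic"):
            assert grp["count"].sum() == 50


class TestPlantedModuleRecovery:
    def test_planted_module_z_large(self):
        # a 10x within-module edge-probability contrast must push the
        # within-set edge z-score far above the null
        module = [f"G{i + 1:04d}" for i in range(60)]
        net = generate_network(800, 0.01, module, 0.1, seed=21)
        universe = {f"G{i + 1:04d}" for i in range(800)}
        observed = target_network_stats(net, set(module))
        samples = sample_null_distribution(net, universe, 60, n_iterations=100, seed=22)
        comp = compare_to_null(observed, samples)
        assert comp.z["n_edges_within"] > 5
        assert comp.empirical_p["n_edges_within"] == pytest.approx(1 / 101)

    def test_null_draw_empirical_p_uniform_tail(self):
        net = generate_network(400, 0.02, [], 0.0, seed=30)
        universe = sorted(net.nodes)
        samples = sample_null_distribution(net, set(universe), 40, n_iterations=100, seed=31)
        rng = np.random.default_rng(32)
        low = 0
        reps = 300
        for _ in range(reps):
            draw = {universe[j] for j in rng.choice(len(universe), 40, replace=False)}
            obs = target_network_stats(net, draw)
            comp = compare_to_null(obs, samples)
            low += comp.empirical_p["n_edges_within"] <= 0.05
        assert low / reps <= 0.07
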