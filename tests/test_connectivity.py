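"""STTC, graph construction, modularity and comparison tests."""

import networkx as nx
import numpy as np
import pytest
from scipy import stats

import bnnvision as bv
from bnnvision.connectivity import ConnectivityGraph


def poisson_train(rate, T, rng):
    n = rng.poisson(rate * T)
    return bv.SpikeTrain(np.sort(rng.uniform(0, T, n)), T)


def brute_force_sttc(a, b, dt):
    """Independent oracle: explicit interval-union tiling + nested loops."""
    def tiled(times, T):
        intervals = sorted((max(0.0, t - dt), min(T, t + dt)) for t in times)
        merged = []
        for s, e in intervals:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return sum(e - s for s, e in merged) / T

    def prop(x, y):
        return sum(
            1 for t in x if any(abs(t - u) <= dt for u in y)
        ) / len(x)

    ta, tb = tiled(a.times, a.duration), tiled(b.times, b.duration)
    pa, pb = prop(a.times, b.times), prop(b.times, a.times)
    return 0.5 * ((pa - tb) / (1 - pa * tb) + (pb - ta) / (1 - pb * ta))


class TestSttc:
    def test_identical_trains_give_one(self):
        t = bv.SpikeTrain(np.array([1.0, 5.0, 12.0, 30.0]), 600.0)
        assert bv.sttc(t, t) == pytest.approx(1.0, abs=1e-12)

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = poisson_train(2.0, 60.0, rng)
            b = poisson_train(3.0, 60.0, rng)
            assert bv.sttc(a, b) == pytest.approx(bv.sttc(b, a), abs=1e-12)

    def test_bounded(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            a = poisson_train(5.0, 20.0, rng)
            b = poisson_train(5.0, 20.0, rng)
            assert -1.0 <= bv.sttc(a, b) <= 1.0

    def test_matches_brute_force_oracle_on_toy_trains(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            na, nb = rng.integers(1, 11, size=2)
            a = bv.SpikeTrain(np.sort(rng.uniform(0, 5.0, na)), 5.0)
            b = bv.SpikeTrain(np.sort(rng.uniform(0, 5.0, nb)), 5.0)
            assert bv.sttc(a, b) == pytest.approx(
                brute_force_sttc(a, b, 0.01), abs=1e-12
            )

    def test_edge_clipped_tiles_match_oracle(self):
        # spikes at the recording boundaries exercise tile clipping
        a = bv.SpikeTrain(np.array([0.0, 0.005, 1.0]), 1.0)
        b = bv.SpikeTrain(np.array([0.004, 0.996]), 1.0)
        assert bv.sttc(a, b) == pytest.approx(brute_force_sttc(a, b, 0.01), abs=1e-12)

    def test_independent_trains_average_zero(self):
        rng = np.random.default_rng(3)
        vals = [
            bv.sttc(poisson_train(2.0, 600.0, rng), poisson_train(2.0, 600.0, rng))
            for _ in range(200)
        ]
        assert abs(np.mean(vals)) <= 0.02

    def test_empty_train_is_zero_with_warning(self):
        a = bv.SpikeTrain(np.empty(0), 10.0)
        b = bv.SpikeTrain(np.array([1.0]), 10.0)
        with pytest.warns(UserWarning):
            assert bv.sttc(a, b) == 0.0


class TestChannelSelection:
    def test_grid_gives_40_unique_spread_channels(self):
        yy, xx = np.divmod(np.arange(1024), 32)
        pos = np.column_stack([xx, yy]).astype(float)
        rep = bv.select_representative_channels(pos, k=40, seed=0)
        assert len(rep) == 40 and len(set(rep)) == 40
        # spatially spread: selected channels span most of the grid
        assert np.ptp(pos[rep, 0]) > 20 and np.ptp(pos[rep, 1]) > 20

    def test_k_equals_n_is_identity(self):
        pos = np.random.default_rng(0).random((12, 2))
        rep = bv.select_representative_channels(pos, k=12, seed=0)
        assert np.array_equal(rep, np.arange(12))

    def test_deterministic(self):
        pos = np.random.default_rng(1).random((100, 2))
        a = bv.select_representative_channels(pos, k=10, seed=5)
        b = bv.select_representative_channels(pos, k=10, seed=5)
        assert np.array_equal(a, b)

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError):
            bv.select_representative_channels(np.zeros((5, 2)), k=10)


class TestBuildGraph:
    def test_null_edge_density_calibrated(self):
        rng = np.random.default_rng(0)
        trains = [poisson_train(1.0, 120.0, rng) for _ in range(10)]
        g = bv.build_graph(trains, n_surrogates=100, alpha=0.05, seed=1)
        n_pairs = 45
        density = g.graph.number_of_edges() / n_pairs
        assert density <= 0.05 + 2 * np.sqrt(0.05 / n_pairs)

    def test_synchronous_pair_always_detected(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            trains = [poisson_train(1.0, 60.0, rng) for _ in range(6)]
            shared = np.sort(rng.uniform(0, 60.0, 60))
            trains[0] = bv.SpikeTrain(shared, 60.0)
            trains[1] = bv.SpikeTrain(
                np.sort(np.clip(shared + rng.normal(0, 0.002, 60), 0, 60)), 60.0
            )
            g = bv.build_graph(trains, n_surrogates=50, seed=seed)
            assert g.graph.has_edge(0, 1)

    def test_symmetric_no_self_loops(self):
        rng = np.random.default_rng(2)
        trains = [poisson_train(2.0, 30.0, rng) for _ in range(8)]
        g = bv.build_graph(trains, n_surrogates=20, seed=0)
        assert not any(u == v for u, v in g.graph.edges)
        a = g.adjacency
        assert np.array_equal(a, a.T)


def star_graph(weights=0.5):
    g = nx.Graph()
    g.add_nodes_from(range(6))
    for leaf in range(1, 6):
        g.add_edge(0, leaf, weight=weights)
    return ConnectivityGraph(
        graph=g, channel_ids=np.arange(6), sttc_matrix=np.zeros((6, 6))
    )


class TestNodeMetrics:
    def test_star_graph_degree_and_strength(self):
        nm = bv.node_metrics(star_graph())
        assert nm.loc[0, "degree"] == 5
        assert nm.loc[0, "strength"] == pytest.approx(2.5)
        assert (nm.loc[1:, "degree"] == 1).all()

    def test_empty_graph_all_zero(self):
        g = nx.Graph()
        g.add_nodes_from(range(4))
        cg = ConnectivityGraph(graph=g, channel_ids=np.arange(4),
                               sttc_matrix=np.zeros((4, 4)))
        nm = bv.node_metrics(cg)
        assert (nm["degree"] == 0).all() and (nm["strength"] == 0).all()

    def test_handshake_lemma(self):
        rng = np.random.default_rng(0)
        g = nx.gnp_random_graph(20, 0.3, seed=3)
        nx.set_edge_attributes(g, 0.4, "weight")
        cg = ConnectivityGraph(graph=g, channel_ids=np.arange(20),
                               sttc_matrix=np.zeros((20, 20)))
        nm = bv.node_metrics(cg)
        assert nm["degree"].sum() == 2 * g.number_of_edges()


class TestConsensusModules:
    def _two_cliques(self):
        g = nx.Graph()
        for base in (0, 5):
            for i in range(base, base + 5):
                for j in range(i + 1, base + 5):
                    g.add_edge(i, j, weight=1.0)
        g.add_edge(0, 5, weight=0.05)
        return ConnectivityGraph(graph=g, channel_ids=np.arange(10),
                                 sttc_matrix=np.zeros((10, 10)))

    def test_two_cliques_recovered(self):
        for seed in range(5):
            part = bv.consensus_modules(self._two_cliques(), n_runs=20, seed=seed)
            assert len(set(part.values())) == 2
            assert len({part[i] for i in range(5)}) == 1
            assert len({part[i] for i in range(5, 10)}) == 1

    def test_partition_covers_all_nodes(self):
        cg = self._two_cliques()
        part = bv.consensus_modules(cg, n_runs=10, seed=0)
        assert set(part) == set(range(10))

    def test_planted_block_model_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(7)
        sizes = [10, 10, 10, 10]
        p_in, p_out = 0.8, 0.05
        g = nx.stochastic_block_model(
            sizes, np.full((4, 4), p_out) + np.eye(4) * (p_in - p_out), seed=7
        )
        nx.set_edge_attributes(g, 1.0, "weight")
        cg = ConnectivityGraph(graph=g, channel_ids=np.arange(40),
                               sttc_matrix=np.zeros((40, 40)))
        part = bv.consensus_modules(cg, n_runs=30, seed=1)
        planted = np.repeat(np.arange(4), 10)
        found = np.array([part[i] for i in range(40)])
        assert adjusted_rand_score(planted, found) >= 0.9


class TestWithinModuleZ:
    def test_uniform_within_degree_gives_zero(self):
        cg = TestConsensusModules()._two_cliques()
        part = {i: 0 if i < 5 else 1 for i in range(10)}
        z = bv.within_module_z(cg, part)
        # every clique node has equal within-module degree (the 0-5 bridge
        # crosses modules and does not count)
        assert all(v == 0.0 for v in z.values())

    def test_per_module_z_mean_is_zero(self):
        rng = np.random.default_rng(0)
        g = nx.gnp_random_graph(30, 0.3, seed=5)
        nx.set_edge_attributes(g, 1.0, "weight")
        cg = ConnectivityGraph(graph=g, channel_ids=np.arange(30),
                               sttc_matrix=np.zeros((30, 30)))
        part = {i: i % 3 for i in range(30)}
        z = bv.within_module_z(cg, part)
        for m in range(3):
            vals = [z[i] for i in range(30) if i % 3 == m]
            if any(v != 0 for v in vals):
                assert abs(np.mean(vals)) < 1e-12

    def test_hub_two_sigma_above_mean(self):
        g = nx.Graph()
        g.add_nodes_from(range(6))
        # within one module: node 0 with degree k = mean + 2 sd
        for j in (1, 2, 3, 4):
            g.add_edge(0, j, weight=1.0)
        cg = ConnectivityGraph(graph=g, channel_ids=np.arange(6),
                               sttc_matrix=np.zeros((6, 6)))
        part = {i: 0 for i in range(6)}
        z = bv.within_module_z(cg, part)
        kin = np.array([4, 1, 1, 1, 1, 0])
        expected = (4 - kin.mean()) / kin.std()
        assert z[0] == pytest.approx(expected, abs=1e-12)

    def test_singleton_module_is_zero(self):
        cg = star_graph()
        part = {0: 0, 1: 1, 2: 1, 3: 1, 4: 1, 5: 1}
        assert bv.within_module_z(cg, part)[0] == 0.0


class TestParticipation:
    def test_all_within_own_module_gives_zero(self):
        cg = star_graph()
        part = {i: 0 for i in range(6)}
        p = bv.participation_coeff(cg, part)
        assert all(v == 0.0 for v in p.values())

    def test_even_spread_over_four_modules(self):
        g = nx.Graph()
        for j in (1, 2, 3, 4):
            g.add_edge(0, j, weight=1.0)
        cg = ConnectivityGraph(graph=g, channel_ids=np.arange(5),
                               sttc_matrix=np.zeros((5, 5)))
        part = {0: 0, 1: 1, 2: 2, 3: 3, 4: 4}
        # node 0's four edges hit four distinct foreign modules
        assert bv.participation_coeff(cg, part)[0] == pytest.approx(0.75)

    def test_bounds_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for seed in range(5):
            g = nx.gnp_random_graph(25, 0.25, seed=seed)
            nx.set_edge_attributes(g, 0.3, "weight")
            cg = ConnectivityGraph(graph=g, channel_ids=np.arange(25),
                                   sttc_matrix=np.zeros((25, 25)))
            part = {i: int(rng.integers(0, 4)) for i in range(25)}
            n_mod = len(set(part.values()))
            for v in bv.participation_coeff(cg, part).values():
                assert 0.0 <= v <= 1.0 - 1.0 / n_mod + 1e-12


class TestCompareConditions:
    def _metrics_frame(self, rng, shift=0.0, n=200):
        import pandas as pd

        return pd.DataFrame({
            "degree": rng.normal(10 + shift, 1, n),
            "strength": rng.normal(3 + shift, 1, n),
            "within_module_z": rng.normal(0 + shift, 1, n),
            "participation": rng.normal(0.4 + 0.1 * shift, 0.1, n),
        })

    def test_identical_samples_not_significant(self):
        rng = np.random.default_rng(0)
        df = self._metrics_frame(rng)
        out = bv.compare_conditions(df, df.copy())
        assert (out["p"] > 0.99).all()
        assert np.allclose(out["t"], 0.0, atol=1e-12)

    def test_shifted_gaussians_detected(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = self._metrics_frame(rng)
            b = self._metrics_frame(rng, shift=2.0)
            out = bv.compare_conditions(a, b)
            if (out.loc[["degree", "strength"], "p"] < 1e-4).all():
                hits += 1
        assert hits >= 99

    def test_summary_columns_present(self):
        rng = np.random.default_rng(1)
        out = bv.compare_conditions(
            self._metrics_frame(rng), self._metrics_frame(rng),
            before_edges=[0.1, 0.2], after_edges=[0.3, 0.4],
        )
        for col in ("n_before", "mean_before", "sd_before", "n_after",
                    "mean_after", "sd_after", "t", "p"):
            assert col in out.columns
        assert "edge_weight" in out.index


class TestTrainingEffectRecovery:
    def test_added_correlations_increase_network_metrics(self):
        """Synthetic before/after recordings: adding jitter-correlated pairs
        produces significant increases in degree, strength and participation."""
        nch = 30
        cfg = bv.SimulatorConfig(
            n_channels=nch, spontaneous_rate=1.5, burst_rate_per_min=0.0,
        )
        before = bv.simulate_spontaneous(120.0, cfg, seed=0)
        after_base = bv.simulate_spontaneous(120.0, cfg, seed=1)
        rng = np.random.default_rng(2)
        pairs = [tuple(rng.choice(nch, 2, replace=False)) for _ in range(45)]
        after = bv.inject_correlated_pairs(after_base, pairs, shared_rate=2.0, seed=3)
        frames, edges = {}, {}
        for tag, rec in (("before", before), ("after", after)):
            trains = [bv.SpikeTrain(rec.train(c), rec.duration) for c in range(nch)]
            g = bv.build_graph(trains, n_surrogates=50, seed=4)
            part = bv.consensus_modules(g, n_runs=20, seed=5)
            frames[tag] = bv.node_metrics(g, part)
            edges[tag] = [d["weight"] for _, _, d in g.graph.edges(data=True)]
        out = bv.compare_conditions(
            frames["before"], frames["after"], edges["before"], edges["after"]
        )
        for metric in ("degree", "strength", "participation"):
            assert out.loc[metric, "mean_after"] > out.loc[metric, "mean_before"]
            assert out.loc[metric, "p"] < 0.05
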