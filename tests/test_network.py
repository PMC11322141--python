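"""Network construction: edge calling, thresholds, bipartite pruning."""

import numpy as np
import pandas as pd
import pytest

from reservoirnet import (
    Block,
    ConfigurationError,
    CorrelationResult,
    NutrientSeries,
    OtuTable,
    SimulationScenario,
    build_network,
    build_nutrient_network,
    generate_counts,
    generate_nutrients,
    network_from_table,
    spearman_all_pairs,
)

from conftest import brute_force_bh, brute_force_spearman


def make_corr(ids, rho_pairs, p_pairs, n=20):
    v = len(ids)
    rho = np.eye(v)
    p = np.zeros((v, v))
    p_adj = np.zeros((v, v))
    for (i, j), r in rho_pairs.items():
        rho[i, j] = rho[j, i] = r
    for (i, j), (praw, padj) in p_pairs.items():
        p[i, j] = p[j, i] = praw
        p_adj[i, j] = p_adj[j, i] = padj
    return CorrelationResult(list(ids), rho, p, p_adj, n)


class TestBuildNetwork:
    def test_threshold_is_strict(self):
        corr = make_corr(["a", "b"], {(0, 1): 0.6}, {(0, 1): (0.0001, 0.0001)})
        assert build_network(corr).number_of_edges() == 0
        corr = make_corr(["a", "b"], {(0, 1): 0.601}, {(0, 1): (0.0001, 0.0001)})
        assert build_network(corr).number_of_edges() == 1

    def test_all_subthreshold_gives_empty_edge_set(self):
        rng = np.random.default_rng(0)
        corr = spearman_all_pairs(rng.normal(size=(5, 200)))
        assert build_network(corr).number_of_edges() == 0

    def test_three_variable_enumeration(self):
        # pairs (a,b): rho .9 / p .001 -> edge; (a,c): -.7/.005 -> negative edge;
        # (b,c): .9/.02 -> fails alpha
        corr = make_corr(
            ["a", "b", "c"],
            {(0, 1): 0.9, (0, 2): -0.7, (1, 2): 0.9},
            {(0, 1): (0.001, 0.001), (0, 2): (0.005, 0.005), (1, 2): (0.02, 0.02)},
        )
        g = build_network(corr)
        assert set(map(frozenset, g.edges)) == {frozenset("ab"), frozenset("ac")}
        signs = [d["sign"] for _, _, d in g.edges(data=True)]
        assert signs.count("negative") == 1
        assert all(
            (d["sign"] == "positive") == (d["rho"] > 0) for _, _, d in g.edges(data=True)
        )

    def test_isolated_nodes_configurable(self):
        corr = make_corr(["a", "b", "c"], {(0, 1): 0.9}, {(0, 1): (0.001, 0.001)})
        assert build_network(corr).number_of_nodes() == 3
        assert build_network(corr, keep_isolated=False).number_of_nodes() == 2

    def test_taxonomy_attached(self):
        corr = make_corr(["a", "b"], {(0, 1): 0.9}, {(0, 1): (0.001, 0.001)})
        tax = pd.Series({"a": "k__Bacteria; g__X"})
        g = build_network(corr, taxonomy=tax)
        assert g.nodes["a"]["lineage"] == "k__Bacteria; g__X"

    def test_config_errors(self):
        corr = make_corr(["a", "b"], {}, {})
        with pytest.raises(ConfigurationError):
            build_network(corr, rho_threshold=1.5)
        with pytest.raises(ConfigurationError):
            build_network(corr, alpha=0.0)


class TestOrderingInvariance:
    def test_edge_set_invariant_to_sample_and_otu_order(self):
        scenario = SimulationScenario(
            n_otus=12, n_ports=4, days=tuple(range(1, 11)),
            block_spec=(Block(3, 0.9),), seed=5,
        )
        table, _ = generate_counts(scenario)
        g1 = network_from_table(table, rho_threshold=0.4, alpha=0.05)
        shuffled = OtuTable(
            table.counts.iloc[::-1, ::-1], table.metadata.iloc[::-1]
        )
        g2 = network_from_table(shuffled, rho_threshold=0.4, alpha=0.05)
        assert set(map(frozenset, g1.edges)) == set(map(frozenset, g2.edges))


class TestOracleEquivalence:
    """Edge set equals a fully independent rank/Pearson/t/BH/threshold oracle."""

    @staticmethod
    def oracle_edges(data, ids, rho_thr=0.6, alpha=0.01):
        from scipy import stats as ss

        v, n = data.shape
        pairs, praws, rhos = [], [], {}
        for i in range(v):
            for j in range(i + 1, v):
                r = brute_force_spearman(list(data[i]), list(data[j]))
                t = r * ((n - 2) / (1 - r**2)) ** 0.5 if abs(r) < 1 else float("inf")
                p = 2 * ss.t.sf(abs(t), n - 2) if np.isfinite(t) else 0.0
                pairs.append((i, j))
                praws.append(p)
                rhos[(i, j)] = r
        padj = brute_force_bh(praws)
        return {
            frozenset((ids[i], ids[j]))
            for (i, j), p in zip(pairs, padj)
            if abs(rhos[(i, j)]) > rho_thr and p < alpha
        }

    @pytest.mark.parametrize("seed", range(20))
    def test_random_instances_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.integers(2, 9)
        n = rng.integers(4, 13)
        data = np.round(rng.normal(size=(v, n)), 1)  # rounding induces ties
        ids = [f"V{i}" for i in range(v)]
        corr = spearman_all_pairs(data, variable_ids=ids)
        g = build_network(corr, rho_threshold=0.6, alpha=0.01)
        assert set(map(frozenset, g.edges)) == self.oracle_edges(data, ids)


class TestNutrientNetwork:
    @staticmethod
    def _table_with_nutrients(seed=0):
        rng = np.random.default_rng(seed)
        n_samples = 30
        days = list(range(1, n_samples + 1))
        ts = np.linspace(1, 100, n_samples)
        driven = 200 * ts + rng.normal(0, 5, n_samples)  # monotone in TS + noise
        independent = rng.normal(1000, 100, n_samples)
        # large constant OTU buffers the denominator so closure effects stay
        # far below the edge-calling threshold
        counts = pd.DataFrame(
            {f"s{i}": [int(driven[i]), int(independent[i]), 10**6] for i in range(n_samples)},
            index=["driven", "independent", "buffer"],
        )
        meta = pd.DataFrame(
            {"day": days, "port": "SP1", "stage": "high"},
            index=pd.Index([f"s{i}" for i in range(n_samples)], name="sample"),
        )
        nutrients = NutrientSeries(
            pd.DataFrame({"day": days, "port": "SP1", "TS": ts, "TN": 5.0, "TP": 1.0})
        )
        return OtuTable(counts, meta), nutrients

    def test_monotone_otu_linked_independent_pruned(self):
        table, nutrients = self._table_with_nutrients()
        g = build_nutrient_network(table, nutrients)
        assert g.has_edge("driven", "TS")
        assert g.edges["driven", "TS"]["sign"] == "positive"
        assert "independent" not in g.nodes

    def test_missing_nutrient_record_lists_keys(self):
        table, nutrients = self._table_with_nutrients()
        trimmed = NutrientSeries(nutrients.records.iloc[:-1])
        with pytest.raises(ConfigurationError, match="30"):
            build_nutrient_network(table, trimmed)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_generator_planted_tn_block_connects_to_tn(self, seed):
        scenario = SimulationScenario.nutrient_demo(seed=seed)
        table, truth = generate_counts(scenario)
        nutrients = generate_nutrients(scenario)
        g = build_nutrient_network(table, nutrients)
        tn_driven = {otu for nut, otu in truth.nutrient_links if nut == "TN"}
        connected = {n for n in g.nodes if g.has_edge(n, "TN")}
        assert tn_driven <= connected
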