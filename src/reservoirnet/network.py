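"""Co-occurrence network construction and export.

A network is an undirected simple :class:`networkx.Graph`.  An edge (i, j)
is included iff |rho(i, j)| exceeds the correlation threshold AND the
FDR-adjusted p-value falls below alpha (a config flag switches to raw p).
Edge attributes carry rho, p values and the sign; node attributes carry the
node class (``otu`` or ``nutrient``) and, when a taxonomy map is supplied,
the lineage string.

The nutrient-OTU bipartite variant adds the three nutrient concentrations
(TS, TN, TP) as extra variables, builds the network identically, and then
prunes every OTU node with no direct edge to a nutrient node.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .abundance import ConfigurationError, OtuTable, relative_abundance
from .correlation import CorrelationResult, spearman_all_pairs
from .simulate import NutrientSeries

NUTRIENT_VARS = ("TS", "TN", "TP")


def build_network(
    corr: CorrelationResult,
    taxonomy: pd.Series | None = None,
    rho_threshold: float = 0.6,
    alpha: float = 0.01,
    use_adjusted_p: bool = True,
    keep_isolated: bool = True,
) -> nx.Graph:
    """Threshold a correlation result into a signed co-occurrence graph.

    The strict inequalities (|rho| > threshold, p < alpha) follow the
    edge-calling rule the pipeline implements: a correlation of exactly the
    threshold is excluded.
    """
    if not 0 < rho_threshold <= 1:
        raise ConfigurationError(f"rho_threshold must be in (0, 1], got {rho_threshold}")
    if not 0 < alpha < 1:
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")

    g = nx.Graph(rho_threshold=rho_threshold, alpha=alpha, use_adjusted_p=use_adjusted_p)
    skip = set(corr.zero_variance)
    for node in corr.variable_ids:
        attrs = {"node_class": "nutrient" if node in NUTRIENT_VARS else "otu"}
        if taxonomy is not None and node in taxonomy.index:
            attrs["lineage"] = taxonomy[node]
        g.add_node(node, **attrs)

    pairs = corr.pair_frame()
    p_col = "p_adj" if use_adjusted_p else "p_raw"
    called = pairs[(pairs["rho"].abs() > rho_threshold) & (pairs[p_col] < alpha)]
    for row in called.itertuples(index=False):
        if row.a in skip or row.b in skip:
            continue
        g.add_edge(
            row.a,
            row.b,
            rho=float(row.rho),
            p_raw=float(row.p_raw),
            p_adj=float(row.p_adj),
            sign="positive" if row.rho > 0 else "negative",
        )
    if not keep_isolated:
        g.remove_nodes_from(list(nx.isolates(g)))
    return g


def network_from_table(
    table: OtuTable,
    taxonomy: pd.Series | None = None,
    rho_threshold: float = 0.6,
    alpha: float = 0.01,
    **kwargs,
) -> nx.Graph:
    """Relative abundance -> all-pairs Spearman -> thresholded network."""
    rel = relative_abundance(table)
    corr = spearman_all_pairs(rel)
    return build_network(corr, taxonomy, rho_threshold, alpha, **kwargs)


def build_nutrient_network(
    table: OtuTable,
    nutrients: NutrientSeries,
    taxonomy: pd.Series | None = None,
    rho_threshold: float = 0.6,
    alpha: float = 0.01,
    **kwargs,
) -> nx.Graph:
    """Bipartite-style nutrient-OTU network.

    TS, TN and TP enter as three extra variables matched to samples by
    (day, port).  After full network construction, every OTU node with no
    direct edge to a nutrient node is removed; OTU-OTU edges among the
    retained nodes are kept.
    """
    rel = relative_abundance(table)
    nut = nutrients.records.set_index(["day", "port"])
    missing = []
    nutrient_rows = {name: [] for name in NUTRIENT_VARS}
    for sid in table.sample_ids:
        key = (int(table.metadata.loc[sid, "day"]), table.metadata.loc[sid, "port"])
        if key not in nut.index:
            missing.append(key)
            continue
        rec = nut.loc[key]
        for name in NUTRIENT_VARS:
            nutrient_rows[name].append(float(rec[name]))
    if missing:
        raise ConfigurationError(
            "samples lacking nutrient records for (day, port): "
            + ", ".join(map(str, sorted(set(missing))))
        )
    aug = pd.concat(
        [rel, pd.DataFrame(nutrient_rows, index=rel.columns).T],
        axis=0,
    )
    corr = spearman_all_pairs(aug)
    g = build_network(corr, taxonomy, rho_threshold, alpha, **kwargs)
    keep = set(NUTRIENT_VARS) & set(g.nodes)
    keep |= {n for n in g.nodes if any(nb in NUTRIENT_VARS for nb in g.neighbors(n))}
    return g.subgraph(keep).copy()


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_edge_list(g: nx.Graph, path) -> None:
    rows = [
        {
            "node_a": a,
            "node_b": b,
            "rho": d["rho"],
            "p_raw": d["p_raw"],
            "p_adj": d["p_adj"],
            "sign": d["sign"],
        }
        for a, b, d in sorted(g.edges(data=True), key=lambda e: (str(e[0]), str(e[1])))
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "rho", "p_raw", "p_adj", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def write_node_table(g: nx.Graph, path, betweenness: dict | None = None) -> None:
    rows = []
    for n in sorted(g.nodes, key=str):
        d = g.nodes[n]
        rows.append(
            {
                "node": n,
                "class": d.get("node_class", "otu"),
                "lineage": d.get("lineage", ""),
                "betweenness": betweenness.get(n, 0.0) if betweenness else "",
            }
        )
    pd.DataFrame(rows, columns=["node", "class", "lineage", "betweenness"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(g: nx.Graph, path) -> None:
    # rebuild with sorted nodes/edges so identical graphs serialize identically
    h = nx.Graph(**g.graph)
    for n in sorted(g.nodes, key=str):
        h.add_node(n, **g.nodes[n])
    for a, b, d in sorted(g.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
        h.add_edge(a, b, **d)
    nx.write_graphml(h, Path(path))
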