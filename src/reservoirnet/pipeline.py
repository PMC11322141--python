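"""End-to-end orchestration: preprocess -> networks -> topology ->
robustness -> stage comparison, with a reproducibility manifest.

A run is configured by a plain dict (or YAML file) and a seed.  Inputs are
either a named simulation scenario or paths to OTU-table / metadata /
taxonomy / nutrient TSVs.  All outputs are TSV/GraphML/JSON; re-running
with the same config and seed reproduces every output byte for byte.

Network grouping
----------------
Per-sampling-day networks with only the 7 ports as observations cannot
reach FDR-adjusted significance at |rho| > 0.6, so the default grouping
(``day_window``) pools, for each focal day, all samples within +/- ``window``
days that belong to the same nutrient stage.  ``stage`` builds one pooled
network per stage and ``all`` a single network.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from .abundance import (
    ConfigurationError,
    OtuTable,
    alpha_diversity,
    filter_low_abundance,
    rarefy,
    read_otu_table,
    read_taxonomy,
)
from .compare import GroupComparison, compare_stages
from .network import build_nutrient_network, network_from_table, write_edge_list, write_graphml, write_node_table
from .robustness import robustness_curve, robustness_random_removal
from .simulate import (
    NutrientSeries,
    SimulationScenario,
    generate_counts,
    generate_nutrients,
    synthetic_taxonomy,
)
from .topology import betweenness, topology_table

DEFAULT_CONFIG = {
    "filter_threshold": 1e-4,
    "rarefy_depth": None,
    "rho_threshold": 0.6,
    "alpha": 0.01,
    "use_adjusted_p": True,
    "group_by": "day_window",
    "focal_days": {"high": [16, 20, 24, 39], "low": [42, 48, 53, 58]},
    "window": 2,
    "with_nutrients": False,
    "diversity_metric": "shannon",
    "robustness": {"fraction": 0.5, "n_reps": 300, "curve": False},
}

_PRESETS = {
    "two_stage": SimulationScenario.two_stage_default,
    "recovery": SimulationScenario.recovery_default,
    "nutrient_demo": SimulationScenario.nutrient_demo,
}


@dataclass
class PipelineResult:
    table: OtuTable
    networks: dict[str, nx.Graph]
    stage_of_network: dict[str, str]
    topology: pd.DataFrame
    robustness_at_fraction: dict[str, float]
    comparisons: list[GroupComparison]
    diversity: pd.Series
    manifest: dict
    out_dir: Path | None = None
    nutrient_networks: dict[str, nx.Graph] = field(default_factory=dict)

    def comparison_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.to_row() for c in self.comparisons])


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _merge_config(config: dict | None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _resolve_inputs(cfg: dict, seed: int):
    """Return (table, taxonomy, nutrients) from a scenario or file paths."""
    if "scenario" in cfg and cfg["scenario"] is not None:
        sc_cfg = dict(cfg["scenario"])
        preset = sc_cfg.pop("preset", "two_stage")
        if preset not in _PRESETS:
            raise ConfigurationError(f"unknown scenario preset {preset!r}")
        scenario = _PRESETS[preset](seed=seed)
        for key, val in sc_cfg.items():
            if not hasattr(scenario, key):
                raise ConfigurationError(f"unknown scenario field {key!r}")
            setattr(scenario, key, val)
        table, _ = generate_counts(scenario)
        taxonomy = synthetic_taxonomy(table.otu_ids, seed=seed)
        nutrients = generate_nutrients(scenario)
        return table, taxonomy, nutrients
    inputs = cfg.get("inputs") or {}
    for key in ("otu_table", "metadata"):
        if key not in inputs:
            raise ConfigurationError(f"config must provide scenario or inputs.{key}")
        if not Path(inputs[key]).exists():
            raise FileNotFoundError(f"input file not found: {inputs[key]}")
    table = read_otu_table(inputs["otu_table"], inputs["metadata"])
    taxonomy = None
    if inputs.get("taxonomy"):
        taxonomy = read_taxonomy(inputs["taxonomy"])
    nutrients = None
    if cfg.get("with_nutrients"):
        path = inputs.get("nutrients")
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"nutrient file requested but not found: {path}")
        nutrients = NutrientSeries(pd.read_csv(path, sep="\t", dtype={"port": str}))
    return table, taxonomy, nutrients


def _group_samples(table: OtuTable, cfg: dict) -> tuple[dict[str, list[str]], dict[str, str]]:
    """Map network label -> sample ids, and network label -> stage."""
    meta = table.metadata
    groups: dict[str, list[str]] = {}
    stage_of: dict[str, str] = {}
    mode = cfg["group_by"]
    if mode == "all":
        groups["all"] = list(meta.index)
        stage_of["all"] = meta["stage"].mode().iloc[0]
    elif mode == "stage":
        for stage in ("high", "low"):
            ids = list(meta.index[meta["stage"] == stage])
            if ids:
                groups[stage] = ids
                stage_of[stage] = stage
    elif mode == "day_window":
        w = int(cfg["window"])
        for stage, days in cfg["focal_days"].items():
            for d in days:
                mask = (meta["stage"] == stage) & meta["day"].between(d - w, d + w)
                ids = list(meta.index[mask])
                if ids:
                    label = f"day{d:02d}"
                    groups[label] = ids
                    stage_of[label] = stage
    else:
        raise ConfigurationError(f"unknown group_by mode {cfg['group_by']!r}")
    return groups, stage_of


def run_pipeline(config: dict | None = None, out_dir=None, seed: int = 0) -> PipelineResult:
    """Execute the full analysis and (optionally) write the report bundle."""
    cfg = _merge_config(config)
    try:
        table, taxonomy, nutrients = _resolve_inputs(cfg, seed)
    except (ConfigurationError, FileNotFoundError):
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"input stage failed: {exc}") from exc

    # --- preprocess ---------------------------------------------------------
    table = filter_low_abundance(table, threshold=float(cfg["filter_threshold"]))
    if cfg["rarefy_depth"]:
        table = rarefy(table, depth=int(cfg["rarefy_depth"]), seed=seed)

    diversity = alpha_diversity(table, metric=cfg["diversity_metric"]).values

    # --- per-group networks -------------------------------------------------
    groups, stage_of = _group_samples(table, cfg)
    networks: dict[str, nx.Graph] = {}
    for label, sample_ids in groups.items():
        sub = table.subset_samples(sample_ids)
        networks[label] = network_from_table(
            sub,
            taxonomy,
            rho_threshold=float(cfg["rho_threshold"]),
            alpha=float(cfg["alpha"]),
            use_adjusted_p=bool(cfg["use_adjusted_p"]),
        )

    topo = topology_table(networks)

    # --- robustness ---------------------------------------------------------
    rb_cfg = cfg["robustness"]
    rob_at: dict[str, float] = {}
    curves: dict[str, pd.DataFrame] = {}
    for i, (label, g) in enumerate(networks.items()):
        if g.number_of_nodes() < 2:
            continue
        point = robustness_random_removal(
            g, float(rb_cfg["fraction"]), n_reps=int(rb_cfg["n_reps"]), seed=seed * 1009 + i
        )
        rob_at[label] = point.mean
        if rb_cfg.get("curve"):
            curve = robustness_curve(g, n_reps=int(rb_cfg["n_reps"]), seed=seed * 1009 + i)
            curves[label] = curve.to_frame(label)

    # --- nutrient-OTU bipartite networks (one per stage) --------------------
    nutrient_networks: dict[str, nx.Graph] = {}
    if cfg["with_nutrients"]:
        if nutrients is None:
            raise ConfigurationError("with_nutrients requested but no nutrient series available")
        for stage in ("high", "low"):
            ids = list(table.metadata.index[table.metadata["stage"] == stage])
            if len(ids) >= 4:
                nutrient_networks[stage] = build_nutrient_network(
                    table.subset_samples(ids),
                    nutrients,
                    taxonomy,
                    rho_threshold=float(cfg["rho_threshold"]),
                    alpha=float(cfg["alpha"]),
                )

    # --- stage comparisons --------------------------------------------------
    comparisons: list[GroupComparison] = []
    stages = table.metadata["stage"]
    div_high = diversity[stages == "high"]
    div_low = diversity[stages == "low"]
    if len(div_high) >= 3 and len(div_low) >= 3:
        comparisons.append(
            compare_stages(div_high, div_low, metric=f"alpha_diversity_{cfg['diversity_metric']}")
        )
    neg = {
        label: row for label, row in zip(topo["label"], topo["negative_pct"])
    }
    by_stage = lambda values: (
        [v for l, v in values.items() if stage_of[l] == "high"],
        [v for l, v in values.items() if stage_of[l] == "low"],
    )
    neg_values = {l: float(p.rstrip("%")) / 100 for l, p in neg.items()}
    high_vals, low_vals = by_stage(neg_values)
    if len(high_vals) >= 3 and len(low_vals) >= 3:
        comparisons.append(compare_stages(high_vals, low_vals, metric="negative_edge_fraction"))
    high_rob, low_rob = by_stage(rob_at)
    if len(high_rob) >= 3 and len(low_rob) >= 3:
        comparisons.append(
            compare_stages(high_rob, low_rob, metric=f"robustness_at_{rb_cfg['fraction']}")
        )

    result = PipelineResult(
        table=table,
        networks=networks,
        stage_of_network=stage_of,
        topology=topo,
        robustness_at_fraction=rob_at,
        comparisons=comparisons,
        diversity=diversity,
        manifest={},
        nutrient_networks=nutrient_networks,
    )

    # --- report bundle ------------------------------------------------------
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        topo.to_csv(out / "topology.tsv", sep="\t", index=False)
        rob_rows = [
            {"network": l, "fraction": rb_cfg["fraction"], "mean": m, "n_reps": rb_cfg["n_reps"]}
            for l, m in rob_at.items()
        ]
        pd.DataFrame(rob_rows, columns=["network", "fraction", "mean", "n_reps"]).to_csv(
            out / "robustness.tsv", sep="\t", index=False
        )
        if curves:
            pd.concat(curves.values(), ignore_index=True).to_csv(
                out / "robustness_curves.tsv", sep="\t", index=False
            )
        result.comparison_frame().to_csv(out / "comparisons.tsv", sep="\t", index=False)
        diversity.rename("value").rename_axis("sample").reset_index().to_csv(
            out / "diversity.tsv", sep="\t", index=False
        )
        for label, g in networks.items():
            write_edge_list(g, out / f"network_{label}_edges.tsv")
            write_node_table(g, out / f"network_{label}_nodes.tsv", betweenness(g))
            write_graphml(g, out / f"network_{label}.graphml")
        for stage, g in nutrient_networks.items():
            write_edge_list(g, out / f"nutrient_network_{stage}_edges.tsv")
            write_graphml(g, out / f"nutrient_network_{stage}.graphml")
        manifest = _manifest(cfg, seed, out)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        result.manifest = manifest
        result.out_dir = out
    else:
        result.manifest = {"config_sha256": _config_hash(cfg), "seed": seed}
    return result


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def _manifest(cfg: dict, seed: int, out: Path) -> dict:
    digests = {}
    for path in sorted(out.glob("*")):
        if path.name == "manifest.json" or path.is_dir():
            continue
        digests[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    return {
        "config": cfg,
        "config_sha256": _config_hash(cfg),
        "seed": seed,
        "version": __version__,
        "outputs_sha256": digests,
    }
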