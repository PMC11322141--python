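"""Synthetic reservoir-community generator with planted association structure.

Emulates the data layout of a long-core nutrient-injection experiment:
seven sampling ports monitored daily for ~60 days, a high-nutrient stage
followed by a reduced-nutrient stage, and OTU abundances carrying known
(planted) inter-OTU correlation blocks so that downstream network inference
can be scored against ground truth.

The abundance model is a latent-Gaussian (copula) construction: a latent
multivariate normal vector with block correlation structure is pushed
through a log-normal marginal transform to heavy-tailed abundances, which
are then multinomially sampled at a fixed sequencing depth.  Because
Spearman correlation is invariant to the monotone marginal transform, the
latent block correlations control the rank correlations the pipeline
measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .abundance import ConfigurationError, OtuTable


@dataclass(frozen=True)
class Block:
    """A planted correlation block: ``size`` OTUs at latent correlation ``rho``.

    ``sign`` = +1 gives an all-positive block; -1 gives an alternating-sign
    block in which pairs of opposite latent loading are negatively
    correlated (an all-negative block of size > 2 would not be a valid
    correlation matrix).
    """

    size: int
    rho: float
    sign: int = 1

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ConfigurationError("block size must be >= 2")
        if not -1 < self.rho < 1:
            raise ConfigurationError("within-block correlation must be in (-1, 1)")
        if self.sign not in (1, -1):
            raise ConfigurationError("block sign must be +1 or -1")


@dataclass
class SimulationScenario:
    """All knobs of one synthetic experiment.

    Defaults describe the study design being emulated: 7 sampling ports,
    days 1..60, nutrient step-down at day 40 (samples on the boundary day
    belong to the low stage), sequencing depth 41051 (the rarefaction depth
    of the emulated workflow).
    """

    n_otus: int = 120
    n_ports: int = 7
    days: tuple[int, ...] = tuple(range(1, 61))
    stage_boundary_day: int = 40
    block_spec: tuple[Block, ...] = ()
    #: optional per-stage override of the planted blocks (two-regime designs)
    block_spec_by_stage: dict[str, tuple[Block, ...]] | None = None
    sequencing_depth: int = 41051
    #: log-normal latent noise scale (per-sample variability of log abundance)
    dispersion: float = 1.0
    #: spread of baseline log abundances across OTUs (unevenness)
    base_log_spread: float = 1.25
    #: relative compression of the log-abundance spread in the low stage;
    #: > 0 makes low-stage communities more even, hence more diverse
    diversity_shift: float = 0.0
    #: per stage, the fraction of planted blocks made alternating-sign
    negative_fraction_by_stage: dict[str, float] | None = None
    #: nutrient name -> (number of driven OTUs, coupling strength); driven
    #: OTUs get the standardized concentration added to their latent log
    #: abundance, planting a monotone nutrient-taxon dependence
    nutrient_driven: dict[str, tuple[int, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_otus < 1 or self.n_ports < 1:
            raise ConfigurationError("n_otus and n_ports must be positive")
        if self.sequencing_depth < 1:
            raise ConfigurationError("sequencing_depth must be positive")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be positive")
        for stage in ("high", "low"):
            for blk in self.blocks_for_stage(stage):
                pass  # Block validates itself
            total = sum(b.size for b in self.blocks_for_stage(stage))
            n_driven = sum(k for k, _ in (self.nutrient_driven or {}).values())
            if total + n_driven > self.n_otus:
                raise ConfigurationError(
                    f"block sizes for stage {stage!r} plus nutrient-driven OTUs "
                    f"sum to {total + n_driven} > n_otus={self.n_otus}"
                )

    # -- stage helpers ---------------------------------------------------------
    def stage_of_day(self, day: int) -> str:
        return "low" if day >= self.stage_boundary_day else "high"

    def blocks_for_stage(self, stage: str) -> tuple[Block, ...]:
        base = self.block_spec
        if self.block_spec_by_stage and stage in self.block_spec_by_stage:
            base = tuple(self.block_spec_by_stage[stage])
        if self.negative_fraction_by_stage and stage in self.negative_fraction_by_stage:
            frac = self.negative_fraction_by_stage[stage]
            if not 0 <= frac <= 1:
                raise ConfigurationError("negative fraction must be in [0, 1]")
            n_neg = int(round(frac * len(base)))
            base = tuple(
                Block(b.size, b.rho, -1 if i < n_neg else 1) for i, b in enumerate(base)
            )
        return tuple(base)

    # -- presets ---------------------------------------------------------------
    @classmethod
    def recovery_default(cls, seed: int = 0) -> "SimulationScenario":
        """Single-structure scenario for planted-edge recovery: 200 samples
        (5 ports x 40 days), blocks at latent correlation 0.9."""
        return cls(
            n_otus=120,
            n_ports=5,
            days=tuple(range(1, 41)),
            block_spec=tuple(Block(6, 0.9) for _ in range(8)),
            diversity_shift=0.0,
            seed=seed,
        )

    @classmethod
    def nutrient_demo(cls, seed: int = 0) -> "SimulationScenario":
        """Scenario with nutrient-driven OTUs for bipartite-network demos:
        restricted to the ramp-up days where concentrations vary strongly
        across samples and ports."""
        return cls(
            n_otus=40,
            days=tuple(range(1, 15)),
            block_spec=(Block(4, 0.9),),
            nutrient_driven={"TN": (4, 2.0), "TS": (3, 2.0)},
            seed=seed,
        )

    @classmethod
    def two_stage_default(cls, seed: int = 0) -> "SimulationScenario":
        """Two-regime scenario reproducing the study's qualitative contrast:
        in the low-nutrient stage the community is more even (higher
        diversity), planted blocks are larger (denser, more robust networks)
        and fewer blocks are negative."""
        return cls(
            n_otus=120,
            block_spec=tuple(Block(6, 0.9) for _ in range(8)),
            block_spec_by_stage={
                "high": tuple(Block(6, 0.9) for _ in range(8)),
                "low": tuple(Block(8, 0.9) for _ in range(8)),
            },
            negative_fraction_by_stage={"high": 0.5, "low": 0.125},
            diversity_shift=0.35,
            seed=seed,
        )


@dataclass
class GroundTruth:
    """Planted pairwise associations and the stage of every sample."""

    planted_edges_by_stage: dict[str, set[tuple[str, str, int]]]
    stage_of_sample: dict[str, str]
    #: planted (nutrient, otu) monotone dependencies, if any
    nutrient_links: set[tuple[str, str]] = field(default_factory=set)

    @property
    def planted_edges(self) -> set[tuple[str, str, int]]:
        """Union over stages of (otu_a, otu_b, sign) with otu_a < otu_b."""
        out: set[tuple[str, str, int]] = set()
        for edges in self.planted_edges_by_stage.values():
            out |= edges
        return out

    def edge_set(self, stage: str | None = None) -> set[frozenset]:
        edges = self.planted_edges if stage is None else self.planted_edges_by_stage[stage]
        return {frozenset((a, b)) for a, b, _ in edges}


@dataclass
class NutrientSeries:
    """Long-format nutrient concentrations: one record per (day, port)."""

    records: pd.DataFrame  # columns: day, port, TS, TN, TP

    def __post_init__(self) -> None:
        df = self.records
        if df.duplicated(subset=["day", "port"]).any():
            raise ConfigurationError("duplicate (day, port) nutrient records")
        if (df[["TS", "TN", "TP"]].to_numpy() < 0).any():
            raise ConfigurationError("nutrient concentrations must be >= 0")

    def lookup(self, day: int, port: str) -> pd.Series:
        hit = self.records[(self.records["day"] == day) & (self.records["port"] == port)]
        if hit.empty:
            raise KeyError(f"no nutrient record for (day={day}, port={port})")
        return hit.iloc[0][["TS", "TN", "TP"]]


# ---------------------------------------------------------------------------
# Latent correlation structure
# ---------------------------------------------------------------------------

def _loadings_for_stage(scenario: SimulationScenario, stage: str) -> tuple[np.ndarray, np.ndarray, list]:
    """Factor loadings of the planted blocks for one stage.

    OTU ``i`` in block ``b`` has latent value
    ``z_i = s_i * (sqrt(rho_b) * f_b + sqrt(1 - rho_b) * eps_i)`` with block
    factor ``f_b``; within a block, corr(z_i, z_j) = s_i * s_j * rho_b.
    Returns (loading matrix lam of shape (n_otus, n_blocks), per-OTU sign
    vector folded into lam, and the planted pair list).
    """
    n = scenario.n_otus
    blocks = scenario.blocks_for_stage(stage)
    lam = np.zeros((n, len(blocks)))
    uniq = np.ones(n)  # sqrt of idiosyncratic variance
    planted = []
    pos = 0
    for b_idx, blk in enumerate(blocks):
        members = range(pos, pos + blk.size)
        signs = [1] * blk.size if blk.sign == 1 else [1 if k % 2 == 0 else -1 for k in range(blk.size)]
        for k, i in enumerate(members):
            lam[i, b_idx] = signs[k] * np.sqrt(blk.rho)
            uniq[i] = np.sqrt(1.0 - blk.rho)
        for a_k, a in enumerate(members):
            for b_k, b in enumerate(members):
                if a < b:
                    pair_sign = int(np.sign(signs[a_k] * signs[b_k]))
                    planted.append((a, b, pair_sign))
        pos += blk.size
    # fold the member sign into uniq via lam only; idiosyncratic part is symmetric
    return lam, uniq, planted


def generate_counts(scenario: SimulationScenario) -> tuple[OtuTable, GroundTruth]:
    """Draw one OTU count table (one sample per day x port) plus ground truth.

    Deterministic for a given ``(scenario, scenario.seed)``.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_otus
    otu_ids = [f"OTU{i + 1:04d}" for i in range(n)]

    # baseline log abundances, shared by all samples (drawn once per scenario)
    base_mu = rng.normal(0.0, scenario.base_log_spread, size=n)

    stage_struct = {s: _loadings_for_stage(scenario, s) for s in ("high", "low")}

    # nutrient-driven OTUs: standardized concentrations shift latent log
    # abundance of dedicated OTUs taken from the tail of the OTU list
    nutrient_links: set[tuple[str, str]] = set()
    conc_shift: dict[tuple[int, str], np.ndarray] = {}
    if scenario.nutrient_driven:
        series = generate_nutrients(scenario).records
        zscored = {}
        for nutrient in scenario.nutrient_driven:
            vals = series[nutrient].to_numpy(dtype=float)
            sd = vals.std()
            zscored[nutrient] = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
        driven_idx = {}
        cursor = n
        for nutrient, (k, _) in scenario.nutrient_driven.items():
            driven_idx[nutrient] = list(range(cursor - k, cursor))
            cursor -= k
            nutrient_links |= {(nutrient, otu_ids[i]) for i in driven_idx[nutrient]}
        for row_i, rec in series.iterrows():
            shift = np.zeros(n)
            for nutrient, (k, strength) in scenario.nutrient_driven.items():
                shift[driven_idx[nutrient]] += strength * zscored[nutrient][row_i]
            conc_shift[(int(rec["day"]), rec["port"])] = shift

    samples, columns, stage_of_sample = [], [], {}
    for day in scenario.days:
        for p in range(1, scenario.n_ports + 1):
            port = f"SP{p}"
            sid = f"d{day:02d}.{port}"
            stage = scenario.stage_of_day(day)
            stage_of_sample[sid] = stage
            lam, uniq, _ = stage_struct[stage]
            factors = rng.normal(size=lam.shape[1]) if lam.shape[1] else np.zeros(0)
            eps = rng.normal(size=n)
            z = lam @ factors + uniq * eps
            mu = base_mu * (1.0 - scenario.diversity_shift) if stage == "low" else base_mu
            if conc_shift:
                mu = mu + conc_shift[(day, port)]
            abundance = np.exp(mu + scenario.dispersion * z)
            probs = abundance / abundance.sum()
            counts = rng.multinomial(scenario.sequencing_depth, probs)
            samples.append(counts)
            columns.append(sid)

    counts_df = pd.DataFrame(
        np.column_stack(samples).astype(np.int64), index=otu_ids, columns=columns
    )
    meta = pd.DataFrame(
        {
            "day": [int(c[1:3]) for c in columns],
            "port": [c.split(".")[1] for c in columns],
            "stage": [stage_of_sample[c] for c in columns],
        },
        index=pd.Index(columns, name="sample"),
    )
    table = OtuTable(counts_df, meta)

    planted_by_stage = {}
    for stage, (_, _, planted) in stage_struct.items():
        planted_by_stage[stage] = {
            (otu_ids[a], otu_ids[b], sign) for a, b, sign in planted
        }
    truth = GroundTruth(
        planted_edges_by_stage=planted_by_stage,
        stage_of_sample=stage_of_sample,
        nutrient_links=nutrient_links,
    )
    return table, truth


# ---------------------------------------------------------------------------
# Nutrient curves
# ---------------------------------------------------------------------------

#: default plateaus (mg/L): high-stage level and low-stage level per nutrient.
#: TS plateaus at 150 mg/L in the high stage; the reduced recipe halves the
#: carbon source, so the low plateau defaults to half.  TN and TP stabilize
#: earlier (ramp ~8 days) at recipe-proportional levels.
NUTRIENT_DEFAULTS = {
    "TS": {"high": 150.0, "low": 75.0, "ramp_days": 17},
    "TN": {"high": 120.0, "low": 60.0, "ramp_days": 8},
    "TP": {"high": 30.0, "low": 15.0, "ramp_days": 8},
}


def generate_nutrients(
    scenario: SimulationScenario,
    levels: dict | None = None,
    port_lags: list[int] | None = None,
) -> NutrientSeries:
    """Piecewise ramp-then-plateau nutrient curves with per-port lag.

    Each port sees the injected front with a fixed integer day lag
    (default 0, 1, ..., n_ports-1): the effective day at port ``p`` is
    ``day - lag_p``.  Before the stage boundary the curve ramps linearly to
    the high plateau over ``ramp_days``; once the boundary has passed the
    port (boundary + lag), concentration steps down to the low plateau.
    """
    levels = levels or NUTRIENT_DEFAULTS
    if port_lags is None:
        port_lags = list(range(scenario.n_ports))
    if len(port_lags) != scenario.n_ports:
        raise ConfigurationError("port_lags length must equal n_ports")

    rows = []
    for day in scenario.days:
        for p in range(1, scenario.n_ports + 1):
            lag = port_lags[p - 1]
            eff = day - lag
            row = {"day": day, "port": f"SP{p}"}
            for nutrient, spec in levels.items():
                if eff <= 0:
                    conc = 0.0
                elif day >= scenario.stage_boundary_day + lag:
                    conc = spec["low"]
                elif eff >= spec["ramp_days"]:
                    conc = spec["high"]
                else:
                    conc = spec["high"] * eff / spec["ramp_days"]
                row[nutrient] = conc
            rows.append(row)
    return NutrientSeries(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# On-disk scenario outputs
# ---------------------------------------------------------------------------

_PHYLA = ["Proteobacteria", "Firmicutes", "Bacteroidota", "Cloacimonadota",
          "Spirochaetota", "Desulfobacterota", "Thermotogota"]


def synthetic_taxonomy(otu_ids: list[str], seed: int = 0) -> pd.Series:
    """Synthetic lineage strings (k__; p__; ...; g__) for generated OTUs."""
    rng = np.random.default_rng(seed)
    lineages = {}
    for otu in otu_ids:
        phylum = _PHYLA[rng.integers(len(_PHYLA))]
        genus = f"Genus{otu[-4:]}"
        lineages[otu] = (
            f"k__Bacteria; p__{phylum}; c__c{otu[-2:]}; o__o{otu[-2:]}; "
            f"f__f{otu[-2:]}; g__{genus}"
        )
    return pd.Series(lineages, name="lineage")


def write_scenario(scenario: SimulationScenario, out_dir) -> dict[str, Path]:
    """Generate and write all scenario artifacts as TSVs; returns the paths."""
    from .abundance import write_otu_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, truth = generate_counts(scenario)
    nutrients = generate_nutrients(scenario)
    paths = {
        "otu_table": out / "otu_table.tsv",
        "metadata": out / "metadata.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "nutrients": out / "nutrients.tsv",
        "ground_truth": out / "ground_truth_edges.tsv",
    }
    write_otu_table(table, paths["otu_table"], paths["metadata"])
    tax = synthetic_taxonomy(table.otu_ids, seed=scenario.seed)
    tax.rename_axis("otu").reset_index().to_csv(paths["taxonomy"], sep="\t", index=False)
    nutrients.records.to_csv(paths["nutrients"], sep="\t", index=False)
    rows = [
        {"otu_a": a, "otu_b": b, "sign": s, "stage": stage}
        for stage, edges in sorted(truth.planted_edges_by_stage.items())
        for a, b, s in sorted(edges)
    ]
    pd.DataFrame(rows, columns=["otu_a", "otu_b", "sign", "stage"]).to_csv(
        paths["ground_truth"], sep="\t", index=False
    )
    return paths
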