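"""OTU-table container, TSV I/O, preprocessing and alpha diversity.

The abundance table follows the QIIME-style feature-table layout: rows are
OTUs, columns are samples, the first column is ``#OTU ID``.  Sample metadata
(day, sampling port, nutrient stage) travels with the counts in
:class:`OtuTable`.

Preprocessing mirrors the standard amplicon workflow: OTUs whose *mean*
relative abundance across samples falls below a threshold (default 0.01%)
are removed, and samples may be rarefied (subsampled without replacement) to
a common depth to equalize sequencing effort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio.diversity import alpha as _skbio_alpha

logger = logging.getLogger(__name__)

STAGES = ("high", "low")

#: metrics accepted by :func:`alpha_diversity`
ALPHA_METRICS = ("shannon", "observed_otus", "simpson", "pielou_evenness")


class FormatError(ValueError):
    """Raised when an input table or metadata file violates the format contract."""


class ConfigurationError(ValueError):
    """Raised when a parameter is outside its documented domain."""


@dataclass
class OtuTable:
    """Sample-by-OTU count matrix with per-sample metadata.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer matrix, index = OTU ids, columns = sample ids.
    metadata : pandas.DataFrame
        Indexed by sample id with columns ``day`` (int), ``port`` (str) and
        ``stage`` (``"high"`` or ``"low"``).
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            raise FormatError("duplicate OTU identifiers in count table")
        if counts.columns.has_duplicates:
            raise FormatError("duplicate sample identifiers in count table")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise FormatError("counts must be integers")
            counts = counts.astype(np.int64)
            object.__setattr__(self, "counts", counts)
        if (counts.to_numpy() < 0).any():
            raise FormatError("counts must be non-negative")
        missing = set(counts.columns) ^ set(self.metadata.index)
        if missing:
            raise FormatError(
                "samples present in only one of table/metadata: "
                + ", ".join(sorted(map(str, missing)))
            )
        bad_stage = set(self.metadata["stage"]) - set(STAGES)
        if bad_stage:
            raise FormatError(f"unknown stage labels: {sorted(bad_stage)}")
        # align metadata row order with the count columns
        object.__setattr__(self, "metadata", self.metadata.loc[list(counts.columns)])

    # -- convenience accessors -------------------------------------------------
    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, sample_ids) -> "OtuTable":
        sample_ids = list(sample_ids)
        return OtuTable(self.counts[sample_ids].copy(), self.metadata.loc[sample_ids].copy())

    def __eq__(self, other) -> bool:  # value equality, used by round-trip tests
        if not isinstance(other, OtuTable):
            return NotImplemented
        return self.counts.equals(other.counts) and self.metadata.equals(other.metadata)


@dataclass
class DiversityResult:
    """Per-sample values of one alpha-diversity metric."""

    metric: str
    values: pd.Series  # indexed by sample id
    base: float | None = field(default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample": self.values.index, "metric": self.metric, "value": self.values.to_numpy()}
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_otu_table(path, metadata_path) -> OtuTable:
    """Read a QIIME-style OTU table TSV plus a sample metadata TSV.

    The table's first column must be ``#OTU ID``; metadata must contain
    ``sample``, ``day``, ``port`` and ``stage`` columns.  Sample sets must
    agree exactly between the two files.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if counts.index.name != "#OTU ID":
        raise FormatError(f"{path}: first column must be '#OTU ID', got {counts.index.name!r}")
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    raw = counts.to_numpy()
    if not np.issubdtype(raw.dtype, np.number):
        raise FormatError(f"{path}: non-numeric counts")
    if np.issubdtype(raw.dtype, np.floating) and not np.allclose(raw, np.round(raw)):
        raise FormatError(f"{path}: non-integer counts")
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample": str, "port": str})
    required = {"sample", "day", "port", "stage"}
    if not required.issubset(meta.columns):
        raise FormatError(f"{metadata_path}: missing columns {sorted(required - set(meta.columns))}")
    if meta["sample"].duplicated().any():
        raise FormatError(f"{metadata_path}: duplicate sample ids")
    meta = meta.set_index("sample")
    meta["day"] = meta["day"].astype(int)
    return OtuTable(counts.astype(np.int64), meta)


def write_otu_table(table: OtuTable, path, metadata_path) -> None:
    """Write the table and metadata in the formats :func:`read_otu_table` accepts."""
    out = table.counts.copy()
    out.index.name = "#OTU ID"
    out.to_csv(path, sep="\t")
    meta = table.metadata.copy()
    meta.index.name = "sample"
    meta.to_csv(metadata_path, sep="\t")


def read_taxonomy(path) -> pd.Series:
    """Read an OTU -> lineage-string map (TSV with columns ``otu``, ``lineage``)."""
    tax = pd.read_csv(path, sep="\t", dtype=str)
    if not {"otu", "lineage"}.issubset(tax.columns):
        raise FormatError(f"{path}: expected columns 'otu' and 'lineage'")
    return tax.set_index("otu")["lineage"]


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Per-sample proportions (columns sum to 1).

    Raises
    ------
    FormatError
        If any sample has a zero total count (proportions undefined).
    """
    totals = table.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise FormatError(f"all-zero samples: {', '.join(map(str, zero.index))}")
    return table.counts / totals


def filter_low_abundance(
    table: OtuTable, threshold: float = 1e-4, criterion: str = "mean"
) -> OtuTable:
    """Drop OTUs below a relative-abundance threshold; samples are untouched.

    ``criterion`` selects how per-sample proportions are summarized per OTU
    before comparison with ``threshold``:

    - ``"mean"`` (default): mean relative abundance across samples,
    - ``"max"``: maximum across samples,
    - ``"pooled"``: proportion of the pooled (summed) counts.

    An OTU is *retained* when its summary is >= ``threshold`` (the default
    1e-4 corresponds to removing OTUs under 0.01%).
    """
    if not 0 <= threshold <= 1:
        raise ConfigurationError(f"threshold must be in [0, 1], got {threshold}")
    rel = relative_abundance(table)
    if criterion == "mean":
        summary = rel.mean(axis=1)
    elif criterion == "max":
        summary = rel.max(axis=1)
    elif criterion == "pooled":
        pooled = table.counts.sum(axis=1)
        summary = pooled / pooled.sum()
    else:
        raise ConfigurationError(f"unknown filter criterion {criterion!r}")
    keep = summary[summary >= threshold].index
    return OtuTable(table.counts.loc[keep].copy(), table.metadata.copy())


def rarefy(table: OtuTable, depth: int = 41051, seed: int | None = 0) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped with a logged warning.
    Deterministic for a given ``seed``.
    """
    if depth <= 0:
        raise ConfigurationError(f"rarefaction depth must be positive, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=0)
    shallow = list(totals[totals < depth].index)
    if shallow:
        logger.warning(
            "dropping %d sample(s) below rarefaction depth %d: %s",
            len(shallow), depth, ", ".join(map(str, shallow)),
        )
    kept = [s for s in table.sample_ids if s not in set(shallow)]
    out = {}
    for s in kept:
        col = table.counts[s].to_numpy()
        if col.sum() == depth:
            out[s] = col
        else:
            out[s] = rng.multivariate_hypergeometric(col, depth)
    counts = pd.DataFrame(out, index=table.counts.index, dtype=np.int64)
    return OtuTable(counts, table.metadata.loc[kept].copy())


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def alpha_diversity(table: OtuTable, metric: str = "shannon", base: float = 2) -> DiversityResult:
    """Per-sample alpha diversity.

    Shannon entropy is reported in bits (log base 2) by default; ``base`` is
    configurable.  ``observed_otus`` counts OTUs with nonzero count,
    ``simpson`` is 1 - sum(p^2), ``pielou_evenness`` is Shannon / log(S).
    """
    if metric not in ALPHA_METRICS:
        raise ConfigurationError(f"unknown metric {metric!r}; choose from {ALPHA_METRICS}")
    values = {}
    for s in table.sample_ids:
        col = table.counts[s].to_numpy()
        if metric == "shannon":
            values[s] = float(_skbio_alpha.shannon(col, base=base))
        elif metric == "observed_otus":
            values[s] = int(_skbio_alpha.sobs(col))
        elif metric == "simpson":
            values[s] = float(_skbio_alpha.simpson(col))
        else:
            values[s] = float(_skbio_alpha.pielou_e(col))
    series = pd.Series(values, name=metric).loc[table.sample_ids]
    return DiversityResult(metric=metric, values=series, base=base if metric == "shannon" else None)
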