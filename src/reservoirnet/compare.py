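"""High- vs low-nutrient stage comparisons with star significance labels.

Defaults to a two-sided Mann-Whitney U test (exact p for small groups
without ties, normal approximation with tie correction otherwise); Welch's
t-test is available by flag.  Labels follow the usual convention:
* p < 0.05, ** p < 0.01, *** p < 0.001, ns otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .abundance import ConfigurationError


def significance_label(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class GroupComparison:
    metric: str
    high: list[float]
    low: list[float]
    test: str
    statistic: float
    p_value: float

    @property
    def label(self) -> str:
        return significance_label(self.p_value)

    def to_row(self) -> dict:
        return {
            "metric": self.metric,
            "n_high": len(self.high),
            "n_low": len(self.low),
            "statistic": self.statistic,
            "p": self.p_value,
            "label": self.label,
        }


def compare_stages(
    high, low, metric: str = "", test: str = "mann_whitney"
) -> GroupComparison:
    """Two-sided comparison of a metric between the two nutrient stages."""
    high = [float(x) for x in high]
    low = [float(x) for x in low]
    if len(high) < 3 or len(low) < 3:
        raise ConfigurationError(
            f"each group needs >= 3 values, got {len(high)} and {len(low)}"
        )
    if test == "mann_whitney":
        res = stats.mannwhitneyu(high, low, alternative="two-sided", method="auto")
    elif test == "welch_t":
        res = stats.ttest_ind(high, low, equal_var=False)
    else:
        raise ConfigurationError(f"unknown test {test!r}")
    return GroupComparison(
        metric=metric,
        high=high,
        low=low,
        test=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )
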