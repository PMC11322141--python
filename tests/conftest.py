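import numpy as np
import pandas as pd
import pytest

from reservoirnet import OtuTable


@pytest.fixture
def toy_table() -> OtuTable:
    """3 OTUs x 4 samples, two per stage, hand-checkable counts."""
    counts = pd.DataFrame(
        {
            "s1": [50, 50, 0],
            "s2": [1, 9999, 0],
            "s3": [10, 10, 10],
            "s4": [4, 0, 0],
        },
        index=["A", "B", "C"],
    )
    meta = pd.DataFrame(
        {
            "day": [10, 20, 45, 50],
            "port": ["SP1", "SP1", "SP1", "SP1"],
            "stage": ["high", "high", "low", "low"],
        },
        index=pd.Index(["s1", "s2", "s3", "s4"], name="sample"),
    )
    return OtuTable(counts, meta)


def brute_force_spearman(x, y):
    """Independent oracle: mid-ranks by sorting with tie averaging, then
    Pearson by its definition."""
    def midranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = (sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)) ** 0.5
    return num / den if den else 0.0


def brute_force_bh(p_values):
    """Independent BH oracle: sort, scale by m/rank, cumulative min, clip."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, p_values[idx] * m / rank)
        adj[idx] = running
    return adj
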