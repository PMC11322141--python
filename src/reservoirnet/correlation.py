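"""All-pairs Spearman correlation with FDR-adjusted significance.

Edges of a co-occurrence network are called from the mid-rank Spearman
correlation matrix of the (variables x samples) abundance matrix.  Raw
p-values come from the t approximation to the null distribution of rho
(t = rho * sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom); for very small
sample counts an exact permutation p-value is available.  Multiple testing
over the V(V-1)/2 unordered pairs is corrected by the Benjamini-Hochberg
step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .abundance import ConfigurationError


@dataclass
class CorrelationResult:
    """Pairwise rho, raw p and FDR-adjusted p over a variable set.

    ``rho`` is symmetric with unit diagonal; ``p_adj >= p_raw`` elementwise.
    Variables with zero variance are listed in ``zero_variance``; their rho
    is 0 and p is 1 against every partner, and network construction skips
    them.
    """

    variable_ids: list[str]
    rho: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray
    n_samples: int
    zero_variance: list[str] = field(default_factory=list)

    def pair_frame(self) -> pd.DataFrame:
        """Upper-triangle pairs as a tidy frame (a, b, rho, p_raw, p_adj)."""
        ids = self.variable_ids
        iu, ju = np.triu_indices(len(ids), k=1)
        return pd.DataFrame(
            {
                "a": [ids[i] for i in iu],
                "b": [ids[j] for j in ju],
                "rho": self.rho[iu, ju],
                "p_raw": self.p_raw[iu, ju],
                "p_adj": self.p_adj[iu, ju],
            }
        )


def _rho_p_values(ranks: np.ndarray, n: int, exact: bool, data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rho = np.corrcoef(ranks)
    rho = np.clip(rho, -1.0, 1.0)
    if exact:
        p = _exact_permutation_p(data)
    else:
        # t approximation; |rho| = 1 gives t = inf -> p = 0
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
    return rho, p


def _exact_permutation_p(data: np.ndarray) -> np.ndarray:
    """Exact two-sided permutation p for every pair (feasible for n <= 10)."""
    v, n = data.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1))
    p = np.ones((v, v))
    perms = np.array(list(permutations(range(n))))
    for i in range(v):
        for j in range(i + 1, v):
            if norms[i] == 0 or norms[j] == 0:
                continue
            obs = float(centered[i] @ centered[j] / (norms[i] * norms[j]))
            null = centered[i][perms] @ centered[j] / (norms[i] * norms[j])
            p[i, j] = p[j, i] = float(np.mean(np.abs(null) >= abs(obs) - 1e-12))
    return p


def spearman_all_pairs(
    matrix: pd.DataFrame | np.ndarray,
    variable_ids: list[str] | None = None,
    exact: bool = False,
) -> CorrelationResult:
    """Mid-rank Spearman rho and p for every unordered variable pair.

    Parameters
    ----------
    matrix : DataFrame or ndarray, shape (variables, samples)
        Abundance (or concentration) values; rows are variables.
    exact : bool
        Use the exact permutation null instead of the t approximation
        (only sensible for n <= 10 samples).
    """
    if isinstance(matrix, pd.DataFrame):
        variable_ids = list(matrix.index.astype(str))
        data = matrix.to_numpy(dtype=float)
    else:
        data = np.asarray(matrix, dtype=float)
        if variable_ids is None:
            variable_ids = [f"V{i}" for i in range(data.shape[0])]
    v, n = data.shape
    if n < 4:
        raise ConfigurationError(f"need >= 4 samples for meaningful p-values, got {n}")
    if v < 2:
        raise ConfigurationError("need >= 2 variables")
    if exact and n > 10:
        raise ConfigurationError("exact permutation p only supported for n <= 10")

    const = np.array([np.ptp(row) == 0 for row in data])
    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    # give constant rows a nonzero variance placeholder so corrcoef is finite
    safe = ranks.copy()
    safe[const] = np.arange(n)
    rho, p = _rho_p_values(safe, n, exact, data)
    np.fill_diagonal(rho, 1.0)
    np.fill_diagonal(p, 0.0)
    if const.any():
        rho[const, :] = 0.0
        rho[:, const] = 0.0
        p[const, :] = 1.0
        p[:, const] = 1.0
        np.fill_diagonal(rho, 1.0)
        np.fill_diagonal(p, 0.0)

    p_adj = fdr_adjust_matrix(p)
    return CorrelationResult(
        variable_ids=variable_ids,
        rho=rho,
        p_raw=p,
        p_adj=p_adj,
        n_samples=n,
        zero_variance=[variable_ids[i] for i in np.flatnonzero(const)],
    )


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment of a flat p-value vector.

    Adjusted values are clipped at 1 and are monotone in the raw order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any()):
        raise ConfigurationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def fdr_adjust_matrix(p: np.ndarray) -> np.ndarray:
    """BH over the upper-triangle pairs only (m = V(V-1)/2), symmetrized."""
    v = p.shape[0]
    iu, ju = np.triu_indices(v, k=1)
    adj_flat = fdr_adjust(p[iu, ju])
    p_adj = np.zeros_like(p)
    p_adj[iu, ju] = adj_flat
    p_adj[ju, iu] = adj_flat
    return p_adj
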