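"""Rank-correlation validation layer.

Spearman's rho between selfie-derived scores, plaque-area fractions and
clinical indices: rho is the Pearson correlation of average ranks (ties
receive their mean rank), with a two-sided p-value from the
t-distribution approximation ``t = rho * sqrt((n-2) / (1-rho^2))``.  For
small samples (n <= 8) an exact permutation p-value over all n!
orderings is computed as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["CorrelationResult", "CorrelationMatrix", "spearman", "correlation_matrix"]

EXACT_N_MAX = 8  # permutation p-value enumerates n! orderings up to here


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman correlation between two paired samples."""

    rho: float
    p_value: float                 # two-sided, t-approximation
    n: int
    p_exact: float | None = None   # exact permutation p, computed for n <= 8


def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def spearman(x, y, exact: bool | None = None) -> CorrelationResult:
    """Spearman rank correlation with two-sided significance.

    Parameters
    ----------
    x, y : equal-length numeric sequences, n >= 3.
    exact : force (True) or suppress (False) the exact permutation
        p-value; by default it is computed whenever n <= 8.

    Raises
    ------
    ValueError
        On length mismatch, n < 3, or zero rank variance in either list
        (rho is undefined for a constant sample).
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError(f"paired samples must match in length: {x.size} vs {y.size}")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs for a rank correlation, got {n}")
    rx = sps.rankdata(x)  # average ranks for ties
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero rank variance: rho is undefined for a constant sample")

    rho = _rank_rho(rx, ry)
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        p_t = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p_t = float(2.0 * sps.t.sf(abs(t), df=n - 2))

    p_exact = None
    if exact or (exact is None and n <= EXACT_N_MAX):
        if n > 10:
            raise ValueError(f"exact permutation p-value is infeasible for n={n}")
        hits = 0
        total = 0
        tol = 1e-12
        for perm in permutations(ry):
            total += 1
            if abs(_rank_rho(rx, np.asarray(perm))) >= abs(rho) - tol:
                hits += 1
        p_exact = hits / total
    return CorrelationResult(rho=rho, p_value=p_t, n=n, p_exact=p_exact)


@dataclass(frozen=True)
class CorrelationMatrix:
    """All-pairs Spearman results over named columns."""

    rho: pd.DataFrame
    p_value: pd.DataFrame
    n: int

    def to_json_dict(self) -> dict:
        return {
            "n": self.n,
            "rho": self.rho.round(10).to_dict(),
            "p_value": self.p_value.round(10).to_dict(),
        }


def correlation_matrix(table: pd.DataFrame, exact: bool | None = False) -> CorrelationMatrix:
    """Symmetric Spearman correlation matrix over the columns of a table.

    The diagonal is rho = 1 (p = 0) by definition.  Raises the underlying
    :func:`spearman` error if any column pair is degenerate.
    """
    table = pd.DataFrame(table)
    cols = list(table.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 columns for a correlation matrix")
    k = len(cols)
    rho = np.eye(k)
    pval = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            res = spearman(table[cols[i]], table[cols[j]], exact=exact)
            rho[i, j] = rho[j, i] = res.rho
            pval[i, j] = pval[j, i] = res.p_value
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=cols, columns=cols),
        p_value=pd.DataFrame(pval, index=cols, columns=cols),
        n=len(table),
    )
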