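"""Tie-corrected Spearman rank correlation with significance flags.

The coefficient is computed as the product-moment correlation of
mid-rank vectors: tied observations receive the mean of the rank
positions they span.  On tie-free data this reduces to the classical
``1 - 6*sum(d^2)/(n*(n^2-1))`` shortcut; with ties (frequent here,
because below-detection cells are recorded as 0.0) only the mid-rank
form reproduces published coefficients.  Zeros participate in ranking
as zeros — no exclusion.

Two-sided p-values come either from the t transform
``t = rho*sqrt((n-2)/(1-rho^2))`` with n-2 degrees of freedom, or from
the permutation null of tie-free ranks (exhaustive for n <= 7, seeded
Monte Carlo otherwise).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ConcentrationTable
from .errors import DomainError

__all__ = ["midranks", "spearman_rho", "spearman_pvalue",
           "CorrelationMatrix", "correlation_matrix"]


def midranks(x) -> np.ndarray:
    """Mid-ranks (1-based): tied values get the mean of the ranks they
    span, so the ranks always sum to n(n+1)/2."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise DomainError("midranks expects a non-empty 1-d vector")
    if not np.isfinite(x).all():
        raise DomainError("midranks expects finite values")
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size, dtype=float)
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and x[order[j + 1]] == x[order[i]]:
            j += 1
        # positions i..j (0-based) share the average rank
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_rho(x, y) -> float:
    """Spearman's rank correlation with mid-rank tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("inputs must be 1-d vectors of equal length")
    if x.size < 3:
        raise DomainError("need at least 3 observations")
    rx, ry = midranks(x), midranks(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise DomainError("correlation undefined for a constant vector")
    return float(((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy))


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    sx, sy = rx.std(), ry.std()
    return float(((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy))


def spearman_pvalue(rho: float, n: int, method: str = "t-approx",
                    n_perm: int = 10_000,
                    seed: int | None = None) -> float:
    """Two-sided p-value for an observed Spearman coefficient.

    ``method="t-approx"`` uses the t transform with n-2 degrees of
    freedom.  ``method="permutation"`` uses the null distribution of the
    coefficient over permutations of tie-free ranks 1..n: exhaustive
    enumeration when n <= 7, otherwise ``n_perm`` seeded random
    permutations (with the add-one correction).
    """
    if n < 4:
        raise DomainError("p-value needs n >= 4")
    if not -1.0 <= rho <= 1.0:
        raise DomainError(f"rho must lie in [-1, 1], got {rho!r}")
    if method == "t-approx":
        if abs(rho) == 1.0:
            return 0.0
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        return float(2.0 * stats.t.sf(abs(t), df=n - 2))
    if method == "permutation":
        base = np.arange(1, n + 1, dtype=float)
        target = abs(rho) - 1e-12  # guard against FP noise at equality
        if n <= 7:
            hits = total = 0
            for perm in itertools.permutations(base):
                total += 1
                if abs(_rho_of_ranks(base, np.array(perm))) >= target:
                    hits += 1
            return hits / total
        rng = np.random.default_rng(seed)
        hits = 0
        perm = base.copy()
        for _ in range(n_perm):
            rng.shuffle(perm)
            if abs(_rho_of_ranks(base, perm)) >= target:
                hits += 1
        return (hits + 1) / (n_perm + 1)
    raise DomainError(f"unknown p-value method {method!r}")


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise rank-correlation matrix for one site.

    ``rho`` and ``p`` are symmetric DataFrames over ``metals``; the
    significance mask applies the two-sided test at level ``alpha``.
    """

    site: str
    metals: tuple[str, ...]
    rho: pd.DataFrame
    p: pd.DataFrame
    n: int
    alpha: float = 0.05

    @property
    def significant(self) -> pd.DataFrame:
        mask = self.p < self.alpha
        np.fill_diagonal(mask.values, False)
        return mask

    def to_long(self, ndigits: int = 3) -> pd.DataFrame:
        """Long-format report: metal_a, metal_b, rho, p, significant
        (upper triangle only)."""
        rows = []
        for i, a in enumerate(self.metals):
            for b in self.metals[i + 1:]:
                rows.append({
                    "metal_a": a, "metal_b": b,
                    "rho": round(float(self.rho.at[a, b]), ndigits),
                    "p": round(float(self.p.at[a, b]), max(ndigits, 4)),
                    "significant": bool(self.p.at[a, b] < self.alpha),
                })
        return pd.DataFrame(rows, columns=["metal_a", "metal_b", "rho", "p",
                                           "significant"])


def correlation_matrix(table: ConcentrationTable, site: str,
                       method: str = "t-approx", alpha: float = 0.05,
                       n_perm: int = 10_000,
                       seed: int | None = None) -> CorrelationMatrix:
    """Full pairwise Spearman matrix over one site's samples.

    Metals whose column is constant within the site (correlation
    undefined) get rho = NaN, p = NaN off-diagonal.
    """
    sub = table.subset(site)
    n = len(sub)
    if n < 4:
        raise DomainError(f"site {site!r} has only {n} samples; need >= 4")
    metals = tuple(sub.metals)
    m = len(metals)
    rho = np.eye(m)
    p = np.zeros((m, m))
    ranks = {}
    for sym in metals:
        col = sub.column(sym)
        ranks[sym] = midranks(col) if np.ptp(col) > 0 else None
    for i in range(m):
        for j in range(i + 1, m):
            ri, rj = ranks[metals[i]], ranks[metals[j]]
            if ri is None or rj is None:
                rho[i, j] = rho[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            r = _rho_of_ranks(ri, rj)
            rho[i, j] = rho[j, i] = r
            pv = spearman_pvalue(min(1.0, max(-1.0, r)), n, method=method,
                                 n_perm=n_perm, seed=seed)
            p[i, j] = p[j, i] = pv
    return CorrelationMatrix(
        site=site, metals=metals,
        rho=pd.DataFrame(rho, index=metals, columns=metals),
        p=pd.DataFrame(p, index=metals, columns=metals),
        n=n, alpha=alpha)
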