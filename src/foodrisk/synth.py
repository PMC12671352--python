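"""Synthetic concentration tables and consumer populations.

The generator emulates the statistical structure the analysis assumes:
right-skewed, site-specific, nonnegative concentrations with targeted
rank dependence between metal pairs.  Marginals are lognormal and the
dependence is induced through a latent Gaussian copula: a pairwise
target Spearman correlation ``rho_s`` is mapped to the latent Pearson
correlation ``r = 2*sin(pi*rho_s/6)`` (exact for bivariate Gaussian
ranks), the joint latent correlation matrix is validated positive
definite, and each metal is ``exp(log_mean + log_sd * z)`` of the
latent draw.  Below-LOD values are reported as 0.0, mirroring the
convention of published survey tables (and deliberately creating ties
for the correlation module to handle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ConcentrationTable
from .errors import ConfigError, NotPositiveDefiniteError
from .mc import PopulationModel

__all__ = ["MetalSpec", "SynthSpec", "generate_table",
           "generate_population", "spec_from_dict"]


@dataclass(frozen=True)
class MetalSpec:
    """Lognormal marginal for one metal: log-scale mean and sd."""

    symbol: str
    log_mean: float
    log_sd: float

    def __post_init__(self) -> None:
        if self.log_sd < 0:
            raise ConfigError(f"{self.symbol}: log_sd must be >= 0")


@dataclass(frozen=True)
class SynthSpec:
    """Ground-truth specification for a synthetic concentration table.

    Attributes
    ----------
    sites : sequence of (label, n_samples)
    metals : sequence of MetalSpec
        Marginals shared by all sites, or a mapping site -> sequence for
        site-specific marginals (same metal set everywhere).
    rank_dependence : sequence of (metal_a, metal_b, rho_s)
        Pairwise target Spearman correlations, |rho_s| < 1; realised
        jointly through one latent Gaussian whose correlation matrix
        must be positive definite.
    lod : mapping, optional
        Detection limit per metal; draws below it are recorded as 0.0.
    seed : int
    """

    sites: tuple[tuple[str, int], ...]
    metals: tuple[MetalSpec, ...] | Mapping[str, tuple[MetalSpec, ...]]
    rank_dependence: tuple[tuple[str, str, float], ...] = ()
    lod: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites",
                           tuple((str(l), int(n)) for l, n in self.sites))
        if not self.sites:
            raise ConfigError("need at least one site")
        for label, n in self.sites:
            if n < 1:
                raise ConfigError(f"site {label!r}: n_samples must be >= 1")
        if not isinstance(self.metals, Mapping):
            object.__setattr__(self, "metals", tuple(self.metals))
        for a, b, r in self.rank_dependence:
            if not abs(r) < 1:
                raise ConfigError(
                    f"target rank correlation for ({a}, {b}) must satisfy "
                    f"|rho| < 1, got {r}")

    def metals_for(self, site: str) -> tuple[MetalSpec, ...]:
        if isinstance(self.metals, Mapping):
            return tuple(self.metals[site])
        return self.metals


def _latent_correlation(symbols: Sequence[str],
                        pairs: Sequence[tuple[str, str, float]]
                        ) -> np.ndarray:
    """Latent Gaussian correlation realising the target Spearman pairs."""
    index = {s: i for i, s in enumerate(symbols)}
    corr = np.eye(len(symbols))
    for a, b, rho_s in pairs:
        if a not in index or b not in index:
            raise ConfigError(f"dependence pair ({a}, {b}) names an "
                              f"unknown metal")
        r = 2.0 * math.sin(math.pi * rho_s / 6.0)
        corr[index[a], index[b]] = corr[index[b], index[a]] = r
    try:
        np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise NotPositiveDefiniteError(
            "the requested rank-dependence targets do not form a positive "
            "definite latent correlation matrix") from None
    return corr


def generate_table(spec: SynthSpec) -> ConcentrationTable:
    """Draw a concentration table with known ground truth.

    Sample ids are ``<SITE><k>`` (k = 1..n per site).  The same spec and
    seed always produce an identical table.
    """
    rng = np.random.default_rng(spec.seed)
    ids, sites, rows = [], [], []
    columns: list[str] | None = None
    for label, n in spec.sites:
        metals = spec.metals_for(label)
        symbols = [m.symbol for m in metals]
        if columns is None:
            columns = symbols
        elif symbols != columns:
            raise ConfigError("all sites must share the same metal set")
        corr = _latent_correlation(symbols, spec.rank_dependence)
        z = rng.multivariate_normal(np.zeros(len(symbols)), corr, size=n,
                                    method="cholesky")
        mu = np.array([m.log_mean for m in metals])
        sd = np.array([m.log_sd for m in metals])
        values = np.exp(mu + sd * z)
        if spec.lod:
            for j, sym in enumerate(symbols):
                lod = spec.lod.get(sym)
                if lod is not None:
                    values[values[:, j] < lod, j] = 0.0
        for k in range(n):
            ids.append(f"{label}{k + 1}")
            sites.append(label)
            rows.append(values[k])
    data = pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"),
                        columns=columns)
    site_series = pd.Series(sites, index=data.index, name="site")
    return ConcentrationTable(data, site_series,
                              dict(spec.lod) if spec.lod else None)


def generate_population(model: PopulationModel, n: int,
                        seed: int = 0) -> pd.DataFrame:
    """Draw ``n`` consumers: columns stratum, bw (kg), dir (g/day)."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = np.random.default_rng(seed)
    props = np.array([s.proportion for s in model.strata])
    idx = rng.choice(len(model.strata), size=n, p=props / props.sum())
    bw = np.empty(n)
    dirs = np.empty(n)
    for k, stratum in enumerate(model.strata):
        mask = idx == k
        cnt = int(mask.sum())
        if cnt:
            bw[mask] = stratum.bw_dist.sample(rng, cnt)
            dirs[mask] = stratum.dir_dist.sample(rng, cnt)
    return pd.DataFrame({
        "stratum": [model.strata[k].label for k in idx],
        "bw": bw,
        "dir": dirs,
    })


def spec_from_dict(doc: Mapping) -> SynthSpec:
    """Build a :class:`SynthSpec` from a parsed YAML/JSON mapping.

    Expected keys: ``sites`` (list of ``{label, n}``), ``metals`` (list
    of ``{symbol, log_mean, log_sd}``), optional ``rank_dependence``
    (list of ``[a, b, rho]``), ``lod`` and ``seed``.
    """
    try:
        sites = tuple((s["label"], int(s["n"])) for s in doc["sites"])
        metals = tuple(MetalSpec(m["symbol"], float(m["log_mean"]),
                                 float(m["log_sd"])) for m in doc["metals"])
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"invalid synthetic-data config: {exc}") from None
    deps = tuple((a, b, float(r))
                 for a, b, r in doc.get("rank_dependence", ()))
    return SynthSpec(sites=sites, metals=metals, rank_dependence=deps,
                     lod=doc.get("lod"), seed=int(doc.get("seed", 0)))
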