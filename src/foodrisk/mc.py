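"""Probabilistic dietary-exposure simulation.

A seeded Monte Carlo chain over a heterogeneous consumer population:
each iteration draws an age/sex stratum by its population proportion, a
body weight and an ingestion rate from that stratum's distributions, and
one concentration per metal; the estimated daily intake then follows
from the same intake formula as the deterministic pipeline.  The output
per metal is the simulated EDI distribution and the probability of
exceeding a tolerable-intake limit, with its binomial standard error
``sqrt(p*(1-p)/n_iter)``.

Draw order is fixed (stratum indices, then body weights, then ingestion
rates, then one block per metal in config order) from a single
generator keyed by one seed, so identical configurations reproduce
bitwise-identical results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ConcentrationTable, builtin_registry
from .errors import ConfigError
from .risk import daily_intake

__all__ = [
    "DistributionSpec", "Stratum", "PopulationModel", "default_population",
    "McConfig", "McResult", "fit_concentration_dists", "run_simulation",
    "exceedance_table", "config_from_dict",
]

_FAMILIES = ("point", "normal", "lognormal", "triangular",
             "empirical-resample")

#: Reporting order for exceedance tables (the conventional order for
#: these seven reference-dose metals).
METAL_ORDER = ("Mn", "Fe", "Cu", "Zn", "As", "Cd", "Pb")


@dataclass(frozen=True)
class DistributionSpec:
    """One marginal sampling distribution.

    families and parameters
    -----------------------
    - ``point(value)``
    - ``normal(mean, sd)``               sd >= 0
    - ``lognormal(log_mean, log_sd)``    log-scale parameters, log_sd >= 0
    - ``triangular(left, mode, right)``  left <= mode <= right
    - ``empirical-resample(values...)``  resampling with replacement

    ``truncation=(low, high)`` (either side may be None) restricts the
    support by rejection sampling.
    """

    family: str
    params: tuple[float, ...]
    truncation: tuple[float | None, float | None] | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigError(f"unknown distribution family {self.family!r}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        p = self.params
        if self.family == "point" and len(p) != 1:
            raise ConfigError("point needs exactly one parameter")
        if self.family == "normal" and (len(p) != 2 or p[1] < 0):
            raise ConfigError("normal needs (mean, sd) with sd >= 0")
        if self.family == "lognormal" and (len(p) != 2 or p[1] < 0):
            raise ConfigError("lognormal needs (log_mean, log_sd) with "
                              "log_sd >= 0")
        if self.family == "triangular" and (
                len(p) != 3 or not p[0] <= p[1] <= p[2] or p[0] == p[2]):
            raise ConfigError("triangular needs left <= mode <= right, "
                              "left < right")
        if self.family == "empirical-resample" and len(p) < 1:
            raise ConfigError("empirical-resample needs at least one value")
        if self.truncation is not None:
            lo, hi = self.truncation
            if lo is not None and hi is not None and not lo < hi:
                raise ConfigError("truncation bounds must be ordered")

    def _draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        p = self.params
        if self.family == "point":
            return np.full(size, p[0])
        if self.family == "normal":
            return rng.normal(p[0], p[1], size)
        if self.family == "lognormal":
            return rng.lognormal(p[0], p[1], size)
        if self.family == "triangular":
            return rng.triangular(p[0], p[1], p[2], size)
        return rng.choice(np.asarray(p), size=size, replace=True)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Draw ``size`` values, applying truncation by rejection."""
        out = self._draw(rng, size)
        if self.truncation is None:
            return out
        lo, hi = self.truncation
        if self.family == "point":
            v = self.params[0]
            if (lo is not None and v <= lo) or (hi is not None and v >= hi):
                raise ConfigError("point mass lies outside its truncation")
            return out
        for _ in range(1000):
            bad = np.zeros(size, dtype=bool)
            if lo is not None:
                bad |= out <= lo
            if hi is not None:
                bad |= out >= hi
            if not bad.any():
                return out
            out[bad] = self._draw(rng, int(bad.sum()))
        raise ConfigError("rejection sampling failed to satisfy truncation")


@dataclass(frozen=True)
class Stratum:
    """One population stratum: label, proportion, and the body-weight
    (kg) and ingestion-rate (g/day) distributions."""

    label: str
    proportion: float
    bw_dist: DistributionSpec
    dir_dist: DistributionSpec

    def __post_init__(self) -> None:
        if not self.proportion > 0:
            raise ConfigError(f"stratum {self.label!r}: proportion must be > 0")


@dataclass(frozen=True)
class PopulationModel:
    """A mixture of strata whose proportions sum to one."""

    strata: tuple[Stratum, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "strata", tuple(self.strata))
        if not self.strata:
            raise ConfigError("population model needs at least one stratum")
        total = sum(s.proportion for s in self.strata)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"stratum proportions sum to {total}, not 1")


def default_population() -> PopulationModel:
    """Illustrative three-stratum population (adult male / adult female /
    child) with truncated-normal body weights and ingestion rates.

    These are the package's own defaults for demonstrating population
    variability — no survey of the study population exists — and should
    be replaced with local data where available.
    """
    return PopulationModel(strata=(
        Stratum("adult_male", 0.35,
                DistributionSpec("normal", (65.0, 10.0), (20.0, None)),
                DistributionSpec("normal", (60.0, 15.0), (0.0, None))),
        Stratum("adult_female", 0.40,
                DistributionSpec("normal", (58.0, 10.0), (20.0, None)),
                DistributionSpec("normal", (60.0, 15.0), (0.0, None))),
        Stratum("child", 0.25,
                DistributionSpec("normal", (25.0, 8.0), (5.0, None)),
                DistributionSpec("normal", (40.0, 12.0), (0.0, None))),
    ))


@dataclass(frozen=True)
class McConfig:
    """Monte Carlo configuration.

    ``conc_dist`` maps metal symbol to its concentration distribution
    (mg/kg); ``limits`` maps every simulated metal to its intake limit
    (µg/kg bw/day).
    """

    conc_dist: Mapping[str, DistributionSpec]
    limits: Mapping[str, float]
    population: PopulationModel = field(default_factory=default_population)
    n_iter: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ConfigError("n_iter must be >= 1")
        if not self.conc_dist:
            raise ConfigError("no concentration distributions supplied")
        missing = [m for m in self.conc_dist if m not in self.limits]
        if missing:
            raise ConfigError(f"no intake limit for metal(s): {missing}")
        for m, lim in self.limits.items():
            if not lim > 0:
                raise ConfigError(f"intake limit for {m!r} must be > 0")


@dataclass(frozen=True)
class McResult:
    """Simulation output: per-metal EDI summary and exceedance."""

    summary: pd.DataFrame      # metal, mean, sd, q2.5, median, q97.5,
                               # exceedance_prob, mc_se
    edi: pd.DataFrame          # n_iter x metals, µg/kg bw/day
    strata: np.ndarray         # stratum label per iteration
    config: McConfig

    @property
    def exceedance_prob(self) -> pd.Series:
        return self.summary.set_index("metal")["exceedance_prob"]


def fit_concentration_dists(table: ConcentrationTable,
                            metals: Iterable[str] | None = None,
                            site: str | None = None
                            ) -> dict[str, DistributionSpec]:
    """Fit lognormal concentration distributions per metal.

    The log-mean and log-sd are the mean and (population) standard
    deviation of the log observations.  Zeros (below-detection cells)
    are replaced by LOD/2 when a detection limit is known, otherwise
    dropped; a metal with fewer than 3 positive values after
    substitution is skipped with a warning.  A metal whose observations
    are all equal yields a degenerate ``point`` spec.
    """
    sub = table.subset(site) if site is not None else table
    metals = list(metals) if metals is not None else sub.metals
    out: dict[str, DistributionSpec] = {}
    for m in metals:
        obs = sub.column(m).astype(float).copy()
        lod = (sub.lod or {}).get(m)
        if lod is not None and lod > 0:
            obs[obs == 0.0] = lod / 2.0
        obs = obs[obs > 0]
        if obs.size < 3:
            warnings.warn(f"metal {m!r} skipped: fewer than 3 positive "
                          f"observations", stacklevel=2)
            continue
        logs = np.log(obs)
        sigma = float(logs.std())
        if sigma == 0.0:
            out[m] = DistributionSpec("point", (float(obs[0]),))
        else:
            out[m] = DistributionSpec("lognormal", (float(logs.mean()), sigma))
    return out


def run_simulation(config: McConfig) -> McResult:
    """Run the seeded exposure simulation.

    Per iteration: stratum ~ proportions; bw, dir from the stratum's
    distributions; one concentration per metal; EDI = c * dir / bw.
    The exceedance probability per metal is the fraction of iterations
    with EDI above that metal's limit.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_iter
    strata = config.population.strata
    props = np.array([s.proportion for s in strata])
    idx = rng.choice(len(strata), size=n, p=props / props.sum())

    bw = np.empty(n)
    dirs = np.empty(n)
    # fixed order: one bw block then one dir block per stratum
    for k, stratum in enumerate(strata):
        mask = idx == k
        cnt = int(mask.sum())
        if cnt:
            bw[mask] = stratum.bw_dist.sample(rng, cnt)
            dirs[mask] = stratum.dir_dist.sample(rng, cnt)

    metals = list(config.conc_dist)
    edi = pd.DataFrame(index=range(n), columns=metals, dtype=float)
    rows = []
    for m in metals:
        conc = config.conc_dist[m].sample(rng, n)
        intake = daily_intake(conc, dirs, bw)
        edi[m] = intake
        limit = float(config.limits[m])
        p_exc = float(np.mean(intake > limit))
        q = np.quantile(intake, [0.025, 0.5, 0.975])
        rows.append({
            "metal": m, "mean": float(intake.mean()),
            "sd": float(intake.std(ddof=1)) if n > 1 else 0.0,
            "q2.5": q[0], "median": q[1], "q97.5": q[2],
            "limit": limit, "exceedance_prob": p_exc,
            "mc_se": float(np.sqrt(p_exc * (1 - p_exc) / n)),
        })
    summary = pd.DataFrame(rows, columns=["metal", "mean", "sd", "q2.5",
                                          "median", "q97.5", "limit",
                                          "exceedance_prob", "mc_se"])
    labels = np.array([strata[k].label for k in idx])
    return McResult(summary=summary, edi=edi, strata=labels, config=config)


def exceedance_table(result: McResult) -> pd.DataFrame:
    """Report rows (metal, limit, probability) in conventional metal
    order, with the probability formatted as a percentage at one
    decimal."""
    summ = result.summary.set_index("metal")
    order = [m for m in METAL_ORDER if m in summ.index]
    order += [m for m in summ.index if m not in order]
    rows = []
    for m in order:
        p = float(summ.at[m, "exceedance_prob"])
        pct = p * 100.0
        if pct in (0.0, 100.0):
            text = f"{pct:.0f} %"
        else:
            text = f"{pct:.1f} %"
        rows.append({"metal": m, "limit": float(summ.at[m, "limit"]),
                     "probability": p, "probability_pct": text})
    return pd.DataFrame(rows, columns=["metal", "limit", "probability",
                                       "probability_pct"])


# -- YAML-style config plumbing ---------------------------------------------

def _dist_from_obj(obj) -> DistributionSpec:
    if isinstance(obj, DistributionSpec):
        return obj
    if isinstance(obj, Mapping):
        return DistributionSpec(
            family=obj["family"],
            params=tuple(obj.get("params", ())),
            truncation=tuple(obj["truncation"]) if obj.get("truncation")
            else None)
    if isinstance(obj, Sequence):
        return DistributionSpec(family=obj[0], params=tuple(obj[1:]))
    raise ConfigError(f"cannot interpret distribution spec {obj!r}")


def config_from_dict(doc: Mapping) -> McConfig:
    """Build an :class:`McConfig` from a parsed YAML/JSON mapping.

    Expected keys: ``n_iter``, ``seed``, ``distributions`` (metal ->
    spec), ``limits`` (metal -> µg/kg bw/day; defaults to the built-in
    registry's intake limits), ``strata`` (optional list of
    ``{label, proportion, bw, dir}``).
    """
    try:
        conc = {m: _dist_from_obj(s)
                for m, s in dict(doc["distributions"]).items()}
    except KeyError as exc:
        raise ConfigError(f"missing config key: {exc}") from None
    limits = dict(doc.get("limits", {}))
    if not limits:
        registry = builtin_registry()
        limits = {m: registry[m].intake_limit for m in conc
                  if m in registry and registry[m].intake_limit is not None}
    if "strata" in doc:
        strata = tuple(
            Stratum(label=s["label"], proportion=float(s["proportion"]),
                    bw_dist=_dist_from_obj(s["bw"]),
                    dir_dist=_dist_from_obj(s["dir"]))
            for s in doc["strata"])
        population = PopulationModel(strata)
    else:
        population = default_population()
    return McConfig(conc_dist=conc, limits=limits, population=population,
                    n_iter=int(doc.get("n_iter", 10_000)),
                    seed=int(doc.get("seed", 0)))
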