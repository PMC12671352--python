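"""Deterministic dietary risk indices: EDI, THQ, HI and limit screening.

The chain is the standard US-EPA style non-carcinogenic screen for a
contaminated foodstuff:

    EDI_i = C_i * DIR / BW                          [µg/kg bw/day]
    THQ_i = EDI_i * EF * ED / (RfD_i * AT) * 1e-3   [-]
    HI    = sum_i THQ_i                             [-]

with C_i the concentration (mg/kg dry weight), DIR the daily ingestion
rate (g/day), BW body weight (kg), EF exposure frequency (days/year),
ED exposure duration (years), AT averaging time (days) and RfD_i the
oral reference dose (mg/kg bw/day).  The 1e-3 factor converts EDI from
µg to mg and lives only here.  With the default scenario EF*ED = AT, so
THQ = EDI * 1e-3 / RfD.  HI > 1 flags likely adverse combined effects.

All arithmetic is kept at full precision; rounding happens only when
tables are emitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_SCENARIO,
    ConcentrationTable,
    ExposureScenario,
    MetalDescriptor,
    builtin_registry,
)
from .errors import DomainError, UnknownMetalError, UnknownSiteError

__all__ = [
    "HI_METALS",
    "daily_intake",
    "estimated_daily_intake",
    "target_hazard_quotient",
    "HazardIndex",
    "hazard_index",
    "RiskTable",
    "compute_risk_table",
    "ExceedanceReport",
    "exceedance_report",
    "SiteSummary",
    "site_summary",
]

#: Metals entering the hazard index by default: exactly those with an
#: oral reference dose in the built-in registry.
HI_METALS = ("Mn", "Fe", "Cu", "Zn", "As", "Cd", "Pb")


def daily_intake(conc, ingestion_rate, body_weight):
    """Vectorised EDI core: ``conc * ingestion_rate / body_weight``.

    mg/kg x g/day / kg gives µg per kg body weight per day directly.
    Accepts scalars or numpy arrays (broadcast).
    """
    return np.asarray(conc, dtype=float) * ingestion_rate / body_weight


def estimated_daily_intake(c: float, scenario: ExposureScenario
                           = DEFAULT_SCENARIO) -> float:
    """Estimated daily intake of one metal, µg/kg bw/day."""
    if c < 0:
        raise DomainError(f"concentration must be >= 0, got {c!r}")
    return float(daily_intake(c, scenario.dir, scenario.bw))


def target_hazard_quotient(edi: float, rfd: float | None,
                           scenario: ExposureScenario = DEFAULT_SCENARIO,
                           metal: str = "?") -> float:
    """Target hazard quotient from an EDI (µg/kg bw/day) and an RfD
    (mg/kg bw/day); dimensionless."""
    if rfd is None or not rfd > 0:
        raise DomainError(f"no positive oral reference dose for metal "
                          f"{metal!r} (rfd={rfd!r})")
    if edi < 0:
        raise DomainError(f"EDI must be >= 0, got {edi!r}")
    return edi * scenario.ef * scenario.ed / (rfd * scenario.at) * 1e-3


class HazardIndex(NamedTuple):
    """Sum of hazard quotients plus the HI > 1 screening flag."""

    value: float
    exceeds: bool


def hazard_index(thqs: Mapping[str, float]) -> HazardIndex:
    """Hazard index: the sum of the supplied THQs."""
    if not thqs:
        raise DomainError("hazard index needs at least one hazard quotient")
    total = float(sum(thqs.values()))
    return HazardIndex(total, total > 1.0)


@dataclass(frozen=True)
class RiskTable:
    """Per-sample risk indices for one scenario.

    Attributes
    ----------
    edi, thq : pandas.DataFrame
        Sample x metal estimated daily intakes (µg/kg bw/day) and hazard
        quotients, over ``metals_in_hi``.
    hi : pandas.Series
        Per-sample hazard index (sum of the THQ row).
    sites : pandas.Series
        Site label per sample.
    scenario : ExposureScenario
    metals_in_hi : tuple of str
    """

    edi: pd.DataFrame
    thq: pd.DataFrame
    hi: pd.Series
    sites: pd.Series
    scenario: ExposureScenario
    metals_in_hi: tuple[str, ...]

    def to_frame(self, ndigits: int = 2) -> pd.DataFrame:
        """Wide report table (sample, site, EDI_*, THQ_*, HI), rounded
        for emission; computation stays at full precision."""
        out = pd.DataFrame({"sample_id": self.hi.index,
                            "site": self.sites.values})
        for m in self.metals_in_hi:
            out[f"EDI_{m}"] = self.edi[m].round(ndigits).values
        for m in self.metals_in_hi:
            out[f"THQ_{m}"] = self.thq[m].round(ndigits).values
        out["HI"] = self.hi.round(ndigits).values
        return out


def compute_risk_table(table: ConcentrationTable,
                       registry: Mapping[str, MetalDescriptor] | None = None,
                       scenario: ExposureScenario = DEFAULT_SCENARIO,
                       metals: Iterable[str] | None = None) -> RiskTable:
    """Run the full deterministic EDI/THQ/HI chain over a table.

    ``metals`` defaults to the seven reference-dose metals; every
    requested metal must be present in the table and carry an RfD.
    """
    registry = registry or builtin_registry()
    metals = tuple(metals) if metals is not None else HI_METALS
    for m in metals:
        if m not in table.data.columns:
            raise UnknownMetalError(f"metal {m!r} missing from table")
        if m not in registry or registry[m].rfd is None:
            raise DomainError(f"no oral reference dose for metal {m!r}")

    conc = table.data[list(metals)]
    edi = conc.mul(scenario.dir / scenario.bw)
    rfds = pd.Series({m: registry[m].rfd for m in metals})
    thq = edi.mul(scenario.ef * scenario.ed / scenario.at * 1e-3).div(rfds)
    hi = thq.sum(axis=1)
    return RiskTable(edi=edi, thq=thq, hi=hi, sites=table.sites,
                     scenario=scenario, metals_in_hi=metals)


@dataclass(frozen=True)
class ExceedanceReport:
    """Fold exceedance of food limits, one row per limit-bearing metal."""

    frame: pd.DataFrame  # metal, max_concentration, food_limit, fold, exceeds
    site: str | None

    @property
    def exceeding_metals(self) -> list[str]:
        return self.frame.loc[self.frame["exceeds"], "metal"].tolist()

    def to_frame(self, ndigits: int = 1) -> pd.DataFrame:
        out = self.frame.copy()
        out["fold"] = out["fold"].round(ndigits)
        return out


def exceedance_report(table: ConcentrationTable,
                      registry: Mapping[str, MetalDescriptor] | None = None,
                      site: str | None = None) -> ExceedanceReport:
    """Screen maximum concentrations against food limits.

    For each registry metal with a food limit (and present in the
    table), report the maximum concentration over the selected samples
    (all samples, or one site), the fold ratio max/limit and the
    exceedance flag (fold > 1).
    """
    registry = registry or builtin_registry()
    sub = table.subset(site) if site is not None else table
    if len(sub) == 0:
        raise DomainError("empty sample selection")
    rows = []
    for m, desc in registry.items():
        if desc.food_limit is None or m not in sub.data.columns:
            continue
        cmax = float(sub.data[m].max())
        fold = cmax / desc.food_limit
        rows.append({"metal": m, "max_concentration": cmax,
                     "food_limit": desc.food_limit, "fold": fold,
                     "exceeds": fold > 1.0})
    if not rows:
        raise DomainError("no registry metal with a food limit is present")
    frame = pd.DataFrame(rows, columns=["metal", "max_concentration",
                                        "food_limit", "fold", "exceeds"])
    return ExceedanceReport(frame=frame, site=site)


class SiteSummary(NamedTuple):
    """Hazard-index summary for one site."""

    hi_min: float
    hi_max: float
    hi_mean: float
    n: int


def site_summary(risk: RiskTable, site: str) -> SiteSummary:
    """Extrema and mean of the hazard index over one site's samples."""
    mask = risk.sites == site
    if not mask.any():
        raise UnknownSiteError(f"site {site!r} not in risk table")
    values = risk.hi.loc[mask]
    return SiteSummary(float(values.min()), float(values.max()),
                       float(values.mean()), int(mask.sum()))
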