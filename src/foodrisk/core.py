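"""Domain types, the built-in metal registry, and delimited-text I/O.

Units are fixed throughout the package: concentrations are mg/kg dry
weight, ingestion rate g/day, body weight kg, estimated daily intake
µg/kg bw/day.  The only unit conversion anywhere is the 10^-3 factor
(µg -> mg) applied inside the target-hazard-quotient formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    ConcentrationValueError,
    DomainError,
    DuplicateSampleError,
    MissingColumnError,
    UnknownMetalError,
    UnknownSiteError,
)

__all__ = [
    "MetalDescriptor",
    "ExposureScenario",
    "DEFAULT_SCENARIO",
    "ConcentrationTable",
    "CsvDialect",
    "builtin_registry",
    "read_concentration_table",
    "write_concentration_table",
]


@dataclass(frozen=True)
class MetalDescriptor:
    """One trace element and its regulatory reference values.

    Parameters
    ----------
    symbol : str
        Element symbol, e.g. ``"Cd"``; unique within a registry.
    name : str
        Human-readable element name.
    rfd : float, optional
        Oral reference dose, mg per kg body weight per day.
    food_limit : float, optional
        Maximum permissible concentration in food, mg/kg.
    intake_limit : float, optional
        Maximum tolerable daily intake, µg per kg body weight per day.
    """

    symbol: str
    name: str
    rfd: float | None = None
    food_limit: float | None = None
    intake_limit: float | None = None

    def __post_init__(self) -> None:
        if not self.symbol:
            raise DomainError("metal symbol must be non-empty")
        for attr in ("rfd", "food_limit", "intake_limit"):
            value = getattr(self, attr)
            if value is not None and not value > 0:
                raise DomainError(f"{attr} must be > 0 when present "
                                  f"({self.symbol}: {value!r})")


@dataclass(frozen=True)
class ExposureScenario:
    """Chronic-ingestion exposure parameters.

    Defaults describe an adult consumer of leafy vegetables: 60 g/day
    ingestion, 58 kg body weight, daily exposure (365 d/y) over a 70-year
    duration averaged over 25,550 days, so EF*ED = AT and the hazard
    quotient reduces to EDI * 1e-3 / RfD.

    Attributes
    ----------
    dir : float
        Daily ingestion rate, g/day.
    bw : float
        Body weight, kg.
    ef : float
        Exposure frequency, days/year.
    ed : float
        Exposure duration, years.
    at : float
        Averaging time, days.
    """

    dir: float = 60.0
    bw: float = 58.0
    ef: float = 365.0
    ed: float = 70.0
    at: float = 25550.0

    def __post_init__(self) -> None:
        for name in ("dir", "bw", "ef", "ed", "at"):
            if not getattr(self, name) > 0:
                raise DomainError(f"scenario field {name!r} must be > 0")
        if self.ef > 366:
            raise DomainError("exposure frequency cannot exceed 366 days/year")


DEFAULT_SCENARIO = ExposureScenario()


# Oral reference doses, mg/kg bw/day (US EPA IRIS values as used for
# leafy-vegetable risk screening).  Only these seven metals enter the
# hazard index by default.
_RFD = {
    "As": 3.0e-4,
    "Cd": 1.0e-3,
    "Cu": 4.0e-2,
    "Fe": 7.0e-1,
    "Mn": 1.4e-1,
    "Pb": 4.0e-3,
    "Zn": 3.0e-1,
}

# FAO/WHO (2003) maximum permissible concentrations in (leafy) vegetables,
# mg/kg.  The printed source row is typographically ambiguous; the values
# below are fixed by back-calculation from the published fold-exceedance
# statements (4.55/3.5 -> 1.3 Cr; 115.39/2.9 -> 40 Cu; 2.95/29.5 -> 0.1 Cd;
# 0.058/58 -> 0.001 Hg; Pb 0.3).
_FOOD_LIMIT = {
    "Cr": 1.3,
    "Cu": 40.0,
    "Cd": 0.1,
    "Pb": 0.3,
    "Hg": 0.001,
}

# WHO tolerable daily-intake limits, µg/kg bw/day, for the probabilistic
# exceedance screen.
_INTAKE_LIMIT = {
    "Mn": 700.0,
    "Fe": 1000.0,
    "Cu": 40.0,
    "Zn": 1000.0,
    "As": 2.14,
    "Cd": 1.0,
    "Pb": 3.6,
}

_NAMES = {
    "Ti": "Titanium", "V": "Vanadium", "Cr": "Chromium", "Mn": "Manganese",
    "Fe": "Iron", "Co": "Cobalt", "Ni": "Nickel", "Cu": "Copper",
    "Zn": "Zinc", "As": "Arsenic", "Se": "Selenium", "Mo": "Molybdenum",
    "Ag": "Silver", "Cd": "Cadmium", "Sn": "Tin", "Sb": "Antimony",
    "Ba": "Barium", "Pb": "Lead", "Hg": "Mercury",
}

REGISTRY_VERSION = "FAO/WHO-2003+EPA-RfD"


def builtin_registry() -> dict[str, MetalDescriptor]:
    """Return the built-in registry covering all 19 surveyed metals.

    Exactly seven metals (Mn, Fe, Cu, Zn, As, Cd, Pb) carry an oral
    reference dose and an intake limit; Cr, Cu, Cd, Pb and Hg carry a
    food limit.
    """
    return {
        sym: MetalDescriptor(
            symbol=sym,
            name=name,
            rfd=_RFD.get(sym),
            food_limit=_FOOD_LIMIT.get(sym),
            intake_limit=_INTAKE_LIMIT.get(sym),
        )
        for sym, name in _NAMES.items()
    }


class ConcentrationTable:
    """A sample-by-metal concentration matrix with site labels.

    Parameters
    ----------
    data : pandas.DataFrame
        Concentrations (mg/kg dry weight), indexed by sample identifier,
        one column per metal symbol.  Values must be finite and >= 0.
    sites : pandas.Series
        Site label per sample identifier (same index as ``data``).
    lod : mapping, optional
        Detection limit (mg/kg) per metal symbol; metals may be absent.
    """

    def __init__(self, data: pd.DataFrame, sites: pd.Series,
                 lod: Mapping[str, float] | None = None) -> None:
        data = data.astype(float).copy()
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise DuplicateSampleError(f"duplicate sample id(s): {dupes}")
        values = data.to_numpy()
        if not np.isfinite(values).all():
            raise ConcentrationValueError("non-finite concentration present")
        if (values < 0).any():
            bad = data.stack().loc[lambda s: s < 0].index[0]
            raise ConcentrationValueError(
                f"negative concentration at sample {bad[0]!r}, metal {bad[1]!r}")
        sites = sites.reindex(data.index)
        if sites.isna().any():
            missing = sites.index[sites.isna()].tolist()
            raise UnknownSiteError(f"no site label for sample(s): {missing}")
        self.data = data
        self.sites = sites.astype(str)
        self.lod = dict(lod) if lod else None

    # -- basic introspection -------------------------------------------------

    @property
    def metals(self) -> list[str]:
        return list(self.data.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def site_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sites:
            seen.setdefault(s, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.data)

    def __getitem__(self, key: tuple[str, str]) -> float:
        """Concentration for ``(sample_id, metal)``."""
        sample, metal = key
        if metal not in self.data.columns:
            raise UnknownMetalError(f"metal {metal!r} not in table")
        return float(self.data.at[sample, metal])

    def column(self, metal: str) -> np.ndarray:
        if metal not in self.data.columns:
            raise UnknownMetalError(f"metal {metal!r} not in table")
        return self.data[metal].to_numpy()

    def subset(self, site: str) -> "ConcentrationTable":
        """Restrict to the samples of one site."""
        if site not in set(self.sites):
            raise UnknownSiteError(
                f"site {site!r} not in table (sites: {self.site_labels})")
        mask = self.sites == site
        return ConcentrationTable(self.data.loc[mask], self.sites.loc[mask],
                                  self.lod)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConcentrationTable):
            return NotImplemented
        return (self.data.equals(other.data)
                and self.sites.equals(other.sites)
                and self.lod == other.lod)

    def __repr__(self) -> str:
        return (f"<ConcentrationTable: {len(self)} samples x "
                f"{len(self.metals)} metals, sites {self.site_labels}>")


@dataclass(frozen=True)
class CsvDialect:
    """Options for reading/writing delimited concentration tables.

    ``site_prefixes`` maps sample-id prefixes to site labels and is used
    to infer sites when no site column is present (survey tables often
    encode the station in the sample code).  ``decimal`` may be set to
    ``","`` for comma-decimal locales.  A row whose sample id equals
    ``lod_label`` is interpreted as per-metal detection limits; blank
    cells there mean "no detection limit reported for this metal".
    """

    sep: str = ","
    decimal: str = "."
    sample_column: str = "sample_id"
    site_column: str = "site"
    site_prefixes: Mapping[str, str] = field(
        default_factory=lambda: {"CS": "Cecomaf", "LS": "Lutendele"})
    lod_label: str = "LOD"


DEFAULT_DIALECT = CsvDialect()


def _infer_site(sample_id: str, prefixes: Mapping[str, str]) -> str | None:
    # longest prefix wins so e.g. "LS" does not shadow "LSX"
    for prefix in sorted(prefixes, key=len, reverse=True):
        if sample_id.startswith(prefix):
            return prefixes[prefix]
    return None


def _parse_number(raw: object, dialect: CsvDialect, sample: str,
                  metal: str) -> float:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        raise ConcentrationValueError(
            f"empty concentration at sample {sample!r}, column {metal!r}")
    text = str(raw).strip()
    if dialect.decimal != ".":
        text = text.replace(dialect.decimal, ".")
    try:
        value = float(text)
    except ValueError:
        raise ConcentrationValueError(
            f"non-numeric concentration {raw!r} at sample {sample!r}, "
            f"column {metal!r}") from None
    if not math.isfinite(value):
        raise ConcentrationValueError(
            f"non-finite concentration at sample {sample!r}, column {metal!r}")
    if value < 0:
        raise ConcentrationValueError(
            f"negative concentration {value} at sample {sample!r}, "
            f"column {metal!r}")
    return value


def read_concentration_table(path: str | Path,
                             dialect: CsvDialect | None = None
                             ) -> ConcentrationTable:
    """Read a wide-format concentration table from delimited text.

    The header row must name the sample-id column; a site column is
    optional (sites are otherwise inferred from sample-id prefixes per
    the dialect).  All remaining columns are treated as metal symbols.
    """
    dialect = dialect or DEFAULT_DIALECT
    raw = pd.read_csv(path, sep=dialect.sep, dtype=str,
                      keep_default_na=False, na_values=[])
    if dialect.sample_column not in raw.columns:
        raise MissingColumnError(
            f"sample-id column {dialect.sample_column!r} not found "
            f"(columns: {list(raw.columns)})")
    has_site = dialect.site_column in raw.columns
    metals = [c for c in raw.columns
              if c not in (dialect.sample_column, dialect.site_column)]

    ids, sites, rows = [], [], []
    lod: dict[str, float] = {}
    seen: set[str] = set()
    for _, record in raw.iterrows():
        sid = str(record[dialect.sample_column]).strip()
        if sid == dialect.lod_label:
            for metal in metals:
                cell = str(record[metal]).strip()
                if cell:
                    lod[metal] = _parse_number(cell, dialect, sid, metal)
            continue
        if sid in seen:
            raise DuplicateSampleError(f"duplicate sample id {sid!r}")
        seen.add(sid)
        site = str(record[dialect.site_column]).strip() if has_site else ""
        if not site:
            site = _infer_site(sid, dialect.site_prefixes)
            if site is None:
                raise UnknownSiteError(
                    f"cannot infer site for sample {sid!r}: no site column "
                    f"and no matching prefix in {dict(dialect.site_prefixes)}")
        ids.append(sid)
        sites.append(site)
        rows.append([_parse_number(record[m], dialect, sid, m)
                     for m in metals])

    data = pd.DataFrame(rows, index=pd.Index(ids, name=dialect.sample_column),
                        columns=metals)
    site_series = pd.Series(sites, index=data.index, name=dialect.site_column)
    return ConcentrationTable(data, site_series, lod or None)


def write_concentration_table(table: ConcentrationTable, path: str | Path,
                              dialect: CsvDialect | None = None) -> None:
    """Write a table as delimited text readable by
    :func:`read_concentration_table` (lossless round trip)."""
    dialect = dialect or DEFAULT_DIALECT

    def fmt(x: float) -> str:
        text = repr(float(x))
        if dialect.decimal != ".":
            text = text.replace(".", dialect.decimal)
        return text

    lines = [dialect.sep.join([dialect.sample_column, dialect.site_column]
                              + table.metals)]
    if table.lod is not None:
        cells = [fmt(table.lod[m]) if m in table.lod else ""
                 for m in table.metals]
        lines.append(dialect.sep.join([dialect.lod_label, ""] + cells))
    for sid in table.sample_ids:
        row = [sid, str(table.sites.at[sid])]
        row += [fmt(table.data.at[sid, m]) for m in table.metals]
        lines.append(dialect.sep.join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
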