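"""Analytical quality control: CRM recovery and detection-limit flagging.

Recovery against a certified reference material (CRM) is the standard
accuracy check for trace-element determinations; a recovery within
90-110 % is conventionally considered acceptable.  Detection-limit
flagging marks cells whose reported concentration falls strictly below
the per-metal limit of detection (LOD); the boundary counts as detected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .core import ConcentrationTable
from .datasets import BCR482_HG_CERTIFIED, BCR482_HG_MEASURED
from .errors import DomainError

__all__ = ["CrmComparison", "crm_recovery", "flag_below_lod", "qc_report",
           "substitute_below_lod", "builtin_crm_pairs"]


def crm_recovery(measured: float, certified: float,
                 ndigits: int | None = 1) -> float:
    """Percent recovery of a certified reference material.

    Parameters
    ----------
    measured, certified : float
        Concentrations in the same units (mg/kg); ``certified`` must be
        positive.
    ndigits : int or None
        Decimals for reporting (default one; ``0`` gives the integer
        rounding conventional in method write-ups, ``None`` no rounding).
    """
    if not certified > 0:
        raise DomainError(f"certified value must be > 0, got {certified!r}")
    if measured < 0:
        raise DomainError(f"measured value must be >= 0, got {measured!r}")
    pct = 100.0 * measured / certified
    return pct if ndigits is None else round(pct, ndigits)


@dataclass(frozen=True)
class CrmComparison:
    """Measured-vs-certified pair for one metal, with percent recovery."""

    metal: str
    measured: float
    certified: float

    @property
    def recovery_pct(self) -> float:
        return crm_recovery(self.measured, self.certified, ndigits=None)


def builtin_crm_pairs() -> list[CrmComparison]:
    """CRM BCR-482 pairs shipped with the package (Hg only: the single
    unambiguous measured/certified pair in the survey record)."""
    return [CrmComparison("Hg", BCR482_HG_MEASURED, BCR482_HG_CERTIFIED)]


def flag_below_lod(table: ConcentrationTable) -> pd.DataFrame:
    """Boolean mask, sample x metal: True iff concentration < LOD.

    Strict inequality: a value equal to its detection limit counts as
    detected.  Metals without an LOD entry are never flagged.
    """
    if table.lod is None:
        raise DomainError("table carries no detection-limit map")
    mask = pd.DataFrame(False, index=table.data.index,
                        columns=table.data.columns)
    for metal, limit in table.lod.items():
        if metal in mask.columns:
            mask[metal] = table.data[metal] < limit
    return mask


def substitute_below_lod(table: ConcentrationTable) -> ConcentrationTable:
    """Return a copy with below-LOD cells replaced by LOD/2.

    This substitution policy is OFF by default everywhere in the
    package: published downstream tables are reproduced only with the
    as-reported zeros.  It is offered for sensitivity analyses.
    """
    mask = flag_below_lod(table)
    data = table.data.copy()
    for metal, limit in (table.lod or {}).items():
        if metal in data.columns:
            data.loc[mask[metal], metal] = limit / 2.0
    return ConcentrationTable(data, table.sites, table.lod)


def qc_report(pairs: Iterable[CrmComparison] | None = None,
              threshold: float = 90.0) -> pd.DataFrame:
    """CRM recovery report: one row per metal with a pass flag.

    ``threshold`` is the minimum acceptable percent recovery (default 90).
    """
    pairs = list(pairs) if pairs is not None else builtin_crm_pairs()
    rows = [{
        "metal": p.metal,
        "measured": p.measured,
        "certified": p.certified,
        "recovery_pct": round(p.recovery_pct, 1),
        "pass": p.recovery_pct >= threshold,
    } for p in pairs]
    return pd.DataFrame(rows, columns=["metal", "measured", "certified",
                                       "recovery_pct", "pass"])
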