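"""Packaged reference dataset.

The built-in table is the published 2025 survey of trace elements in
*Brassica pekinensis* Lour. leaves from two urban gardening stations in
Kinshasa (DR Congo): 19 samples (11 from Cecomaf, 8 from Lutendele),
19 metals, mg/kg dry weight, with the reported per-metal detection
limits.  Below-detection cells are stored as 0.0 exactly as published;
see :mod:`foodrisk.qc` for an optional LOD/2 substitution policy.
"""

from __future__ import annotations

from importlib import resources

from .core import ConcentrationTable, read_concentration_table

__all__ = ["load_brassica"]

# BCR-482 (lichen) certified-vs-measured mercury pair, mg/kg: the one CRM
# pair from the survey's quality-control record that is unambiguous.
BCR482_HG_MEASURED = 0.46
BCR482_HG_CERTIFIED = 0.48


def load_brassica() -> ConcentrationTable:
    """Load the packaged Kinshasa *Brassica pekinensis* survey table."""
    path = resources.files("foodrisk") / "data" / "brassica_kinshasa.csv"
    with resources.as_file(path) as p:
        return read_concentration_table(p)
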