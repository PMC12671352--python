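"""Exception hierarchy for foodrisk.

Every error raised on a user-facing contract violation derives from
:class:`FoodRiskError`, so callers (and the CLI) can catch one base class.
Reader errors are split into distinct classes because malformed survey
tables are the most common failure mode in practice and each cause calls
for a different fix.
"""


class FoodRiskError(Exception):
    """Base class for all foodrisk errors."""


class TableFormatError(FoodRiskError):
    """A delimited concentration table violates the expected layout."""


class MissingColumnError(TableFormatError):
    """The sample-identifier (or another required) column is absent."""


class ConcentrationValueError(TableFormatError):
    """A concentration cell is non-numeric, negative or non-finite."""


class DuplicateSampleError(TableFormatError):
    """Two rows share the same sample identifier."""


class DomainError(FoodRiskError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class UnknownMetalError(DomainError):
    """A metal symbol is not present in the table or registry at hand."""


class UnknownSiteError(DomainError):
    """A site label is not present in the table at hand."""


class ConfigError(FoodRiskError):
    """A simulation or generator configuration is invalid."""


class NotPositiveDefiniteError(ConfigError):
    """The requested latent dependence structure is not realisable."""
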