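"""Exception hierarchy for the dmienrich pipeline."""


class DmiEnrichError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(DmiEnrichError):
    """An input file does not contain the expected columns."""


class EmptyInputError(DmiEnrichError):
    """A required input file contains no data rows."""


class ConfigError(DmiEnrichError):
    """Inconsistent configuration (e.g. strategy/schema mismatch)."""


class InfeasibleShuffleError(DmiEnrichError):
    """No duplicate-free shuffle could be produced within the retry budget."""


class UndefinedStatError(DmiEnrichError):
    """A statistic is undefined for the given inputs (e.g. mean random count 0)."""
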