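"""Exception hierarchy for panel/registry validation and scoring failures."""


class SdgAttainError(Exception):
    """Base class for all package errors."""


class SchemaError(SdgAttainError):
    """A file or table violates the expected schema (missing field, bad enum, wrong cardinality)."""


class DuplicateKeyError(SchemaError):
    """Duplicate (location, indicator, sex, year) or duplicate indicator_id."""


class DomainError(SdgAttainError):
    """A value lies outside its indicator's transform domain."""


class ConsistencyError(SdgAttainError):
    """Cross-table keys disagree (e.g. scores vs topic indices)."""


class InsufficientDataError(SdgAttainError):
    """Too few observations for the requested operation."""


class DegenerateAnchorError(SdgAttainError):
    """Worst and target anchors coincide; the 0-100 scale is undefined."""
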