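"""Exception hierarchy for the package."""


class PiradsCdeError(Exception):
    """Base class for all package errors."""


class SchemaParseError(PiradsCdeError):
    """Raised when a schema definition file is malformed."""


class DuplicateVariableError(SchemaParseError):
    """Raised when a schema defines the same variable name twice."""


class UnknownValueError(PiradsCdeError):
    """Raised when a categorical value is outside its vocabulary."""


class UnknownVariableError(PiradsCdeError):
    """Raised when report data references variables absent from the schema."""


class DuplicateRecordError(PiradsCdeError):
    """Raised when the same (lesion, rater, session, variable) cell appears twice."""


class IncompleteReportError(PiradsCdeError):
    """Raised when scoring requires CDE values that are not populated."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"report is missing required CDE values: {', '.join(self.missing)}")


class InsufficientDataError(PiradsCdeError):
    """Raised when an agreement statistic has no usable subjects or pairs."""


class DegenerateDataError(PiradsCdeError):
    """Raised when a statistic is undefined for the observed data (e.g. pe = 1)."""


class AlignmentError(PiradsCdeError):
    """Raised when two rating matrices do not share subjects/raters."""


class ConfigError(PiradsCdeError):
    """Raised for invalid generator or analysis configuration."""
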