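"""Exception taxonomy shared across the pipeline stages."""


class TagfunError(Exception):
    """Base class for all package errors."""


class ParameterError(TagfunError, ValueError):
    """A parameter is outside its natural range."""


class SizeError(TagfunError, ValueError):
    """A sample size / count argument is degenerate (zero or too small)."""


class FeasibilityError(TagfunError, ValueError):
    """Requested configuration is mathematically unattainable.

    Carries ``attainable`` where a maximum attainable value is known
    (e.g. the maximum r-squared for given marginal allele frequencies).
    """

    def __init__(self, message: str, attainable: float | None = None):
        super().__init__(message)
        self.attainable = attainable


class DegenerateInputError(TagfunError, ValueError):
    """Input is structurally degenerate (constant vector, zero margin, monomorphic SNP)."""


class ParseError(TagfunError, ValueError):
    """A file does not parse under the named standard."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class TemplateError(TagfunError, ValueError):
    """Allele-template string is malformed (zero or multiple allele slots)."""


class CoordinateError(TagfunError, ValueError):
    """Sequence coordinate disagrees with the stated allele."""


class ConfigError(TagfunError, ValueError):
    """Pipeline configuration failed validation."""
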