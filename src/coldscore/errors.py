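"""Exception hierarchy for coldscore.

Every error raised by the library derives from :class:`ColdscoreError`, so
callers (and the CLI) can distinguish pipeline failures from programming
errors with a single ``except`` clause.
"""


class ColdscoreError(Exception):
    """Base class for all coldscore errors."""


class FormatError(ColdscoreError):
    """A tabular input file does not conform to the expected layout."""


class ParseError(FormatError):
    """A cell could not be parsed; carries the offending row number."""


class RegistryError(ColdscoreError):
    """A trait is missing from, or inconsistent with, the trait registry."""


class ValidationError(ColdscoreError):
    """Dataset-level invariant violated (labels, completeness, positivity)."""


class DomainError(ColdscoreError):
    """A numeric precondition of a formula is violated (e.g. control mean <= 0)."""


class ConfigError(ColdscoreError):
    """Invalid generator or pipeline configuration."""
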