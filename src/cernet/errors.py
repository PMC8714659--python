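"""Exception hierarchy for the cernet pipeline.

Every stage raises a subclass of :class:`CernetError` so the CLI can map
failure classes to distinct exit codes (config = 2, I/O/parse = 3,
validation = 4).
"""


class CernetError(Exception):
    """Base class for all cernet errors."""

    exit_code = 1


class ConfigurationError(CernetError):
    """Invalid configuration value; the message names the offending field."""

    exit_code = 2


class ParseError(CernetError):
    """Malformed input file; the message carries the line number."""

    exit_code = 3


class ValidationError(CernetError):
    """Input data violates a stage precondition."""

    exit_code = 4


class AlphabetError(ValidationError):
    """Sequence contains characters outside the RNA alphabet."""


class BoundsError(ValidationError):
    """Position falls outside the target sequence."""


class InsufficientReplicationError(ValidationError):
    """A sample group has fewer than two replicates; no t-test possible."""


class MissingFeatureError(ValidationError):
    """A required feature id is absent from the expression matrix."""
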