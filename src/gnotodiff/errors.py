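"""Exception hierarchy for the pipeline.

All package-specific failures derive from :class:`GnotodiffError` so callers
can catch one base class at the CLI boundary.
"""


class GnotodiffError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(GnotodiffError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class SchemaError(GnotodiffError, ValueError):
    """A feature table violates the delimited-dialect schema or an invariant."""


class AlignmentError(GnotodiffError, ValueError):
    """Tables cannot be merged because their sample sheets disagree."""


class InputError(GnotodiffError, ValueError):
    """A numeric input violates a precondition (negative intensity, empty vector, ...)."""
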