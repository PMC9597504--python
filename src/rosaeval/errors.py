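"""Exception hierarchy shared across the pipeline.

All data-facing failures derive from :class:`RosaevalError` so callers (and
the CLI) can catch one base class; the subclasses mirror the distinct
failure modes of reading tables, validating invariants and configuring runs.
"""


class RosaevalError(Exception):
    """Base class for all rosaeval errors."""


class SchemaError(RosaevalError):
    """A table is missing a required column or has an unknown schema."""


class ParseError(RosaevalError):
    """A cell could not be parsed (e.g. non-numeric text in a numeric column)."""


class ValidationError(RosaevalError):
    """A value or structure violates a type invariant."""


class RangeError(RosaevalError):
    """A numeric argument falls outside its admissible range."""


class ConfigError(RosaevalError):
    """A run configuration is malformed or names an unknown key."""
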