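"""Exception hierarchy.

All errors raised on bad user input derive from :class:`LitpathError` so
callers (and the CLI) can distinguish usage problems from bugs.
"""


class LitpathError(Exception):
    """Base class for all litpath errors."""


class ConfigurationError(LitpathError):
    """A configuration object violates its invariants; names the field."""


class UsageError(LitpathError):
    """An operation was called with arguments it cannot accept."""

class InputError(LitpathError):
    """A data value (taxid, sequence, partition) is invalid."""


class FormatError(LitpathError):
    """A file could not be parsed into a valid object."""


class CurationError(LitpathError):
    """Interaction curation failed under strict rules."""


class SerializationError(LitpathError):
    """A graph violating its invariants cannot be serialized."""
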