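"""Exception hierarchy.

Errors are split by origin: bad configuration values, malformed register
files, inconsistent stand state, and misuse of an operation (e.g. applying a
peatland-only rule to a mineral compartment, or re-applying a protection
structure to an already-protected ledger).
"""


class CatchexError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CatchexError, ValueError):
    """A configuration value violates its documented constraints."""


class SchemaError(CatchexError, ValueError):
    """A register/ledger file does not conform to the documented CSV schema."""


class StandStateError(CatchexError, ValueError):
    """A compartment's stand state is internally inconsistent."""


class UsageError(CatchexError, ValueError):
    """An operation was applied to an object it is not defined for."""
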