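"""Typed exceptions raised throughout the package.

Every malformed input raises one of these; nothing is silently coerced.
"""


class UbafitError(Exception):
    """Base class for all package errors."""


class FormatError(UbafitError):
    """A table is structurally wrong (missing column, unparsable cell)."""


class ValidationError(UbafitError):
    """A table parsed but violates a physical or structural invariant."""


class UndefinedEquilibriumError(ValidationError):
    """A per-point dissociation constant is undefined (e.g. no dimer signal)."""


class NonIdentifiableError(UbafitError):
    """The data cannot constrain the requested fit parameters."""


class NumericError(UbafitError):
    """A numeric routine failed to converge or hit an impossible regime."""
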