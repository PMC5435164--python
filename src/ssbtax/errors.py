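"""Exception hierarchy.

Exit-code mapping in the CLI relies on this split: configuration problems
(bad scenario names, invalid probability vectors) are user-fixable,
domain errors indicate invalid data, numerical errors indicate solver
failure, and I/O errors bubble up from the filesystem.
"""


class SSBTaxError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SSBTaxError):
    """Invalid configuration: unknown scenario, bad probability vector, ..."""


class DomainError(SSBTaxError):
    """Input data violates a documented precondition or invariant."""


class ValidationError(DomainError):
    """A file row failed validation; message names the offending row."""


class NumericalError(SSBTaxError):
    """Integration or root finding produced a non-finite or out-of-range result."""
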