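"""Exception hierarchy shared across the package.

Exit-code mapping used by the command-line layer:
``ValidationError`` -> 2, ``IdentityError`` -> 3, ``NumericalError`` -> 4.
"""


class MethylhetError(Exception):
    """Base class for all package errors."""


class ValidationError(MethylhetError):
    """An input file or in-memory object violates a structural invariant."""


class IdentityError(MethylhetError):
    """SNP-probe sample-identity verification found a mismatched sample."""


class NumericalError(MethylhetError):
    """A numerical routine failed (non-convergence, non-identifiable model)."""
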