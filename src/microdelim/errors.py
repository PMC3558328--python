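"""Exception hierarchy shared across the package.

``InputError`` maps to CLI exit code 2, ``NumericalError`` to exit code 3.
"""


class MicrodelimError(Exception):
    """Base class for all package-specific errors."""


class InputError(MicrodelimError):
    """Malformed or inconsistent user input."""


class AlignmentError(InputError):
    """Sequences violate alignment invariants (e.g. unequal lengths)."""


class ValidationError(InputError):
    """Data fails a validity check (e.g. a non-ultrametric tree)."""


class UndefinedDistanceError(MicrodelimError):
    """A pairwise distance cannot be computed (no comparable sites)."""


class NumericalError(MicrodelimError):
    """A numerical routine failed or produced non-finite intermediates."""
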