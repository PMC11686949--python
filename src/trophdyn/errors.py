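"""Exception hierarchy shared across the package.

Validation problems (bad arguments, malformed tables) and numerical
problems (factorization failures, non-convergence) are kept distinct so
the CLI can map them to different exit codes.
"""


class TrophdynError(Exception):
    """Base class for all package errors."""


class ValidationError(TrophdynError, ValueError):
    """Invalid arguments or malformed input tables."""


class AlignmentError(ValidationError):
    """Covariate / observation index misalignment; names the missing key."""


class NumericalError(TrophdynError, RuntimeError):
    """Numerical failure (factorization, non-finite intermediates)."""


class ConvergenceError(NumericalError):
    """Inner or outer optimizer failed to reach its tolerance."""
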