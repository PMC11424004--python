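"""Exception hierarchy.

``ValidationError`` covers malformed inputs (exit code 1 from the CLI);
everything else derives from ``HmbfitError`` (exit code 2).
"""


class HmbfitError(Exception):
    """Base class for package errors."""


class ValidationError(HmbfitError, ValueError):
    """Input data violates a documented precondition."""


class FitFailureError(HmbfitError, RuntimeError):
    """Every optimizer start for a model variant was infeasible."""


class DegenerateFitError(HmbfitError, RuntimeError):
    """Operation undefined for a perfect (zero residual) fit."""


class UndefinedStatisticError(HmbfitError, ArithmeticError):
    """A statistic (R^2, contribution share) has no defined value here."""
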