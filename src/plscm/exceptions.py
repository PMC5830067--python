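"""Exception hierarchy for the plscm pipeline.

Errors are split into data-format problems (bad files), validation problems
(well-formed but scientifically invalid input), and numerical degeneracies
encountered during model fitting.
"""


class PLSCMError(Exception):
    """Base class for all plscm errors."""


class FormatError(PLSCMError):
    """A file or table violates the expected structural format."""


class ValidationError(PLSCMError):
    """Input values violate a domain invariant (named row/column in message)."""


class DegenerateDirectionError(PLSCMError):
    """A PLS component direction has zero norm (e.g. all-zero X block)."""


class ConvergenceError(PLSCMError):
    """A NIPALS component failed to converge within the iteration budget."""


class UndefinedVarianceError(PLSCMError):
    """A sum of squares needed for an explained-variance ratio is zero."""


class UndefinedVIPError(PLSCMError):
    """All per-component response sums of squares are zero; VIP undefined."""


class SelectionFailureError(PLSCMError):
    """Variable selection produced an empty set; threshold must change."""


class DegenerateDensityError(PLSCMError):
    """A class has zero variance in its calculated responses."""


class InsufficientDataError(PLSCMError):
    """Too few observations or variables for the requested statistic."""
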