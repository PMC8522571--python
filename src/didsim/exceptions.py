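"""Exception hierarchy for didsim."""


class DidSimError(Exception):
    """Base class for all didsim-specific errors."""


class StructuralConflictError(DidSimError, ValueError):
    """An override contradicts a scenario's structural constraints.

    Each canonical scenario fixes a qualitative structure (time-invariant vs
    time-varying covariate, constant vs time-varying effect, which group
    trajectories may diverge). Overrides may change magnitudes but not that
    structure.
    """


class DegenerateAssignmentError(DidSimError, RuntimeError):
    """Treatment assignment produced no treated or no control units after
    the allowed number of re-draws."""


class SingularDesignError(DidSimError, ValueError):
    """The regression design matrix is rank deficient."""


class MatchingError(DidSimError, ValueError):
    """Matching preconditions violated (e.g., no pretreatment periods,
    empty control group)."""


class UndefinedRelativeBiasError(DidSimError, ZeroDivisionError):
    """Percent bias is undefined for a zero true effect; use absolute bias."""


class StudyIntegrityError(DidSimError, RuntimeError):
    """Too many replicate-level estimator failures in a Monte Carlo study."""
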