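"""Exception hierarchy for trophnet.

Every stage raises a subclass of :class:`TrophnetError` so that the pipeline
can surface failures with stage context while callers can still catch the
specific condition.
"""


class TrophnetError(Exception):
    """Base class for all trophnet errors."""


# --- tracking IO -----------------------------------------------------------

class MissingColumnError(TrophnetError):
    """A required column is absent from an input table."""


class DuplicateDetectionError(TrophnetError):
    """The same ant appears more than once in a single frame."""


class NonFiniteCoordinateError(TrophnetError):
    """A detection has a NaN or infinite coordinate or angle."""


class InsufficientFramesError(TrophnetError):
    """Fewer than two distinct timestamps; no frame rate can be computed."""


# --- simulator -------------------------------------------------------------

class InfeasibleConfigError(TrophnetError):
    """The simulator cannot satisfy the requested separation constraints."""


# --- interaction inference -------------------------------------------------

class EmptyMeasurementsError(TrophnetError):
    """A trial has no manual distance measurements for threshold calibration."""


class UnknownAntError(TrophnetError):
    """An edge endpoint does not appear on the trial roster."""


class InconsistentRosterError(TrophnetError):
    """More network participants than tagged ants in the group."""


# --- measures --------------------------------------------------------------

class JoinMismatchError(TrophnetError):
    """Trial identifiers do not line up when assembling the measures table."""


# --- statistics ------------------------------------------------------------

class NonConvergenceError(TrophnetError):
    """A mixed-model fit failed to converge."""


class RankDeficientDesignError(TrophnetError):
    """The fixed-effect design matrix is rank deficient."""


class NonPositiveResponseError(TrophnetError):
    """Gamma family requires a strictly positive response."""


class SingularCovarianceError(TrophnetError):
    """Coefficient covariance is singular; Wald tests are undefined."""


class MissingFactorError(TrophnetError):
    """A factor requested for contrasts is not in the fitted model."""
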