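"""Exception hierarchy for milkmir.

All errors derive from :class:`MilkMirError` so callers can catch the
package's failures with a single except clause; the subclasses mirror the
distinct failure modes of the analysis contracts (bad arguments, degenerate
data, incompatible grids).
"""


class MilkMirError(Exception):
    """Base class for all milkmir errors."""


class InvalidArgumentError(MilkMirError, ValueError):
    """An argument violates an operation's precondition."""


class EmptySelectionError(MilkMirError):
    """A region selection retained no wavenumbers."""


class InsufficientDataError(MilkMirError):
    """Too few samples or points for the requested computation."""


class DegenerateSegmentError(MilkMirError):
    """A grid segment is too short for the requested transform."""


class DegenerateVariableError(MilkMirError):
    """One or more spectral variables have zero variance."""

    def __init__(self, columns, message=None):
        self.columns = list(columns)
        super().__init__(message or f"zero-variance columns at wavenumbers: {self.columns}")


class NormalizationError(MilkMirError):
    """A spectrum could not be vector normalized (zero norm)."""


class GridMismatchError(MilkMirError):
    """Spectra are not on the grid the model was fitted on."""


class NonEstimableError(MilkMirError):
    """A requested marginal mean is not estimable from the fitted design."""


class SingularDesignError(MilkMirError):
    """The design matrix is rank deficient beyond nesting-induced aliasing."""


class WrongPretreatmentError(MilkMirError):
    """An operation received spectra with an unsupported pretreatment tag."""


class EmptyWindowError(MilkMirError):
    """No cow had any sample inside the requested averaging window."""


class ConfigError(MilkMirError):
    """A trial or pipeline configuration is internally inconsistent."""
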