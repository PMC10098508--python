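"""Exception types shared across the package."""


class QdstedError(Exception):
    """Base class for package errors."""


class ParameterError(QdstedError, ValueError):
    """An argument is outside its physical or logical domain."""


class InputError(QdstedError, ValueError):
    """Inputs are structurally invalid (shape mismatch, empty stack, ...)."""


class InsufficientDataError(QdstedError, ValueError):
    """Too few data points for the requested fit or statistic."""


class FitError(QdstedError, RuntimeError):
    """A nonlinear fit failed to converge or hit its bounds."""


class PlacementError(QdstedError, RuntimeError):
    """Constructive placement of emitters/structures is infeasible."""


class DegenerateInputError(QdstedError, ValueError):
    """A quantity is undefined on this input (empty mask, zero prediction, ...)."""


class UndefinedSFPError(DegenerateInputError):
    """Single-fraction parameter undefined: no single emitters outside vesicles."""
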