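"""Exception types shared across the toolkit."""


class DicarnError(Exception):
    """Base class for all toolkit errors."""


class FormatError(DicarnError, ValueError):
    """Unknown or malformed file format / dialect."""


class ValidationError(DicarnError, ValueError):
    """Input violates a documented invariant (negative counts, bad intervals, ...)."""


class BoundsError(DicarnError, IndexError):
    """Index or tile extends beyond the matrix it refers to."""


class StateError(DicarnError, ValueError):
    """Operation applied to a matrix in the wrong normalization state."""


class ParameterError(DicarnError, ValueError):
    """Parameter outside its admissible range."""


class ShapeError(DicarnError, ValueError):
    """Operand shapes are incompatible."""


class ConvergenceError(DicarnError, RuntimeError):
    """Iterative balancing failed to reach tolerance; carries the residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


class DataError(DicarnError, ValueError):
    """Empty or degenerate data set where content is required."""


class DivergenceError(DicarnError, RuntimeError):
    """Non-finite loss during training; carries the epoch index."""

    def __init__(self, message: str, epoch: int):
        super().__init__(message)
        self.epoch = epoch


class UndefinedScoreError(DicarnError, ValueError):
    """Similarity score undefined for this input (all-zero map, degenerate strata)."""


class SplitError(DicarnError, ValueError):
    """Chromosome split lists overlap."""


class DependencyError(DicarnError, FileNotFoundError):
    """A pipeline stage's upstream artifact is missing; names the missing stage."""
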