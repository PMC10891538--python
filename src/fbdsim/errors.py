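"""Exception and warning types shared across the package.

Simulation-time errors carry enough context (bead/bond index, step number)
to diagnose a failing run, and errors raised mid-integration expose the
partial trajectory flushed up to the failure.
"""

from __future__ import annotations


class FbdError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(FbdError, ValueError):
    """A parameter is outside its mathematical or physical domain."""


class AlgorithmFailureError(FbdError, RuntimeError):
    """An exact sampling algorithm cannot proceed.

    Raised, e.g., when circulant embedding of the noise covariance produces
    genuinely negative eigenvalues and the recursive fallback is disabled.
    The generator never silently returns noise with the wrong covariance.
    """


class MemoryBudgetError(FbdError, MemoryError):
    """Pre-generating the full noise tensor would exceed the memory budget."""


class GeometryInfeasibleError(FbdError, RuntimeError):
    """The confinement cannot hold the requested polymer."""


class TooShortError(FbdError, ValueError):
    """A trajectory or series is too short for the requested estimator."""


class TrajectoryFormatError(FbdError, ValueError):
    """A trajectory file is malformed."""

    def __init__(self, message: str, frame: int | None = None,
                 line: int | None = None):
        if frame is not None:
            message = f"{message} (frame {frame})"
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.frame = frame
        self.line = line


class SimulationError(FbdError, RuntimeError):
    """Base for errors raised while integrating.

    ``partial_trajectory`` holds everything recorded before the failure
    (set by the integrator before re-raising), ``step`` the global step
    index at which the error occurred.
    """

    def __init__(self, message: str, step: int | None = None):
        if step is not None:
            message = f"{message} (step {step})"
        super().__init__(message)
        self.step = step
        self.partial_trajectory = None


class OverstretchError(SimulationError):
    """A finitely extensible bond reached its maximum extension."""

    def __init__(self, bond_index: int, step: int | None = None):
        super().__init__(f"FENE bond {bond_index} overstretched", step=step)
        self.bond_index = bond_index


class OverlapError(SimulationError):
    """Two beads collapsed onto each other below the hard-core floor."""

    def __init__(self, bead_index: int, step: int | None = None):
        super().__init__(f"hard-core overlap at bead {bead_index}", step=step)
        self.bead_index = bead_index


class EscapedBeadError(SimulationError):
    """A bead left the confinement volume."""

    def __init__(self, bead_index: int, step: int | None = None):
        super().__init__(f"bead {bead_index} escaped the confinement",
                         step=step)
        self.bead_index = bead_index


class NumericalBlowupError(SimulationError):
    """Positions became non-finite."""


class HurstRangeWarning(UserWarning):
    """Hurst parameter outside the well-tested practical range [0.35, 0.65]."""
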