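"""Named exceptions raised across the package."""


class BetaRollError(Exception):
    """Base class for all package errors."""


class InvalidResidueError(BetaRollError, ValueError):
    """A residue code outside the one-letter amino-acid alphabet."""


class GeometryError(BetaRollError, ValueError):
    """Geometry parameters that violate a structural constraint."""


class RestraintSelectionError(BetaRollError, ValueError):
    """A restraint selection that the topology cannot support."""


class OverlapError(BetaRollError, ValueError):
    """Two beads at (numerically) zero separation."""


class NonFiniteCoordinateError(BetaRollError, FloatingPointError):
    """Coordinates became NaN/inf during integration; carries the step index."""

    def __init__(self, step: int):
        self.step = step
        super().__init__(f"non-finite coordinates at integration step {step}")


class InvalidBoostParameterError(BetaRollError, ValueError):
    """Boost acceleration factor alpha must be positive."""


class ScheduleError(BetaRollError, ValueError):
    """A scripted-unfolding schedule inconsistent with the topology."""


class EmptyTrajectoryError(BetaRollError, ValueError):
    """An analysis operation received a trajectory with no frames."""


class DegenerateHistogramError(BetaRollError, ValueError):
    """All samples identical: no histogram support for a PMF."""


class NoPeakError(BetaRollError, ValueError):
    """A PMF profile with no local maximum beyond its global minimum."""


class FormatError(BetaRollError, ValueError):
    """A malformed record in an on-disk file; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
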