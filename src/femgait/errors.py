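"""Exception hierarchy for femgait.

The pipeline distinguishes user-facing parameter problems from data-level
problems (malformed files, degenerate geometry) so that the study driver can
record per-model failures without aborting the whole sweep.
"""


class FemgaitError(Exception):
    """Base class for all femgait errors."""


class ParameterError(FemgaitError):
    """An argument violates a documented precondition."""


class DataError(FemgaitError):
    """Input data is structurally valid but semantically unusable."""


class FormatError(DataError):
    """A motion or model file could not be parsed.

    Carries the 1-based line number where parsing failed when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class DegenerateGeometryError(DataError):
    """Landmark geometry does not define the requested axis or plane."""


class ConfigurationError(FemgaitError):
    """A study or deformation configuration is inconsistent."""


class SolverError(FemgaitError):
    """The static-optimization solver failed to converge on a frame."""

    def __init__(self, message: str, frame: int | None = None):
        self.frame = frame
        if frame is not None:
            message = f"{message} (frame {frame})"
        super().__init__(message)
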