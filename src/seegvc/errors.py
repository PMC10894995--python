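"""Exception types shared across the package."""


class SeegvcError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(SeegvcError):
    """Phantom geometry violates a precondition (e.g. non-nested radii)."""


class DegenerateShellError(InvalidGeometryError):
    """A requested tissue shell produced no voxels at the chosen resolution."""


class PlacementError(SeegvcError):
    """An electrode shaft could not be placed inside the head."""


class UnsupportedConfigurationError(SeegvcError):
    """Source/sensor configuration outside the analytic solver's domain."""


class SeriesConvergenceError(SeegvcError):
    """Legendre series did not reach the requested tolerance.

    Carries the running tail estimate in ``tail``.
    """

    def __init__(self, message: str, tail: float):
        super().__init__(message)
        self.tail = tail


class OutsideMeshError(SeegvcError):
    """A point required by an operation lies outside the mesh."""


class IncompatibleLoadError(SeegvcError):
    """FEM load vector violates the insulating-boundary compatibility condition."""


class ConvergenceError(SeegvcError):
    """Iterative linear solver exceeded its iteration cap.

    Carries the last relative residual in ``residual``.
    """

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual
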