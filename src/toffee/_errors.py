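"""Exception hierarchy shared across the package."""


class ToffeeError(Exception):
    """Base class for all package-specific errors."""


class IndexRangeError(ToffeeError, ValueError):
    """An integer m/z index lies outside the physical range of the transfer function."""


class UnderdeterminedError(ToffeeError, ValueError):
    """Too few m/z values to identify the intrinsic mass spacing of a scan."""


class EstimationError(ToffeeError):
    """No consistent integer lattice was found within the residual tolerance.

    Carries the worst parts-per-million residual achieved so callers can report
    how far from grid-consistent the input was.
    """

    def __init__(self, message: str, max_residual_ppm: float):
        super().__init__(message)
        self.max_residual_ppm = max_residual_ppm


class StorageOverflowError(ToffeeError, OverflowError):
    """A coordinate or intensity does not fit the unsigned 32-bit on-disk dtype."""


class CorruptFileError(ToffeeError):
    """A persisted file violates a structural invariant of the format."""


class FormatVersionError(CorruptFileError):
    """The file declares a major format version this library does not support."""


class LossyInputError(ToffeeError):
    """Input spectra cannot be placed on an integer lattice without loss."""

    def __init__(self, message: str, max_residual_ppm: float):
        super().__init__(message)
        self.max_residual_ppm = max_residual_ppm


class StructureError(ToffeeError, ValueError):
    """The acquisition cycle structure of the input is inconsistent."""


class WindowResolutionError(ToffeeError, ValueError):
    """A precursor m/z does not fall inside any MS2 isolation window."""


class DegenerateInputError(ToffeeError, ValueError):
    """Input carries no usable signal (e.g. an all-zero raster)."""


class FitFailureError(ToffeeError):
    """Peak-model optimisation did not converge; best parameters are attached."""

    def __init__(self, message: str, params=None, residual: float | None = None):
        super().__init__(message)
        self.params = params
        self.residual = residual
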