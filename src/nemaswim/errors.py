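"""Exception types raised across the pipeline."""


class NemaswimError(Exception):
    """Base class for all package errors."""


class ValidationError(NemaswimError, ValueError):
    """A parameter or input failed validation.

    Carries the offending field name so callers (and the CLI) can point at it.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class NoWormFound(NemaswimError):
    """Segmentation found no foreground component above the minimum area."""


class SelfOverlap(NemaswimError):
    """The body mask skeleton has no end-to-end path (closed loop / self-overlap)."""


class TrackFailure(NemaswimError):
    """Too many frames of a movie could not be tracked."""


class NoOscillation(NemaswimError):
    """No spectral peak above the noise floor in the curvature signal."""


class NormalizationUndefined(NemaswimError):
    """Head curvature is (numerically) zero; a head-normalized profile is undefined."""


class DomainError(NemaswimError, ValueError):
    """An argument is outside the mathematical domain of a formula."""


class OutOfFieldOfView(NemaswimError):
    """The worm leaves the rendered image; reports the first offending frame."""

    def __init__(self, frame: int, message: str = ""):
        self.frame = frame
        super().__init__(message or f"worm exits field of view at frame {frame}")


class CalibrationError(NemaswimError):
    """Force-balance calibration of the gait amplitude failed to bracket a root."""
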