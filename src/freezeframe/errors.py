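"""Exception types shared across the package."""


class FreezeframeError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FreezeframeError, ValueError):
    """Invalid argument or malformed input data."""


class VideoIOError(FreezeframeError, IOError):
    """A video file could not be read, decoded, or written."""


class CalibrationError(FreezeframeError):
    """Calibration cannot proceed (degenerate manual score, no usable fits...)."""


class CalibrationFileError(FreezeframeError, IOError):
    """A calibration file is missing, corrupt, or has an unsupported schema version."""
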