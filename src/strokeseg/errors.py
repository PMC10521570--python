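"""Exception types raised across the package."""


class StrokesegError(Exception):
    """Base class for all package-specific errors."""


class FormatError(StrokesegError):
    """A file on disk is not a readable volume/mask in the expected format."""


class ShapeError(StrokesegError):
    """Array arguments have incompatible or disallowed shapes."""


class ArchitectureError(StrokesegError):
    """A constructed layer deviates from the published layer schedule."""


class TrainingError(StrokesegError):
    """The optimisation loop hit a non-recoverable state (e.g. NaN loss)."""
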