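"""Exception hierarchy shared across the package."""


class LidmetricsError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(LidmetricsError, ValueError):
    """An input parameter violates its documented constraints."""


class MaskError(LidmetricsError, ValueError):
    """A binary mask is empty, malformed, or missing a required class."""


class MeasurementError(LidmetricsError, RuntimeError):
    """A geometric measurement could not be completed on the given masks."""


class SegmentationBackendError(LidmetricsError, RuntimeError):
    """A segmentation backend failed; carries the backend identity."""

    def __init__(self, backend: str, message: str):
        self.backend = backend
        super().__init__(f"[{backend}] {message}")


class SceneIOError(LidmetricsError, OSError):
    """A scene directory is missing or contains corrupt files."""
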