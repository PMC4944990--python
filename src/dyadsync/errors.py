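"""Exception hierarchy shared across the pipeline stages."""


class DyadSyncError(Exception):
    """Base class for all package errors."""


class ConfigurationError(DyadSyncError):
    """Invalid configuration (simulation or pipeline)."""


class InputError(DyadSyncError):
    """Malformed or inconsistent input data."""


class DetectionError(DyadSyncError):
    """R-peak detection failed (signal too short, flat, or unusable)."""


class LayoutError(DyadSyncError):
    """Classroom layout violates its invariants."""


class ParseError(InputError):
    """A file failed to parse; message names file, line and field."""
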