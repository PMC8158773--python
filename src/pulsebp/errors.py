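"""Exception hierarchy shared across the pipeline stages."""


class PulseBPError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PulseBPError):
    """A file could not be parsed into a valid recording or table."""


class NoSignalError(PulseBPError):
    """A channel carries no usable signal (flat, all-NaN, ...)."""


class InsufficientDataError(PulseBPError):
    """Too few beats / peaks / subjects for the requested operation."""


class RecordRejectedError(PulseBPError):
    """The whole record failed the quality gate or yielded too few beats."""


class FiducialFailureError(PulseBPError):
    """A beat has no detectable pulse-wave upstroke; it is demoted to rejected."""


class ConfigError(PulseBPError):
    """A pipeline configuration failed schema validation."""
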