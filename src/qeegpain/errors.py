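"""Labeled errors raised across the pipeline.

Every error carries a human-readable message naming the violated
precondition; stages re-raise with their stage name attached so a failed
run points at the offending step.
"""


class QeegPainError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(QeegPainError):
    """Invalid configuration value (rates, durations, bands, grids)."""


class LayoutError(QeegPainError):
    """Cohort layout cannot be arranged into valid subject pre/post pairs."""


class SessionError(QeegPainError):
    """A session violates its contract (too short, constant, bad NRS)."""


class NormalizationError(QeegPainError):
    """Signal cannot be z-scored (zero variance or too short)."""


class BandError(QeegPainError):
    """Filter band incompatible with the sampling rate."""


class SegmentationError(QeegPainError):
    """Signal duration is not an exact multiple of the window length."""


class CoverageError(QeegPainError):
    """Spectral estimate does not cover the required 0.5-35.5 Hz range."""


class StatsError(QeegPainError):
    """Undersized, empty, or degenerate samples passed to a test."""


class FoldError(QeegPainError):
    """Cross-validation fold layout is infeasible for the data."""


class LabelError(QeegPainError):
    """Missing or inconsistent labels for a session or window."""


class ParseError(QeegPainError):
    """Malformed input file; message includes record context."""


class UnsupportedFormatError(QeegPainError):
    """Requested file format not available in this build."""
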