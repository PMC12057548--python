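"""Exception hierarchy shared across the pipeline."""


class CrumbscanError(Exception):
    """Base class for all package errors."""


class ParameterError(CrumbscanError, ValueError):
    """An argument is outside its documented domain."""


class NoSeparationError(CrumbscanError):
    """Histogram has fewer than two occupied gray levels; no threshold exists."""


class NotBimodalError(CrumbscanError):
    """Intermodes smoothing failed to reach a two-mode histogram."""


class InsufficientScalesError(CrumbscanError):
    """Fewer than two usable (size, count) points for a fractal fit."""


class ProfileValidationError(CrumbscanError, ValueError):
    """A digestion profile violates 0 <= FG <= G20 <= G120 <= TG."""


class DegenerateProfileError(CrumbscanError):
    """Total starch is non-positive; fractions are undefined."""


class DegenerateColorError(CrumbscanError):
    """Browning-index denominator is zero for this CIELAB triplet."""
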