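"""Exception hierarchy for blotmap.

All package errors derive from :class:`BlotmapError` so callers can catch
everything with one clause; the subclasses distinguish bad parameters,
degenerate data, geometry problems and pipeline state.
"""


class BlotmapError(Exception):
    """Base class for all blotmap errors."""


class ParameterError(BlotmapError, ValueError):
    """An argument is outside its documented domain."""


class DegenerateInputError(BlotmapError, ValueError):
    """Input is syntactically valid but statistically unusable
    (constant vector, all-zero image, zero control mean, ...)."""


class ConfigurationError(BlotmapError, ValueError):
    """A study or pipeline configuration is internally inconsistent."""


class GeometryError(BlotmapError, ValueError):
    """An ROI or background box is out of bounds or overlapping."""


class FormatError(BlotmapError, ValueError):
    """An input file has the wrong pixel format (e.g. RGB where
    grayscale is required)."""


class ShapeMismatchError(FormatError):
    """Images in one stack do not share a common shape."""


class StateError(BlotmapError, RuntimeError):
    """An operation was called on a stack in the wrong state
    (e.g. correlation on an unaligned stack)."""


class AlignmentError(BlotmapError, RuntimeError):
    """Registration failed (flat reference image)."""


class RatioUndefinedError(DegenerateInputError):
    """FL:beta/gamma ratio requested with a zero denominator."""
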