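"""Exception hierarchy shared across the package."""


class WidecaError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(WidecaError, ValueError):
    """A parameter violates its documented range or invariant."""


class CalibrationError(WidecaError, RuntimeError):
    """A numeric calibration has no solution in the admissible region."""


class FormatError(WidecaError, ValueError):
    """A file does not conform to the expected on-disk format."""


class EmptyRoiError(WidecaError, ValueError):
    """An ROI rasterizes to zero pixels on the given grid."""


class DegenerateDataError(WidecaError, ValueError):
    """Input data admit no variance estimate (e.g. identical paired values)."""
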