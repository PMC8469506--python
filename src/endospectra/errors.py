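"""Exception hierarchy.

All package errors derive from :class:`EndoSpectraError` so callers (and the
CLI) can distinguish data problems from configuration problems.
"""


class EndoSpectraError(Exception):
    """Base class for all errors raised by this package."""


class DataError(EndoSpectraError):
    """Invalid or missing input data (exit code 1 in the CLI)."""


class ConfigurationError(EndoSpectraError):
    """Invalid configuration or parameters (exit code 2 in the CLI)."""


class RangeError(DataError):
    """A numeric value falls outside its documented range."""


class GridError(DataError):
    """Wavelength grids of two objects do not match."""


class DimensionError(DataError):
    """An array has the wrong shape or length."""


class BoxValidityError(DataError):
    """A bounding box is degenerate or has invalid coordinates."""


class LabelError(DataError):
    """An unknown stage label was encountered."""


class UndefinedMetricError(DataError):
    """A metric is undefined (zero denominator); never reported as 0."""
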