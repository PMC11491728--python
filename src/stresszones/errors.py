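"""Exception hierarchy for the stresszones pipeline.

``StressZonesError`` is the base for every error the library raises on
bad inputs, so callers (and the CLI) can distinguish user error from a
genuine bug.
"""


class StressZonesError(Exception):
    """Base class for all stresszones errors."""


class ConfigurationError(StressZonesError):
    """Invalid configuration values (extents, date ranges, sweeps...)."""


class FormatError(StressZonesError):
    """Malformed or inconsistent input files (grid mismatch, bad dates)."""


class SchemaError(StressZonesError):
    """A table is missing required columns."""


class GeoreferenceError(StressZonesError):
    """Coordinate systems or grids of two inputs do not line up."""


class DegenerateInputError(StressZonesError):
    """Input is valid but carries no usable signal (all-constant stack,
    fewer distinct values than requested classes, ...)."""


class InfeasibleConfigurationError(StressZonesError):
    """A requested simulation or domain restriction cannot be satisfied
    (positively weighted zone with no pixels, empty domain intersection)."""


class NoDataError(StressZonesError):
    """An analysis was requested on zero usable records."""


class UnresolvedOrientationError(StressZonesError):
    """The stress-index sign convention cannot be resolved automatically."""
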