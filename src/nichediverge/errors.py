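"""Exception hierarchy.

The CLI maps these onto exit codes: configuration problems (2), data
problems (3), numerical failures (4).
"""


class NicheDivergeError(Exception):
    """Base class for all package errors."""


class ConfigError(NicheDivergeError):
    """Invalid configuration value or inconsistent scenario/analysis setup."""


class DataError(NicheDivergeError):
    """Malformed or insufficient input data."""


class GridFormatError(DataError):
    """Unparseable ESRI ASCII grid header or body."""


class DimensionError(DataError):
    """Row/column count mismatch or incompatible grid geometry."""


class GeometryError(DimensionError):
    """Two grids that must share geometry and mask do not."""


class SamplingError(DataError):
    """A random draw cannot be satisfied (too few eligible cells/records)."""


class NumericalError(NicheDivergeError):
    """Optimization or linear-algebra failure."""


class FittingError(NumericalError):
    """Model fit did not converge, with diagnostics in the message."""


class DegenerateDataError(NumericalError):
    """Inputs make the requested statistic undefined (e.g. constant layer)."""
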