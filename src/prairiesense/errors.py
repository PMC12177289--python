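"""Exception hierarchy shared across the pipeline.

Errors are split so the CLI can map them onto distinct exit codes:
configuration problems, file-format problems, geometry problems, and
physically inadmissible values discovered during computation.
"""


class PrairieSenseError(Exception):
    """Base class for all package errors."""


class ConfigError(PrairieSenseError):
    """Invalid configuration or parameter values."""


class FormatError(PrairieSenseError):
    """Malformed input file (missing metadata, wrong dialect, bad units)."""


class GeometryError(PrairieSenseError):
    """Coordinates, extents or polygons that do not fit together."""


class PhysicsError(PrairieSenseError):
    """Physically inadmissible quantity (T <= 0, tau <= 0, emissivity <= 0...)."""


class DegeneracyError(PrairieSenseError):
    """Singular or rank-deficient system (collinear tarps, constant predictor...)."""


class DataError(PrairieSenseError):
    """Inconsistent tabular data (locations outside plots, unmapped species...)."""


class RangeError(PrairieSenseError):
    """Value outside the attainable/representable range of an operation."""
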