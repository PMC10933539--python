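"""Exception hierarchy for the TLS tree-carbon pipeline."""


class TlsCarbonError(Exception):
    """Base class for all package errors."""


class PointCloudParseError(TlsCarbonError):
    """A point-cloud file could not be parsed; message names the byte/line."""


class EmptyCloudError(TlsCarbonError):
    """A point cloud contained no points."""


class SchemaError(TlsCarbonError):
    """A tabular input is missing required columns or rows are invalid."""


class InsufficientPointsError(TlsCarbonError):
    """Too few points for a geometric fit.

    Carries ``count``, the number of points actually available.
    """

    def __init__(self, message: str, count: int):
        super().__init__(message)
        self.count = count


class InsufficientCoverageError(TlsCarbonError):
    """A cloud has too many empty vertical slices for volume estimation.

    Carries ``empty_slices``, the (z_low, z_high) intervals that held too
    few trunk points.
    """

    def __init__(self, message: str, empty_slices: list):
        super().__init__(message)
        self.empty_slices = empty_slices


class FitError(TlsCarbonError):
    """A geometric or statistical fit failed (degenerate input or non-convergence)."""


class DegenerateCrownError(TlsCarbonError):
    """Crown points are too few or coplanar for a 3-D hull."""


class ConfigError(TlsCarbonError):
    """An invalid configuration value, rejected before any computation runs."""
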