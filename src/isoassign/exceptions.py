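"""Exception hierarchy for isoassign."""


class IsoassignError(Exception):
    """Base class for all isoassign errors."""


class FormatError(IsoassignError):
    """A raster or table file is malformed or missing required metadata."""


class ConfigError(IsoassignError):
    """Invalid configuration (degenerate extent, k > n, unknown keys, ...)."""


class SamplingError(IsoassignError):
    """Site sampling could not satisfy its constraints."""


class SingularFitError(IsoassignError):
    """Regression design is singular (zero predictor variance, collinearity)."""


class WeightsError(IsoassignError):
    """Spatial weights cannot be built (e.g. duplicated coordinates)."""


class PropagationError(IsoassignError):
    """Variance propagation produced an invalid (negative) total."""


class AssignmentError(IsoassignError):
    """Posterior computation degenerate (no valid cells, all-zero posterior)."""


class LocationError(IsoassignError):
    """A queried site falls outside the grid extent."""


class PairingError(IsoassignError):
    """Two record/surface collections cannot be paired sample-by-sample."""
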