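"""Exception types raised across the pipeline."""


class MammoCADError(Exception):
    """Base class for all package errors."""


class FormatError(MammoCADError, ValueError):
    """Unsupported image format or bit depth."""


class SchemaError(MammoCADError, ValueError):
    """Inconsistent tabular schema (feature names, class sets)."""


class ParameterError(MammoCADError, ValueError):
    """Out-of-contract parameter value."""


class EmptyImageError(MammoCADError, ValueError):
    """Image contains no foreground above the working threshold."""


class GeometryError(MammoCADError, ValueError):
    """Requested geometry (e.g. a lesion) falls outside the valid region."""


class StratificationError(MammoCADError, ValueError):
    """A class is too small for the requested number of CV folds."""


class UndefinedMetricError(MammoCADError, ValueError):
    """Metric undefined for the given inputs (e.g. AUC on a single class)."""
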