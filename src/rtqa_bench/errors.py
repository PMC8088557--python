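"""Exception types shared across the package."""


class RTQAError(Exception):
    """Base class for all rtqa-bench errors."""


class GridMismatchError(RTQAError, ValueError):
    """Two volumes are not co-registered (shape, spacing or origin differ)."""


class EmptyStructureError(RTQAError, ValueError):
    """An operation required a non-empty structure mask."""


class UndefinedMetricError(RTQAError, ValueError):
    """A metric is undefined for the given inputs (e.g. Dice of two empty masks)."""


class GeometryError(RTQAError, ValueError):
    """Invalid spatial configuration (out-of-grid recipe, disjoint extents...)."""


class ConfigError(RTQAError, ValueError):
    """Invalid configuration value (rule file, metric spec, run config)."""


class SequencingError(RTQAError, RuntimeError):
    """Benchmark review order violated (dose submitted before volume approval)."""


class FormatError(RTQAError, ValueError):
    """On-disk data does not match the expected format (non-binary mask...)."""


class UnsupportedFeatureError(RTQAError, NotImplementedError):
    """Input uses a feature the reader deliberately does not support."""


class PairingError(RTQAError, ValueError):
    """First/final observations could not be paired by institution."""
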