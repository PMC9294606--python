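"""Exception hierarchy shared across the package."""


class StpkitError(Exception):
    """Base class for all package errors."""


class ParameterError(StpkitError, ValueError):
    """A numeric parameter is outside its valid domain."""


class ConfigurationError(StpkitError, ValueError):
    """Inconsistent or incomplete run configuration (e.g. missing seed)."""


class FormatError(StpkitError, ValueError):
    """A file does not conform to the declared trace/table format."""


class ShapeError(StpkitError, ValueError):
    """Array/sweep dimensions or sampling rates are incompatible."""


class BoundsError(StpkitError, ValueError):
    """A measurement window falls outside the recorded trace."""


class MeasurementError(StpkitError, ValueError):
    """A waveform does not support the requested measurement."""
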