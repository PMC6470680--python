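"""Exception hierarchy shared by all pipeline stages."""


class RaceWalkError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RaceWalkError):
    """Invalid generator, classifier, or run configuration."""


class ParameterError(ConfigurationError):
    """A numeric parameter is outside its valid range (e.g. cutoff >= Nyquist)."""


class InputError(RaceWalkError):
    """Malformed or inconsistent data passed to an operation."""


class FormatError(InputError):
    """A file on disk does not match the expected table schema."""


class DetectionError(RaceWalkError):
    """An event-detection stage found no usable signal."""


class InsufficientDataError(RaceWalkError):
    """Too few strides / labels to carry out the requested operation."""
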