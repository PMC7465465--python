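"""Exception hierarchy.

Argument-validation failures raise plain :class:`ValueError`; the classes
here mark problems with input *files*, pipeline *configuration*, or the
*data* itself, so a CLI can map them to distinct exit codes.
"""


class SidquantError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SidquantError):
    """An input file does not conform to the expected dialect."""


class ConfigurationError(SidquantError):
    """The pipeline configuration is inconsistent or incomplete."""


class DataError(SidquantError):
    """The data are well-formed but violate an integrity constraint."""


class MissingChannelError(DataError):
    """A required SIM channel is absent from a chromatogram."""


class InternalStandardError(DataError):
    """The internal standard produced no usable signal in a sample."""


class ExtrapolationError(DataError):
    """A requested threshold lies outside the measured range."""
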