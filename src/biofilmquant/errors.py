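"""Exception hierarchy.

Errors are grouped so the CLI can map them onto stable exit codes:
configuration/validation problems (exit 2), data/format problems (exit 3)
and numerical failures such as a degenerate Otsu histogram (exit 4).
"""


class BiofilmQuantError(Exception):
    """Base class for all package errors."""


class ConfigError(BiofilmQuantError):
    """Invalid parameter, option or configuration value."""


class ValidationError(BiofilmQuantError):
    """Inputs are structurally valid but mutually inconsistent."""


class EmptyInputError(ValidationError):
    """An operation that requires non-empty input received an empty one."""


class FormatError(BiofilmQuantError):
    """A file could not be parsed as the expected format."""


class MetadataError(FormatError):
    """Required metadata (e.g. voxel size) is missing and no override given."""


class NumericalError(BiofilmQuantError):
    """A numerical procedure failed on this input."""


class DegenerateHistogramError(NumericalError):
    """Automatic thresholding failed because the intensity histogram has a
    single bin (constant volume)."""
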