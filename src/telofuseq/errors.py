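"""Exception hierarchy shared by all pipeline stages.

Validation problems (bad configuration, malformed input files) raise
subclasses of :class:`ValidationError`, which the CLI maps to exit code 2;
everything else surfaces as exit code 1.
"""


class TelofuseqError(Exception):
    """Base class for all package errors."""


class ValidationError(TelofuseqError):
    """A problem the user can fix by correcting configuration or input."""


class ConfigurationError(ValidationError):
    """Invalid configuration value or combination."""


class InputError(ValidationError):
    """Invalid data handed to an operation (empty read, zero DNA input, ...)."""


class ParseError(ValidationError):
    """Malformed line in an input file; message carries the location."""


class DataError(TelofuseqError):
    """Internally inconsistent data (e.g. breakpoint telomere-distal of the
    telomere origin) detected at analysis time."""


class InfeasibleError(TelofuseqError):
    """A simulation request that cannot be satisfied (e.g. the exclusion mask
    covers every base)."""
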