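"""Exception hierarchy shared across the package."""


class EcgDenoiseError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(EcgDenoiseError, ValueError):
    """A configuration value or argument is outside its valid domain."""


class DegenerateInputError(EcgDenoiseError, ValueError):
    """Input is structurally valid but degenerate (e.g. all-zero signal)."""


class FormatError(EcgDenoiseError, ValueError):
    """A file could not be parsed; message carries line/field context."""
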