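"""Exception hierarchy."""


class PolybiasError(Exception):
    """Base class for all package errors."""


class FormatError(PolybiasError, ValueError):
    """Malformed or inconsistent input table."""


class ConfigurationError(PolybiasError, ValueError):
    """Invalid simulation or analysis configuration."""


class InputError(PolybiasError, ValueError):
    """Semantically invalid input values (negative expression etc.)."""
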