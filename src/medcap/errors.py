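"""Exception hierarchy."""


class MedcapError(Exception):
    """Base class for package errors."""


class ConfigurationError(MedcapError):
    """Invalid configuration (unknown optimizer, bad fractions, missing weights)."""


class ValidationError(MedcapError, ValueError):
    """Invalid data handed to an operation (empty input, out-of-range index)."""
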