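"""Exception types shared across the package."""


class DoubleWellError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(DoubleWellError, ValueError):
    """A numeric argument is non-finite or outside its admissible range."""


class ConfigurationError(DoubleWellError, ValueError):
    """A configuration object or file violates an invariant.

    The message names the offending key or field.
    """
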