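"""Exception types shared across the rating modules."""


class PomerateError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PomerateError):
    """A backend name, reference table, or config key is invalid."""


class DegenerateInputError(PomerateError):
    """An image contains no usable fruit pixels for the requested rating."""


class UndefinedScoreError(PomerateError):
    """A color score cannot be defined for this chromaticity (origin point
    or origin ray parallel to the reference line)."""
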