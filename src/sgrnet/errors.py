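"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: :class:`ValidationError` -> 2,
:class:`NumericalError` -> 3.
"""


class SgrnetError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SgrnetError, ValueError):
    """Invalid user input: bad values, missing columns/features, bad config."""


class DegenerateRangeError(ValidationError):
    """A feature range with max == min; a constant feature carries no signal."""


class NumericalError(SgrnetError, RuntimeError):
    """A numerical failure inside an otherwise valid computation."""


class ModelFileError(SgrnetError, ValueError):
    """A model file that cannot be parsed or has an unsupported version."""
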