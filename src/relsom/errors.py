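"""Structured exceptions raised across the package."""


class RelsomError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(RelsomError, ValueError):
    """An argument violates an operation's preconditions."""


class InvalidConfigError(RelsomError, ValueError):
    """A run/training configuration is inconsistent or out of range."""


class ShapeError(RelsomError, ValueError):
    """Array arguments have incompatible shapes."""


class DegenerateInputError(RelsomError, ValueError):
    """Input is degenerate for the requested operation (e.g. constant series)."""


class NotTrainedError(RelsomError, RuntimeError):
    """An operation requires a trained model/matrix but got an untrained one."""


class NotDecodableError(RelsomError, ValueError):
    """A population activity pattern carries no decodable evidence."""


class NumericFailureError(RelsomError, ArithmeticError):
    """A numeric routine produced non-finite values or failed to converge."""


class ModelFormatError(RelsomError, ValueError):
    """A serialized model file is malformed or has an unsupported version."""


class ParseError(RelsomError, ValueError):
    """A data file could not be parsed; the message names the offending row."""


class ExtrapolationWarning(UserWarning):
    """A query lies outside the learned input bounds by more than 10% of range."""
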