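"""Exception hierarchy shared across the package."""


class PhidynError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(PhidynError, ValueError):
    """An argument violates a documented precondition."""


class DivergenceError(PhidynError, ArithmeticError):
    """A simulated state became non-finite.

    Carries ``step``, the index of the first bad integration step.
    """

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class UnsupportedOperationError(PhidynError, NotImplementedError):
    """The operation is defined but not supported for these arguments."""


class ValidationError(PhidynError, ValueError):
    """A configuration or parameter set failed validation.

    ``key`` names the offending entry when known.
    """

    def __init__(self, message: str, key: str | None = None):
        super().__init__(message)
        self.key = key


class CorruptionError(PhidynError, RuntimeError):
    """A results bundle failed its integrity check on load."""
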