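"""Exception types shared across the package.

The CLI maps these onto exit codes: configuration problems exit with 2,
numerical failures with 3 (see :mod:`spindlesim.cli`).
"""


class SpindleSimError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SpindleSimError, ValueError):
    """A configuration value is missing, unknown, or out of range."""


class NumericalInstabilityError(SpindleSimError, ArithmeticError):
    """A state variable became non-finite during integration."""


class CalibrationError(SpindleSimError, RuntimeError):
    """The measured f-I curve could not be inverted into a rate->current map."""


class ParseError(SpindleSimError, ValueError):
    """A delimited text file could not be parsed.

    Carries the offending line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
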