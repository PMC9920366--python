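"""Exception hierarchy shared by all maizephase modules."""


class MaizephaseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MaizephaseError, ValueError):
    """Invalid configuration value; the message names the offending field."""


class InputError(MaizephaseError, ValueError):
    """Invalid runtime input to an operation (e.g. out-of-range argument)."""


class WeatherFormatError(MaizephaseError, ValueError):
    """Malformed weather file; carries the 1-based file line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class SequencingError(MaizephaseError, RuntimeError):
    """Daily records fed to the simulator out of order or with gaps."""
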