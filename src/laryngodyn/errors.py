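"""Exception hierarchy for laryngodyn."""


class LaryngodynError(Exception):
    """Base class for all laryngodyn-specific errors."""


class ConfigError(LaryngodynError):
    """Invalid configuration value or unusable stage configuration."""


class UnusableSeriesError(LaryngodynError):
    """A phonation series cannot be analysed (e.g. no vocalizing frames)."""


class CsvFormatError(LaryngodynError):
    """Malformed input table. ``line`` is the 1-based file line when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
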