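"""Exception hierarchy shared across the package."""


class RecsoiError(Exception):
    """Base class for all package errors."""


class CorpusParseError(RecsoiError):
    """A JSONL line could not be parsed; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


class IntegrityError(RecsoiError):
    """A referential-integrity invariant of the corpus is violated."""


class ColdStartError(RecsoiError):
    """An author has no prior abstracts to build a profile from."""


class ConfigurationError(RecsoiError):
    """A configuration value is missing, unknown or inconsistent."""


class TrainingError(RecsoiError):
    """A model cannot be fitted on the provided data."""
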