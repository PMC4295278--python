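"""Exception hierarchy.

``InputError`` covers everything wrong with user-supplied files or
parameters (CLI exit code 2); ``StageError`` wraps failures inside a
pipeline stage (exit code 3).
"""


class CoexpairError(Exception):
    """Base class for all package errors."""


class InputError(CoexpairError):
    """Malformed or inconsistent user input (file contents, parameters)."""


class StageError(CoexpairError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")


class UndefinedCorrelationError(CoexpairError):
    """Correlation is undefined (zero variance in an input vector)."""
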