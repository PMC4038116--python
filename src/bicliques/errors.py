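"""Exception hierarchy.

``ParseError`` and ``InputError`` signal problems with user-supplied data
(CLI exit code 1); ``ContractError`` signals a violated internal contract
such as calling an operation outside its precondition (CLI exit code 2).
"""


class BicliqueError(Exception):
    """Base class for all package errors."""


class ParseError(BicliqueError):
    """Malformed textual input (edge lists, score matrices, biclique files)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class InputError(BicliqueError):
    """Structurally valid input that violates an operation's precondition."""


class ContractError(BicliqueError):
    """An internal contract was violated (caller bug, not data problem)."""
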