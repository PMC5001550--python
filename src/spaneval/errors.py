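"""Exception hierarchy."""


class SpanEvalError(Exception):
    """Base class for all package errors."""


class InvariantError(SpanEvalError):
    """A domain-type invariant was violated (overlap, bad span, bad class...)."""


class FormatError(SpanEvalError):
    """A file does not conform to the expected TSV dialect."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += str(path)
        if line is not None:
            prefix += f":{line}"
        super().__init__(f"{prefix}: {message}" if prefix else message)


class ScopeError(SpanEvalError):
    """An operation was asked for on an empty or incompatible scope."""
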