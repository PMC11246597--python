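"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError (and its
ParseError subclass) -> 3.
"""


class CnvMethError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(CnvMethError):
    """A configuration field is missing, malformed, or out of range."""


class DataError(CnvMethError):
    """Input data violate a contract (negative counts, missing samples...)."""


class ParseError(DataError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            if line is not None:
                loc += f":{line}"
            loc += "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line
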