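"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: validation/config problems exit 2,
I/O problems exit 3.
"""


class FixiscanError(Exception):
    """Base class for all pipeline errors."""


class ParseError(FixiscanError):
    """A file could not be parsed; carries the offending path/line."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class ValidationError(FixiscanError):
    """Input parsed but violates a contract (duplicate ids, missing ranks...)."""


class ConfigError(FixiscanError):
    """A configuration is internally inconsistent or infeasible."""
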