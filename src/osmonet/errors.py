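"""Exception hierarchy shared across the pipeline stages."""


class OsmonetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OsmonetError, ValueError):
    """Invalid parameter set (bad weights, probabilities outside [0,1], ...)."""


class DataError(OsmonetError, ValueError):
    """Input table violates a documented invariant (e.g. gene in two operons)."""


class DimensionError(OsmonetError, ValueError):
    """Mismatched vector lengths (profile vs genome panel)."""


class ParseError(OsmonetError, ValueError):
    """Malformed input row; message names the file and line."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(message + loc)
        self.path = path
        self.line = line
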