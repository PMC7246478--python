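"""Exception hierarchy shared across the pipeline."""


class NoisecrossError(Exception):
    """Base class for all package errors."""


class ParseError(NoisecrossError):
    """Malformed input file; message carries the file and line/row number."""


class OutOfExtentError(NoisecrossError):
    """Receiver point lies outside the footprint grid extent."""


class InvalidGridError(NoisecrossError):
    """Grid does not satisfy its structural invariants."""


class MissingFootprintError(NoisecrossError, KeyError):
    """No footprint (even after fallback) for a requested key."""

    def __init__(self, message: str, key=None, flight_id: str | None = None):
        super().__init__(message)
        self.key = key
        self.flight_id = flight_id

    def __str__(self) -> str:  # KeyError quotes its arg; keep a plain message
        return self.args[0]
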