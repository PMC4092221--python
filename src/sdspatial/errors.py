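"""Exception types shared across the package."""


class SdspatialError(Exception):
    """Base class for package errors."""


class ParseError(SdspatialError):
    """A text input file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class IntegrityError(SdspatialError):
    """Input violates an integrity contract (e.g. duplicate unordered bin pair)."""


class PlacementError(SdspatialError):
    """Random interval placement failed: requested features exceed capacity."""


class BreakpointSpanningError(SdspatialError):
    """An interval straddles an inversion breakpoint and cannot be remapped whole."""
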