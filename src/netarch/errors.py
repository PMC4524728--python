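"""Exception types shared across the package."""


class NetarchError(Exception):
    """Base class for all package-specific errors."""


class EdgeListParseError(NetarchError):
    """A line of an edge-list file could not be parsed; carries the line number."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


class UndefinedMetricError(NetarchError):
    """A metric is mathematically undefined for the given input
    (e.g. average path length of a graph with no connected pair)."""


class PowerLawFitError(NetarchError):
    """Degree sequence is degenerate or too small for a power-law fit."""
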