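"""Exception hierarchy shared across the toolkit."""


class SprmapError(Exception):
    """Base class for all package errors."""


class AlphabetError(SprmapError, ValueError):
    """A sequence contains a character outside the permitted alphabet.

    Carries the offending symbol and its 1-based position.
    """

    def __init__(self, symbol: str, position: int, context: str = "sequence"):
        self.symbol = symbol
        self.position = position
        super().__init__(
            f"invalid character {symbol!r} at position {position} in {context}"
        )


class ParameterError(SprmapError, ValueError):
    """An operation was called with out-of-range or inconsistent parameters."""


class DesignError(SprmapError, ValueError):
    """An oligomer design constraint was violated (overhangs, truncation floor...)."""


class PhaseError(SprmapError, ValueError):
    """A sensorgram phase window is missing, mis-ordered, or a report time
    falls outside the sampled trace."""


class FitError(SprmapError, RuntimeError):
    """Nonlinear fit failed to converge or landed on a parameter bound."""


class FeatureParseError(SprmapError, ValueError):
    """A BED/GFF3 feature line could not be parsed; carries the line number."""

    def __init__(self, path: str, lineno: int, message: str):
        self.path = path
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")
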