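"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes (config 2, format 3, empty result 4);
library users catch :class:`NauticaError` to handle any package failure.
"""


class NauticaError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(NauticaError):
    """Invalid configuration (bad thresholds, grids, simulation parameters)."""


class FormatError(NauticaError):
    """A file does not conform to its declared dialect (missing columns,
    unparseable values, conflicting duplicate rows)."""


class EmptyResultError(NauticaError):
    """An operation produced an empty result where a non-empty one is
    required (e.g. an edge list with no surviving rows after filtering)."""


class SymbolNotFoundError(NauticaError, KeyError):
    """A protein symbol was looked up in a network that does not contain it."""

    def __init__(self, symbol: str):
        super().__init__(symbol)
        self.symbol = symbol

    def __str__(self) -> str:  # KeyError quotes its arg; keep a plain message
        return f"unknown protein symbol: {self.symbol!r}"
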