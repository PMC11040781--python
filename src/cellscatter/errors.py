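"""Exception hierarchy shared across the package."""

__all__ = [
    "CellScatterError",
    "ValidationError",
    "ParseError",
    "StateError",
    "FitError",
    "NoPeakError",
    "DomainError",
]


class CellScatterError(Exception):
    """Base class for all package errors."""


class ValidationError(CellScatterError, ValueError):
    """Invalid input data or configuration."""


class ParseError(CellScatterError, ValueError):
    """Malformed input file."""


class StateError(CellScatterError, RuntimeError):
    """Operation applied in an invalid order (e.g. double normalization)."""


class FitError(CellScatterError, RuntimeError):
    """Nonlinear fit failed to converge or was handed degenerate data."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class NoPeakError(FitError):
    """No interior maximum found where a peak fit was requested."""


class DomainError(CellScatterError, ValueError):
    """Argument outside the mathematical domain of a formula."""
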