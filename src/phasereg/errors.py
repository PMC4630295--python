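"""Exception taxonomy shared across the package."""


class PhaseregError(Exception):
    """Base class for all phasereg errors."""


class DegenerateVarianceError(PhaseregError):
    """A series (or condition subset) has zero variance where variance is required."""


class InsufficientDataError(PhaseregError):
    """Too few samples for the requested operation."""


class DomainError(PhaseregError):
    """A parameter is outside its valid domain (e.g. negative expected fSNR)."""


class ConfigurationError(PhaseregError):
    """Invalid configuration (unknown method tag, bad kernel size, ...)."""


class DataError(PhaseregError):
    """Malformed or mismatched input data (shapes, affines, phase conventions)."""


class ComplexRootError(PhaseregError):
    """The PR quadratic has no real root; carries the coefficients as diagnostics."""

    def __init__(self, message: str, A: float, B: float, C: float):
        super().__init__(message)
        self.A, self.B, self.C = A, B, C
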