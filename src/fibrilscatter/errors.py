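"""Exception hierarchy shared across the package."""


class FibrilScatterError(Exception):
    """Base class for all package errors."""


class ProfileFormatError(FibrilScatterError):
    """A text profile file violates the two-column / CSV-grid contract."""


class ConfigurationError(FibrilScatterError):
    """Inconsistent or incomplete parameters for a generator or analysis."""


class FitError(FibrilScatterError):
    """A nonlinear fit failed to converge after bounded restarts."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class InversionError(FibrilScatterError):
    """A lattice-parameter inversion has no real solution."""


class UnsupportedGeometryError(FibrilScatterError):
    """Absorption geometry outside the modelled cuboid faces."""
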