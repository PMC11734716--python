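"""Exception types shared across the package."""


class ThermowireError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(ThermowireError, ValueError):
    """An argument is non-finite, complex, or outside its admissible range."""


class InvalidDatasetError(ThermowireError, ValueError):
    """A dataset violates a structural precondition (missing reference group, <2 temperatures, ...)."""


class FitError(ThermowireError, RuntimeError):
    """A model fit failed to converge or the design is singular/degenerate."""


class ClusteringError(ThermowireError, RuntimeError):
    """Coordinate clustering cannot proceed (degenerate geometry, too few distinct points)."""


class NumericalError(ThermowireError, RuntimeError):
    """A numerical routine (ODE solver, quadrature) failed; message carries diagnostics."""
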