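"""Exception types shared across the package."""


class OligopathError(Exception):
    """Base class for all package-specific errors."""


class FitError(OligopathError):
    """A nonlinear least-squares fit failed.

    Carries a ``diagnostics`` dict (initial guess, bounds, optimizer message)
    so callers can report why the fit did not converge.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class PeakFitError(FitError):
    """Gaussian peak fit failed (flat region, non-convergence, bad region)."""


class DecayFitError(FitError):
    """Near-Lorentzian decay fit failed (no decay information, bounds hit)."""


class MissingAtomsError(OligopathError):
    """A geometric analysis could not find required named atoms."""

    def __init__(self, message: str, missing: list | None = None):
        super().__init__(message)
        self.missing = missing or []


class CoverageError(OligopathError):
    """A spectrum does not cover the requested ppm range."""
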