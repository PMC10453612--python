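"""Exception hierarchy shared across the pipeline stages."""


class RescueKitError(Exception):
    """Base class for all package errors."""


class ParameterError(RescueKitError, ValueError):
    """A supplied parameter violates its documented domain."""


class InsufficientDataError(RescueKitError, ValueError):
    """Too few usable observations to run the requested estimator."""


class UnfittableError(RescueKitError, RuntimeError):
    """The data admit no finite fit (e.g. a flat dose-effect line)."""


class DegenerateControlError(RescueKitError, ValueError):
    """Control wells did not grow past the background count."""


class GenerationError(RescueKitError, RuntimeError):
    """A synthetic-data generator could not satisfy its constraints."""


class IneligiblePathwayError(RescueKitError, ValueError):
    """Pathway has fewer scored members than the eligibility minimum."""


class FitConvergenceError(RescueKitError, RuntimeError):
    """Iterative fit failed to converge; diagnostics attached."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
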