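"""Exception hierarchy for pulsebench.

All library errors derive from :class:`PulsebenchError` so callers can catch
one base class; the subclasses distinguish configuration problems, solver
failures, and signal-analysis failures (the latter are routinely caught and
logged as per-subject exclusions by the case-study drivers).
"""


class PulsebenchError(Exception):
    """Base class for all pulsebench errors."""


class ConfigError(PulsebenchError):
    """Invalid or inconsistent configuration (ranges, numerics, cohort)."""


class StructuralError(PulsebenchError):
    """Invalid network topology (cycle, orphan leaf, duplicate daughter...)."""


class DomainError(PulsebenchError):
    """Physically meaningless input (non-positive area, speed, density...)."""


class ConvergenceError(PulsebenchError):
    """Solver failed to reach a periodic state within the cycle budget."""

    def __init__(self, message: str, residual_mmhg: float | None = None):
        super().__init__(message)
        self.residual_mmhg = residual_mmhg


class StabilityError(PulsebenchError):
    """Numerical blow-up (negative area); suggests a smaller time step."""


class FormatError(PulsebenchError):
    """Waveform file does not follow the documented dialect."""


class DetectionError(PulsebenchError):
    """A waveform feature (foot, systolic shoulder) could not be located."""


class EstimationError(PulsebenchError):
    """A PWV estimator could not produce a valid positive wave speed."""


class ReconstructionError(PulsebenchError):
    """Central-pressure reconstruction could not satisfy its constraints."""

    def __init__(self, message: str, map_residual_mmhg: float | None = None):
        super().__init__(message)
        self.map_residual_mmhg = map_residual_mmhg


class ReportError(PulsebenchError):
    """Summary/reporting requested on empty results."""
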