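"""Exception hierarchy for camfret.

All package errors derive from :class:`CamfretError` so callers can catch one
base class at pipeline boundaries.
"""


class CamfretError(Exception):
    """Base class for all camfret errors."""


class DegenerateEndpointsError(CamfretError):
    """Normalization endpoints coincide (r_max == r_min or f_max <= f_min)."""


class OutOfRangeError(CamfretError):
    """A value lies outside its physical range by more than the clamp tolerance."""


class ScheduleError(CamfretError):
    """A titration schedule is physically inconsistent (negative volumes, overflow)."""


class ParameterError(CamfretError):
    """A model parameter violates its constraint (e.g. kd <= 0)."""


class SaturationError(CamfretError):
    """Indicator fluorescence at or beyond its Ca2+-saturated intensity; free
    Ca2+ is not computable."""


class FitFailureError(CamfretError):
    """No optimizer start converged; carries per-start diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class ConfigurationError(CamfretError):
    """Invalid or incomplete configuration (missing channel, bad schema...)."""


class SolverError(CamfretError):
    """Root-finding for the free-Ca2+ balance failed to converge."""
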