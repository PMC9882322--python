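"""Exception types shared across the analysis stages."""


class NucleoquantError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(NucleoquantError, ValueError):
    """A numeric parameter violates its documented precondition."""


class PlacementError(NucleoquantError):
    """Requested particle placement cannot be satisfied on the chain."""


class RenderError(NucleoquantError):
    """A simulated object does not fit inside the image extent."""


class BackgroundEstimationError(NucleoquantError):
    """Too few pixels qualify as background for a robust estimate."""


class PathError(NucleoquantError, ValueError):
    """A pixel path is not 8-connected and ordered."""


class FitError(NucleoquantError):
    """Nonlinear fit failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class C50UndefinedError(NucleoquantError):
    """The 50%-bound level is never bracketed by the titration.

    ``max_fraction`` records the highest fraction bound attained, which is
    what gets reported for unsaturated titrations.
    """

    def __init__(self, message: str, max_fraction: float):
        super().__init__(message)
        self.max_fraction = max_fraction


class ConfigError(NucleoquantError):
    """A run configuration fails schema validation."""
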