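"""Exception hierarchy."""


class VocalFemError(Exception):
    """Base class for all package errors."""


class GeometryError(VocalFemError):
    """Degenerate or inconsistent layer polygons."""


class ResolutionError(VocalFemError):
    """Mesh resolution too coarse for the requested layer structure."""


class ChannelExtractionError(VocalFemError):
    """The fluid-loaded surface is not single-valued in z (mesh fold-over)."""


class AssemblyError(VocalFemError):
    """Finite-element assembly failed (non-conforming mesh, bad material)."""


class PrecompressionError(VocalFemError):
    """Static medial-compression solve did not converge."""


class IntegrationError(VocalFemError):
    """Time integration failed (singular effective operator)."""


class ShootingError(VocalFemError):
    """Viscous-flow shooting solve could not bracket or locate the flow rate."""


class SimulationBlowupError(VocalFemError):
    """Coupled simulation diverged (NaN/overflow in the displacement field)."""

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class AlignmentError(VocalFemError):
    """Simulated and observed series cannot be placed on a common grid."""


class DegeneratePosteriorError(VocalFemError):
    """All importance weights are zero; widen the priors or the noise level."""


class ConfigurationError(VocalFemError):
    """Malformed prior/configuration descriptor."""
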