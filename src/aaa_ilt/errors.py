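"""Exception hierarchy for the AAA/ILT analysis package."""


class AaaIltError(Exception):
    """Base class for all package-specific errors."""


class ContainmentError(AaaIltError):
    """Lumen (offset + radius) does not fit strictly inside the cavity."""


class GeometryError(AaaIltError):
    """Inconsistent radii or other invalid geometric parameters."""


class MeshQualityError(AaaIltError):
    """Generated mesh violates the configured quality floor."""


class DegenerateProbeError(AaaIltError):
    """A probe cutting line fails to intersect a target boundary twice."""


class SingularSystemError(AaaIltError):
    """Assembled system is singular (rigid-body modes unconstrained)."""


class NonConvergence(AaaIltError):
    """Newton iteration failed; carries the last converged load fraction."""

    def __init__(self, message: str, last_converged_fraction: float = 0.0):
        super().__init__(message)
        self.last_converged_fraction = last_converged_fraction


class BaselineDivergedError(AaaIltError):
    """Threshold search aborted: even the baseline modulus fails to converge."""


class InsufficientDataError(AaaIltError):
    """Too few converged sweep records to evaluate the requested summary."""


class UnknownClassError(AaaIltError):
    """Voxel class label outside the declared segmentation class set."""


class EmptyCavityError(AaaIltError):
    """Label volume or slice contains no lumen+thrombus voxels."""


class LengthMismatchError(AaaIltError):
    """Paired samples have different lengths."""


class DegenerateError(AaaIltError):
    """A statistic is undefined (e.g. a constant variable in rank correlation)."""


class MissingDensityError(AaaIltError):
    """Density channel requested but absent from the label volume."""


class DegenerateContourError(AaaIltError):
    """Boundary track contour is degenerate (self-intersecting or collapsed)."""


class InterpolationError(AaaIltError):
    """Requested interpolation point lies outside the mesh."""


class ResolutionError(AaaIltError):
    """Voxel spacing too coarse to resolve the requested structure."""


class ConfigError(AaaIltError):
    """Run configuration failed validation."""
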