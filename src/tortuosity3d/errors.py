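"""Exception hierarchy for the tortuosity pipeline.

Every failure mode has a dedicated class so that batch orchestration can map
exceptions to stable error codes in the output CSV instead of aborting.
"""


class TortuosityError(Exception):
    """Base class for all pipeline errors."""

    #: short machine-readable code written to the CSV ``warnings``/error column
    code = "error"


class InvalidSpecError(TortuosityError, ValueError):
    """A phantom or fit specification violates its invariants."""

    code = "invalid_spec"


class VoxelizationError(TortuosityError):
    """Curve could not be rasterized into a connected binary tube."""

    code = "voxelization_failed"


class EmptyStructureError(TortuosityError):
    """The requested label/mask contains no foreground voxels."""

    code = "label_not_found"


class MultiComponentError(TortuosityError):
    """Foreground splits into several 26-connected components.

    Carries ``component_sizes`` (descending voxel counts) so callers can
    decide whether the largest-component fallback is sensible.
    """

    code = "multi_component"

    def __init__(self, message, component_sizes=()):
        super().__init__(message)
        self.component_sizes = tuple(component_sizes)


class LoopTopologyError(TortuosityError):
    """Skeleton has no endpoints: a closed loop, which has no open path."""

    code = "loop_topology"


class DegenerateStructureError(TortuosityError):
    """Skeleton too small to define a path (e.g. a single isolated voxel)."""

    code = "degenerate_structure"


class DisconnectionError(TortuosityError):
    """Requested start/end voxels are not connected on the skeleton graph."""

    code = "disconnected"


class InsufficientPointsError(TortuosityError, ValueError):
    """Fewer than the 4 distinct points a cubic spline needs."""

    code = "insufficient_points"


class DegenerateChordError(TortuosityError):
    """Curve endpoints (nearly) coincide, so arc/chord is undefined."""

    code = "degenerate_chord"
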