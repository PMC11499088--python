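"""Exception hierarchy for morphodetail."""


class MorphoDetailError(Exception):
    """Base class for all morphodetail errors."""


class InvalidSpecError(MorphoDetailError, ValueError):
    """An anatomy or cohort specification violates its invariants."""


class InvalidMeshError(MorphoDetailError, ValueError):
    """A mesh does not satisfy the preconditions of an operation
    (open surface, inconsistent orientation, non-positive volume, ...)."""


class FormatError(MorphoDetailError, IOError):
    """A mesh file could not be read or is degenerate."""


class InsufficientPointsError(MorphoDetailError, ValueError):
    """A point cloud is too small for the requested reduction."""


class ReconstructionError(MorphoDetailError, RuntimeError):
    """Surface reconstruction produced an empty or non-watertight result."""


class CorrespondenceError(MorphoDetailError, RuntimeError):
    """Particle correspondence failed (particle left the surface, or
    particle counts disagree across shapes)."""


class UndefinedCorrelationError(MorphoDetailError, ValueError):
    """Correlation distance is undefined for constant vectors."""


class DegenerateShapeWarning(UserWarning):
    """Emitted when a shape is too symmetric for moment-based alignment."""
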