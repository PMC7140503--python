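"""Exception hierarchy for the remodel3d pipeline."""


class Remodel3DError(Exception):
    """Base class for all pipeline errors."""


class DimensionalityError(Remodel3DError):
    """Image is not a 3D scalar volume."""


class GeometryError(Remodel3DError):
    """Incompatible grids, spacings, or physical extents."""


class TransformError(Remodel3DError):
    """Invalid rigid transform (non-orthonormal or reflecting rotation)."""


class ParameterError(Remodel3DError):
    """Invalid parameter value (thresholds, overlap fractions, ...)."""


class DegenerateInputError(Remodel3DError):
    """Input lacks the structure an operation needs (e.g. empty foreground)."""


class StitchingError(Remodel3DError):
    """Multi-stack alignment failed; the message names the offending stack."""


class ValidationError(Remodel3DError):
    """Malformed manifest or scan record."""
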