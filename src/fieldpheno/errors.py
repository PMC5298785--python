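"""Exception hierarchy for the fieldpheno pipeline."""


class FieldPhenoError(Exception):
    """Base class for all fieldpheno errors."""


class BehindCameraError(FieldPhenoError):
    """A 3D point lies at or behind the camera's optical center (z <= 0)."""


class InversionError(FieldPhenoError):
    """Iterative distortion inversion did not converge."""


class DegenerateGeometryError(FieldPhenoError):
    """Viewing rays are (near-)parallel or a fit is rank deficient."""


class InsufficientViewsError(FieldPhenoError):
    """Fewer calibration views than the method requires."""


class NoOverlapError(FieldPhenoError):
    """No shared observations between two cameras or series."""


class NoCorrespondencesError(FieldPhenoError):
    """Empty list where at least one matched pair is required."""


class EmptyInputError(FieldPhenoError):
    """An operation received an empty cloud, grid or series."""


class NoPlaneError(FieldPhenoError):
    """No dominant plane found in a point cloud."""


class NoPlantError(FieldPhenoError):
    """No points above the ground plane."""


class InvalidParameterError(FieldPhenoError):
    """A parameter violates its documented domain."""


class SaturatedCanopyError(FieldPhenoError):
    """Gap fraction of zero: the gap-fraction LAI estimator diverges."""


class ParseError(FieldPhenoError):
    """A file does not conform to its documented format."""
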