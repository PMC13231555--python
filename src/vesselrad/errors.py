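"""Exception hierarchy for vesselrad."""


class VesselradError(Exception):
    """Base class for all vesselrad errors."""


class MaskFormatError(VesselradError):
    """File could not be read/written in the requested volume format."""


class DimensionalityError(VesselradError):
    """Volume is not three-dimensional."""


class LabelError(VesselradError):
    """Mask contains a label outside the 0/1/2 convention."""


class GeometryError(VesselradError):
    """Phantom or ROI geometry is inconsistent with the target grid."""


class SchemaError(VesselradError):
    """Tabular input is missing required columns or measurements."""


class ValidationError(VesselradError):
    """A value violates its domain constraints (e.g. nonpositive height)."""


class PropagationError(VesselradError):
    """Radius propagation cannot proceed (e.g. empty centerline)."""


class EstimationError(VesselradError):
    """Statistical model cannot be estimated (e.g. rank-deficient design)."""
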