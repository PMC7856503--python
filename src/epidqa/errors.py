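"""Exception hierarchy for portal-image QA analysis."""


class EpidQAError(Exception):
    """Base class for all package errors."""


class FormatError(EpidQAError):
    """An input file does not meet the expected image format contract."""


class GeometryError(EpidQAError):
    """A requested region (profile band, ROI) falls outside the image grid."""


class DetectionError(EpidQAError):
    """Field-edge detection failed (no usable penumbra on one or both sides)."""


class NumericError(EpidQAError):
    """A metric is undefined for the given values (e.g. non-positive Dcenter)."""


class InputError(EpidQAError):
    """Invalid arguments to an analysis operation (too few points, mismatch...)."""


class ConsistencyError(EpidQAError):
    """Paired acquisitions disagree beyond plausibility (e.g. open vs wedge field size)."""
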