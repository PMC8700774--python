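"""Exception hierarchy for the visqc pipeline."""


class VisQCError(Exception):
    """Base class for all visqc errors."""


class LayoutError(VisQCError):
    """Scene layout is geometrically invalid (overlapping or out-of-frame regions)."""


class ReferenceNotFoundError(VisQCError):
    """No usable white/black reference patch could be located in the image."""


class DegenerateReferencesError(VisQCError):
    """White reference is not brighter than the black reference in some channel."""


class ROINotFoundError(VisQCError):
    """No cluster matching the sample appearance passed the area/hue criteria."""


class DegenerateClusteringError(VisQCError):
    """Image has fewer distinct colors than requested clusters."""


class EmptyMaskError(VisQCError):
    """Operation requires a non-empty region-of-interest mask."""


class DecompositionDepthError(VisQCError):
    """Rectangle too small for the requested wavelet decomposition depth."""


class InsufficientExtentError(VisQCError):
    """Crop smaller than the largest requested co-occurrence displacement."""


class ConfigInconsistencyError(VisQCError):
    """Feature block lengths do not match the feature configuration."""


class RankError(VisQCError):
    """Requested number of components exceeds the rank of the calibration data."""


class FeatureMapError(VisQCError):
    """Sample vector length does not match the model's feature map."""


class DegreesOfFreedomError(VisQCError):
    """Not enough calibration samples for the requested limit (O <= A)."""


class MomentError(VisQCError):
    """Nonpositive residual moments; Q limit undefined."""
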