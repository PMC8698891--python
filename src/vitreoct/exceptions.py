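"""Exception hierarchy for vitreoct."""


class VitreoctError(Exception):
    """Base class for all vitreoct errors."""


class FormatError(VitreoctError):
    """Input data does not conform to an expected format (frame shape,
    channel count, container layout)."""


class SceneError(VitreoctError):
    """A synthetic scene specification is invalid (layer ordering, opacity
    outside the vitreous, overlapping planted regions)."""


class SegmentationError(VitreoctError):
    """Layer segmentation failed (no threshold crossing, no bright band,
    boundary ordering violated)."""


class ComputationError(VitreoctError):
    """A metric cannot be computed from the given inputs (empty mask,
    zero reference intensity)."""


class ConfigError(VitreoctError):
    """A pipeline configuration is invalid (unknown keys, out-of-range
    parameter values)."""
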