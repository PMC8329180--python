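"""Exception hierarchy for ccflow.

All pipeline stages raise subclasses of :class:`CCFlowError` so callers can
catch domain failures without masking programming errors.
"""


class CCFlowError(Exception):
    """Base class for all ccflow domain errors."""


class SpacingInfeasibleError(CCFlowError):
    """Vessel placement failed: requested minimum spacing cannot be met."""


class DegenerateMapError(CCFlowError):
    """Vascular map cannot drive a pressure solve (e.g. all strengths zero)."""


class TooShortError(CCFlowError):
    """A sequence has too few frames for the requested operation."""


class NoFeatureError(CCFlowError):
    """Registration input carries no usable image structure (constant image)."""


class ExcessiveMotionError(CCFlowError):
    """Registered frames share no common field of view."""


class EmptySelectionError(CCFlowError):
    """A filter or measurement selected zero items."""


class NoUnitsError(CCFlowError):
    """Functional-unit segmentation found nothing to segment."""


class UnsupportedFormatError(CCFlowError):
    """Input container or codec is not supported (e.g. compressed AVI)."""
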