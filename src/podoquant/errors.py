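"""Exception hierarchy.

Every error carries a short machine-readable ``code`` so pipeline stages can
log rejections uniformly instead of aborting a whole scene.
"""


class PodoquantError(Exception):
    """Base class; ``code`` identifies the failure mode."""

    code = "error"

    def __init__(self, message: str = ""):
        super().__init__(message or self.code)


class InvalidSpecError(PodoquantError):
    code = "invalid_spec"


class SceneOutOfBoundsError(PodoquantError):
    code = "scene_out_of_bounds"


class InvalidImageError(PodoquantError):
    code = "invalid_image"


class LineOutOfBoundsError(PodoquantError):
    code = "line_out_of_bounds"


class InvalidNormalError(PodoquantError):
    code = "invalid_normal"


class EmptyWindowError(PodoquantError):
    code = "empty_window"


class NoPeakError(PodoquantError):
    code = "no_peak"


class UnknownChannelError(PodoquantError):
    code = "unknown_channel"


class MismatchedProfilesError(PodoquantError):
    code = "mismatched_profiles"


class ZeroVarianceError(PodoquantError):
    code = "zero_variance"


class LengthMismatchError(PodoquantError):
    code = "length_mismatch"


class RegionTooSmallError(PodoquantError):
    code = "region_too_small"


class UnsortedPositionsError(PodoquantError):
    code = "unsorted_positions"


class InsufficientSitesError(PodoquantError):
    code = "insufficient_sites"


class InsufficientDataError(PodoquantError):
    code = "insufficient_data"


class MissingChannelError(PodoquantError):
    code = "missing_channel"


class ChannelShapeMismatchError(PodoquantError):
    code = "channel_shape_mismatch"
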