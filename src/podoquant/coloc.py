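"""Channel colocalization via the Pearson correlation coefficient.

Membrane colocalization of two markers (e.g. an actin-associated target and
a junctional partner) is quantified as the Pearson R of their luminances
over matched sample points — either along a plotted line (the default,
matching the plot-profile workflow) or over a boundary-band region of
interest. No thresholding or background masking is applied before
correlating, and R values are compared between groups directly (no Fisher z
transform) with a two-sided t test; both choices can be overridden.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .errors import (
    LengthMismatchError,
    MissingChannelError,
    RegionTooSmallError,
    ZeroVarianceError,
)
from .profiles import sample_profile
from .stats import t_test
from .types import (
    PARTNER,
    TARGET,
    ColocalizationResult,
    GroupComparison,
    LineSegment,
    MultiChannelImage,
)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation Σ(xᵢ−x̄)(yᵢ−ȳ) / √(Σ(xᵢ−x̄)² Σ(yᵢ−ȳ)²)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size:
        raise LengthMismatchError(f"lengths differ: {x.size} vs {y.size}")
    if x.size < 3:
        raise RegionTooSmallError("pearson_r needs n >= 3")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(np.dot(dx, dx))
    syy = float(np.dot(dy, dy))
    if sxx == 0.0 or syy == 0.0:
        raise ZeroVarianceError("constant sequence has undefined correlation")
    r = float(np.dot(dx, dy) / np.sqrt(sxx * syy))
    return float(np.clip(r, -1.0, 1.0))


def membrane_colocalization(
    image: MultiChannelImage,
    region: Union[LineSegment, np.ndarray],
    pair: Tuple[str, str] = (TARGET, PARTNER),
    intensity_floor: Optional[float] = None,
    region_id: Optional[str] = None,
) -> ColocalizationResult:
    """Pearson R of a channel pair over a line or a boolean-mask ROI.

    A :class:`LineSegment` region is sampled as an intensity profile (both
    channels at identical points); a boolean mask uses the raw pixels inside
    it. ``intensity_floor`` optionally drops sample points where both
    channels fall below the floor (off by default).
    """
    for role in pair:
        if role not in image.channels:
            raise MissingChannelError(f"channel {role!r} not in image")
    if isinstance(region, LineSegment):
        profile = sample_profile(image, region)
        x = profile.values[pair[0]]
        y = profile.values[pair[1]]
    else:
        mask = np.asarray(region, dtype=bool)
        if mask.shape != image.shape:
            raise LengthMismatchError("mask shape does not match image")
        x = image.channels[pair[0]][mask]
        y = image.channels[pair[1]][mask]
    if intensity_floor is not None:
        keep = (x >= intensity_floor) | (y >= intensity_floor)
        x, y = x[keep], y[keep]
    if x.size < 3:
        raise RegionTooSmallError(f"region yields n={x.size} < 3 samples")
    return ColocalizationResult(
        r=pearson_r(x, y), n=int(x.size), region_id=region_id, channel_pair=pair
    )


def compare_colocalization(
    group_a: Sequence[float],
    group_b: Sequence[float],
    group_labels: Tuple[str, str] = ("A", "B"),
    variant: str = "welch",
    fisher_z: bool = False,
) -> GroupComparison:
    """Two-sided t test on per-region R values (mean ± SEM per group).

    ``fisher_z=True`` applies arctanh before testing; the default compares
    the R values directly.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if fisher_z:
        a, b = np.arctanh(a), np.arctanh(b)
    return t_test(a, b, variant=variant, group_labels=group_labels)
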