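"""Apicobasal positional-ratio statistic from line profiles.

For each measurement line crossing a capillary-loop wall, the intensity
peaks of the basal-membrane, target and apical markers are located along the
profile. With ``a = |apical peak − basal peak|`` and
``b = |target peak − basal peak|``, the positional ratio ``b/a`` places the
target on the apicobasal axis: 0 at the basement membrane, 1 at the apical
surface.

Peaks are the global profile maximum (profiles cross a single wall by
construction and QC, so the global maximum is the band center), refined by
three-point parabolic interpolation so the ratio is insensitive to the
sampling step. QC rejects degenerate lines (basal/apical peaks closer than a
minimum separation) and lines where the target peak falls outside the
basal–apical interval, rather than clamping them, which would bias group
means.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .errors import (
    LineOutOfBoundsError,
    MismatchedProfilesError,
    NoPeakError,
    PodoquantError,
    UnknownChannelError,
)
from .profiles import check_parallel_alignment, sample_profile
from .scenes import PlannedLine
from .types import (
    APICAL,
    BASAL,
    TARGET,
    IntensityProfile,
    LineSegment,
    MultiChannelImage,
    PeakEstimate,
    PositionalRatioMeasurement,
)


def detect_peak(
    profile: IntensityProfile, channel_role: str, refine: bool = True
) -> PeakEstimate:
    """Position of a channel's intensity maximum along the profile.

    The peak sample is the global maximum; exact ties break toward the
    smaller distance (``argmax`` returns the first index). If ``refine`` and
    the maximum is interior, a three-point parabola through the maximum and
    its neighbors shifts the position sub-sample; the offset is confined to
    ± half a step.
    """
    if channel_role not in profile.values:
        raise UnknownChannelError(f"channel {channel_role!r} not in profile")
    y = profile.values[channel_role]
    if y.size == 0:
        raise NoPeakError("empty profile")
    # relative tolerance absorbs interpolation round-off on flat profiles
    if np.ptp(y) <= 1e-9 * max(np.abs(y).max(), 1.0):
        raise NoPeakError(f"channel {channel_role!r} profile is constant")
    i = int(np.argmax(y))
    pos = float(profile.distances[i])
    height = float(y[i])
    subpixel = False
    if refine and 0 < i < y.size - 1:
        denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
        if denom < 0:  # strict local maximum; plateau edges are left as-is
            delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            pos += delta * profile.spacing_um
            subpixel = True
    return PeakEstimate(
        channel_role=channel_role,
        position=pos,
        height=height,
        subpixel=subpixel,
        line_id=profile.line_id,
        scene_id=profile.scene_id,
    )


def compute_positional_ratio(
    basal: PeakEstimate,
    target: PeakEstimate,
    apical: PeakEstimate,
    min_separation_um: float = 0.0,
    group_label: Optional[str] = None,
) -> PositionalRatioMeasurement:
    """Combine the three marker peaks of one profile into b/a with QC.

    Rejects with reason ``degenerate`` when the basal/apical separation is
    below ``min_separation_um`` and ``misordered`` when the target peak does
    not lie between the basal and apical peaks (inclusive).
    """
    ids = {(p.line_id, p.scene_id) for p in (basal, target, apical)}
    if len(ids) != 1:
        raise MismatchedProfilesError("peaks come from different profiles")
    line_id, scene_id = next(iter(ids))

    a = abs(apical.position - basal.position)
    b = abs(target.position - basal.position)
    common = dict(line_id=line_id, scene_id=scene_id, group_label=group_label)
    if a < min_separation_um or a == 0.0:
        return PositionalRatioMeasurement(
            a=a, b=b, ratio=float("nan"), qc_status="rejected", reason="degenerate", **common
        )
    lo = min(basal.position, apical.position) - 1e-12
    hi = max(basal.position, apical.position) + 1e-12
    if not (lo <= target.position <= hi):
        return PositionalRatioMeasurement(
            a=a, b=b, ratio=float("nan"), qc_status="rejected", reason="misordered", **common
        )
    return PositionalRatioMeasurement(
        a=a, b=b, ratio=min(b / a, 1.0), qc_status="accepted", reason="", **common
    )


@dataclass(frozen=True)
class QCParams:
    """Quality-control knobs for per-line measurement.

    ``min_separation_steps`` — minimum basal↔apical peak separation in
    sampling steps below which a line is degenerate (default 3; avoids ratio
    blow-up). ``max_angle_deg`` — parallel-alignment tolerance for the window
    around each line. ``alignment_pad_px`` — half-width of that window around
    the line's bounding box. ``peak_window_um`` — optional restriction of
    peak search to ± this distance around the basal channel's global maximum
    (single-wall windowing for lines that cross a loop twice); None searches
    the whole profile. ``check_alignment`` — disable the orientation gate for
    user-drawn lines that were already vetted.
    """

    min_separation_steps: float = 3.0
    max_angle_deg: float = 15.0
    alignment_pad_px: int = 8
    peak_window_um: Optional[float] = None
    check_alignment: bool = True
    refine: bool = True


def _rejection(line: PlannedLine, reason: str) -> PositionalRatioMeasurement:
    return PositionalRatioMeasurement(
        a=float("nan"), b=float("nan"), ratio=float("nan"),
        qc_status="rejected", reason=reason,
        line_id=line.line_id, scene_id=line.scene_id, group_label=line.group_label,
    )


def _alignment_window(line: PlannedLine, shape, pad: int):
    r0 = int(np.floor(min(line.p0[0], line.p1[0]))) - pad
    r1 = int(np.ceil(max(line.p0[0], line.p1[0]))) + pad + 1
    c0 = int(np.floor(min(line.p0[1], line.p1[1]))) - pad
    c1 = int(np.ceil(max(line.p0[1], line.p1[1]))) + pad + 1
    return max(r0, 0), min(r1, shape[0]), max(c0, 0), min(c1, shape[1])


def measure_line(
    image: MultiChannelImage,
    line: PlannedLine,
    qc: QCParams = QCParams(),
) -> PositionalRatioMeasurement:
    """Measure one planned line; any failure becomes a rejection, not an abort."""
    if qc.check_alignment:
        try:
            window = _alignment_window(line, image.shape, qc.alignment_pad_px)
            result = check_parallel_alignment(
                image, window, qc.max_angle_deg, roles=(BASAL, TARGET, APICAL)
            )
            if not result.accepted:
                return _rejection(line, "misaligned")
        except PodoquantError as exc:
            return _rejection(line, exc.code)
    try:
        seg = LineSegment(line.p0, line.p1, line.step)
        profile = sample_profile(image, seg, line_id=line.line_id, scene_id=line.scene_id)
    except (LineOutOfBoundsError, ValueError):
        return _rejection(line, "line_out_of_bounds")
    try:
        basal = detect_peak(profile, BASAL, refine=qc.refine)
        if qc.peak_window_um is not None:
            profile = profile.restrict(
                basal.position - qc.peak_window_um, basal.position + qc.peak_window_um
            )
            basal = detect_peak(profile, BASAL, refine=qc.refine)
        target = detect_peak(profile, TARGET, refine=qc.refine)
        apical = detect_peak(profile, APICAL, refine=qc.refine)
    except PodoquantError as exc:
        return _rejection(line, exc.code)
    min_sep = qc.min_separation_steps * line.step * image.pixel_size
    return compute_positional_ratio(
        basal, target, apical, min_separation_um=min_sep, group_label=line.group_label
    )


def measure_scene(
    image: MultiChannelImage,
    sampling_plan: Sequence[PlannedLine],
    qc: QCParams = QCParams(),
) -> List[PositionalRatioMeasurement]:
    """Measure every planned line of one scene, in plan order.

    Per-line errors are recorded as rejections with their error code; the
    scene is never aborted, and the output order is deterministic.
    """
    return [measure_line(image, line, qc) for line in sampling_plan]


def accepted_ratios(measurements: Sequence[PositionalRatioMeasurement]) -> np.ndarray:
    return np.asarray([m.ratio for m in measurements if m.accepted], dtype=np.float64)
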