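"""Shared data containers.

Coordinate convention: images are 2-D arrays indexed ``(row, col)``, pixel
centers at integer coordinates, 0-based; ``col`` increases rightward and
``row`` downward. Physical distances are pixel distances times
``pixel_size`` (µm/px). Channels are keyed by marker *role*:

- ``basal``  — basement-membrane marker (nidogen-like)
- ``apical`` — apical-surface marker (podocalyxin-like)
- ``target`` — the protein whose apicobasal depth is measured (Synpo-like)
- ``partner``— a second channel for colocalization (MAGI-2 / actinin-like)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ChannelShapeMismatchError, InvalidImageError

BASAL = "basal"
APICAL = "apical"
TARGET = "target"
PARTNER = "partner"

LOOP_ROLES = (BASAL, TARGET, APICAL)


@dataclass
class MultiChannelImage:
    """Registered 2-D intensity channels keyed by marker role."""

    channels: Dict[str, np.ndarray]
    pixel_size: float  # µm per pixel
    provenance: str = ""

    def __post_init__(self):
        if not self.channels:
            raise InvalidImageError("image has no channels")
        if self.pixel_size <= 0:
            raise InvalidImageError("pixel_size must be positive")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ChannelShapeMismatchError(f"channel shapes differ: {shapes}")
        self.channels = {k: np.asarray(v, dtype=np.float64) for k, v in self.channels.items()}

    @property
    def shape(self) -> Tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def roles(self) -> Tuple[str, ...]:
        return tuple(self.channels)


@dataclass(frozen=True)
class LineSegment:
    """Straight sampling line in continuous pixel coordinates.

    ``p0``/``p1`` are (row, col); ``step`` is the sampling interval in px.
    """

    p0: Tuple[float, float]
    p1: Tuple[float, float]
    step: float = 0.5

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("step must be positive")
        if np.allclose(self.p0, self.p1):
            raise ValueError("degenerate line: p0 == p1")

    @property
    def length_px(self) -> float:
        return float(np.hypot(self.p1[0] - self.p0[0], self.p1[1] - self.p0[1]))

    def reversed(self) -> "LineSegment":
        return LineSegment(self.p1, self.p0, self.step)


@dataclass
class IntensityProfile:
    """Distance-parameterized luminance along a sampled line.

    ``distances`` are µm from the line's start, strictly increasing with
    uniform spacing; ``values`` maps each channel role to a sequence of the
    same length.
    """

    distances: np.ndarray
    values: Dict[str, np.ndarray]
    line_id: Optional[str] = None
    scene_id: Optional[str] = None

    def __post_init__(self):
        self.distances = np.asarray(self.distances, dtype=np.float64)
        n = self.distances.size
        for role, v in self.values.items():
            v = np.asarray(v, dtype=np.float64)
            if v.size != n:
                raise ValueError(f"channel {role!r} length {v.size} != {n}")
            self.values[role] = v

    @property
    def n_samples(self) -> int:
        return int(self.distances.size)

    @property
    def spacing_um(self) -> float:
        return float(self.distances[1] - self.distances[0]) if self.n_samples > 1 else 0.0

    def restrict(self, lo_um: float, hi_um: float) -> "IntensityProfile":
        """Sub-profile with lo_um <= distance <= hi_um (distances preserved)."""
        m = (self.distances >= lo_um) & (self.distances <= hi_um)
        return IntensityProfile(
            self.distances[m],
            {r: v[m] for r, v in self.values.items()},
            line_id=self.line_id,
            scene_id=self.scene_id,
        )


@dataclass
class SceneGroundTruth:
    """Simulator sidecar: the true quantities a scene was rendered with."""

    marker_depth_fractions: Dict[str, float] = field(default_factory=dict)
    wall_thickness: Optional[float] = None  # µm, the true "a"
    junction_fraction: Optional[float] = None  # q, share of signal at contacts
    junction_positions: Optional[np.ndarray] = None  # µm, ordered arc lengths
    foot_process_widths: Optional[np.ndarray] = None  # µm
    boundary_polylines: Optional[List[np.ndarray]] = None  # px, (N,2) rc arrays

    def __post_init__(self):
        if self.junction_positions is not None:
            self.junction_positions = np.asarray(self.junction_positions, dtype=np.float64)
        if self.foot_process_widths is not None:
            self.foot_process_widths = np.asarray(self.foot_process_widths, dtype=np.float64)
            if np.any(self.foot_process_widths <= 0):
                raise ValueError("foot-process widths must be positive")
        if self.junction_positions is not None and self.foot_process_widths is not None:
            if not np.allclose(np.diff(self.junction_positions), self.foot_process_widths):
                raise ValueError("widths must equal successive junction-position differences")


@dataclass(frozen=True)
class PeakEstimate:
    """Location of a channel's intensity maximum along a profile."""

    channel_role: str
    position: float  # µm along the profile
    height: float
    subpixel: bool = False
    line_id: Optional[str] = None
    scene_id: Optional[str] = None


@dataclass
class PositionalRatioMeasurement:
    """The apicobasal positional ratio b/a for one measurement line.

    ``a`` is the apical-to-basal peak distance, ``b`` the target-to-basal
    peak distance; accepted measurements satisfy 0 <= b/a <= 1 with the
    target peak lying between the basal and apical peaks.
    """

    a: float  # µm
    b: float  # µm
    ratio: float
    qc_status: str  # "accepted" | "rejected"
    reason: str = ""
    line_id: Optional[str] = None
    scene_id: Optional[str] = None
    group_label: Optional[str] = None

    @property
    def accepted(self) -> bool:
        return self.qc_status == "accepted"


@dataclass(frozen=True)
class ColocalizationResult:
    """Pearson correlation of two channels over a region."""

    r: float
    n: int
    region_id: Optional[str] = None
    channel_pair: Tuple[str, str] = (TARGET, PARTNER)


@dataclass(frozen=True)
class WidthMeasurement:
    """A single foot-process width (µm)."""

    width: float
    site_id: Optional[str] = None
    scene_id: Optional[str] = None
    group_label: Optional[str] = None


@dataclass(frozen=True)
class GroupComparison:
    """Two-group test outcome with per-group summaries."""

    group_labels: Tuple[str, str]
    n_per_group: Tuple[int, int]
    statistic_name: str
    statistic_value: float
    p_value: float
    means: Tuple[float, float]
    sems: Tuple[float, float]
    test_variant: str  # exact | normal_approx | welch | student

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


def widths_list(measurements: Sequence[WidthMeasurement]) -> np.ndarray:
    return np.asarray([m.width for m in measurements], dtype=np.float64)
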