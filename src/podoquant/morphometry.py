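"""Foot-process width morphometry.

A foot-process width is operationalized as the arc distance between
successive slit-diaphragm/junction positions along the basement-membrane
polyline, so widths telescope: they always sum to the covered arc length.
Widths are kept in µm internally; nanometre input is accepted with an
explicit unit tag. Site sampling mirrors the "n randomly selected sites"
design: uniform, without replacement, seeded.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import (
    InsufficientDataError,
    InsufficientSitesError,
    UnsortedPositionsError,
)
from .stats import mann_whitney_u, t_test
from .types import GroupComparison, WidthMeasurement, widths_list

_UNIT_TO_UM = {"um": 1.0, "µm": 1.0, "nm": 1e-3}


def widths_from_junctions(
    junction_positions: Sequence[float],
    unit: str = "um",
    scene_id: Optional[str] = None,
    group_label: Optional[str] = None,
) -> List[WidthMeasurement]:
    """Successive differences of ordered junction arc positions.

    Positions must be strictly increasing; n positions yield n−1 widths.
    """
    if unit not in _UNIT_TO_UM:
        raise ValueError(f"unknown unit {unit!r}; use 'um' or 'nm'")
    pos = np.asarray(junction_positions, dtype=np.float64) * _UNIT_TO_UM[unit]
    if pos.size < 2:
        raise UnsortedPositionsError("need >= 2 junction positions")
    diffs = np.diff(pos)
    if np.any(diffs <= 0):
        raise UnsortedPositionsError("junction positions must be strictly increasing")
    return [
        WidthMeasurement(
            width=float(w), site_id=f"site_{i:04d}", scene_id=scene_id, group_label=group_label
        )
        for i, w in enumerate(diffs)
    ]


def sample_sites(
    widths: Sequence[WidthMeasurement], n_sites: int, seed: int = 0
) -> List[WidthMeasurement]:
    """Seeded uniform sampling of measurement sites without replacement.

    The selection is canonicalized to the original site order so identical
    seeds give identical output lists.
    """
    if n_sites > len(widths):
        raise InsufficientSitesError(
            f"requested {n_sites} sites but only {len(widths)} available"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(widths), size=n_sites, replace=False))
    return [widths[i] for i in idx]


def compare_widths(
    control: Sequence[WidthMeasurement],
    ko: Sequence[WidthMeasurement],
    test: str = "t",
    group_labels: Tuple[str, str] = ("control", "ko"),
) -> GroupComparison:
    """Two-group width comparison (t test by default, Mann–Whitney optional)
    with mean ± SEM per group."""
    x = widths_list(control)
    y = widths_list(ko)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("each group needs >= 2 widths")
    if test == "t":
        return t_test(x, y, group_labels=group_labels)
    if test == "mannwhitney":
        return mann_whitney_u(x, y, group_labels=group_labels)
    raise ValueError(f"unknown test {test!r}")
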