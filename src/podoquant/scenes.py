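"""Synthetic fluorescence-scene generator with known ground truth.

Two scene families are rendered:

* **Capillary-loop scenes** — three marker channels drawn as Gaussian-profile
  bands running parallel to a common centerline at signed radial offsets
  0 (basal membrane marker), ``f·a`` (target) and ``a`` (apical marker)
  along the outward normal, where ``a`` is the wall thickness in µm and
  ``f ∈ [0, 1]`` the target's true depth fraction. This is the geometry the
  apicobasal positional-ratio measurement assumes: on any line crossing the
  wall perpendicularly, the three intensity peaks sit at 0, f·a and a.

* **Cultured-cell scenes** — two or more adjacent cell polygons where the
  target channel's integrated signal is split between interior stress-fiber
  segments and Gaussian tubes along the shared cell–cell boundaries, with a
  known junctional fraction ``q``; a partner channel is purely junctional by
  default. Boundary-band Pearson correlation then increases with ``q``.

All randomness flows through a single integer seed; identical spec + seed
yields bit-identical pixels and ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.spatial import cKDTree

from .errors import InvalidSpecError, SceneOutOfBoundsError
from .types import (
    APICAL,
    BASAL,
    LOOP_ROLES,
    PARTNER,
    TARGET,
    MultiChannelImage,
    SceneGroundTruth,
)

# ---------------------------------------------------------------------------
# noise models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseModel:
    """``none`` | ``gaussian`` (additive, sd) | ``poisson_gaussian`` (gain, sd).

    Gaussian read noise is clipped at zero so intensities stay valid;
    poisson_gaussian applies shot noise to the noiseless image (photon gain
    in intensity units per photon) followed by additive read noise.
    """

    kind: str = "none"
    sd: float = 0.0
    gain: float = 1.0

    def __post_init__(self):
        if self.kind not in ("none", "gaussian", "poisson_gaussian"):
            raise InvalidSpecError(f"unknown noise model {self.kind!r}")
        if self.kind != "none" and self.sd < 0:
            raise InvalidSpecError("noise sd must be >= 0")
        if self.kind == "poisson_gaussian" and self.gain <= 0:
            raise InvalidSpecError("gain must be positive")

    def apply(self, image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none":
            return image
        if self.kind == "gaussian":
            noisy = image + rng.normal(0.0, self.sd, size=image.shape)
        else:
            photons = rng.poisson(np.maximum(image, 0.0) / self.gain)
            noisy = photons * self.gain + rng.normal(0.0, self.sd, size=image.shape)
        return np.clip(noisy, 0.0, None)


NO_NOISE = NoiseModel("none")


# ---------------------------------------------------------------------------
# centerlines
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CircleCenterline:
    """Closed circular centerline; outward normal points away from center."""

    center: Tuple[float, float]  # (row, col) px
    radius_px: float

    def __post_init__(self):
        if self.radius_px <= 0:
            raise InvalidSpecError("circle radius must be positive")


@dataclass(frozen=True)
class PolylineCenterline:
    """Open or closed polyline through control points (N,2) in px."""

    points: Tuple[Tuple[float, float], ...]
    closed: bool = False

    def __post_init__(self):
        if len(self.points) < 2:
            raise InvalidSpecError("polyline needs >= 2 points")


Centerline = Union[CircleCenterline, PolylineCenterline]


def _resample_polyline(points: np.ndarray, closed: bool, step_px: float = 0.2):
    """Densely resample a polyline; returns points and unit normals.

    Normals are the per-segment left normals (rotate tangent by -90° in
    rc-coordinates), averaged at interior vertices.
    """
    pts = np.asarray(points, dtype=np.float64)
    if closed:
        pts = np.vstack([pts, pts[:1]])
    out_pts, out_nrm = [], []
    for i in range(len(pts) - 1):
        seg = pts[i + 1] - pts[i]
        seg_len = float(np.hypot(*seg))
        if seg_len == 0:
            continue
        t = seg / seg_len
        normal = np.array([-t[1], t[0]])
        n_steps = max(int(math.ceil(seg_len / step_px)), 1)
        ts = np.linspace(0.0, 1.0, n_steps, endpoint=False)
        out_pts.append(pts[i] + ts[:, None] * seg)
        out_nrm.append(np.repeat(normal[None, :], n_steps, axis=0))
    out_pts.append(pts[-1:])
    out_nrm.append(out_nrm[-1][-1:])
    return np.vstack(out_pts), np.vstack(out_nrm)


# ---------------------------------------------------------------------------
# loop scenes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LoopSceneSpec:
    """Parameters of a capillary-loop cross-section scene.

    ``wall_thickness`` is the basal-to-apical band-center distance in µm
    (the ground-truth "a"); ``target_depth_fraction`` the ground-truth b/a.
    ``band_sigma`` (µm) may be a single value or a per-role mapping.
    """

    image_shape: Tuple[int, int] = (256, 256)
    pixel_size: float = 0.05  # µm/px
    centerline: Centerline = CircleCenterline((128.0, 128.0), 80.0)
    wall_thickness: float = 1.0  # µm
    target_depth_fraction: float = 0.5
    band_sigma: Union[float, Dict[str, float]] = 0.08  # µm
    amplitudes: Dict[str, float] = field(
        default_factory=lambda: {BASAL: 1000.0, TARGET: 1000.0, APICAL: 1000.0}
    )
    background: float = 100.0
    noise_model: NoiseModel = NO_NOISE
    seed: int = 0

    def sigma_for(self, role: str) -> float:
        if isinstance(self.band_sigma, dict):
            return float(self.band_sigma[role])
        return float(self.band_sigma)

    def validate(self):
        if not (0.0 <= self.target_depth_fraction <= 1.0):
            raise InvalidSpecError("target_depth_fraction must be in [0, 1]")
        if self.pixel_size <= 0:
            raise InvalidSpecError("pixel_size must be positive")
        if self.wall_thickness <= 0:
            raise InvalidSpecError("wall_thickness must be positive")
        for role in LOOP_ROLES:
            if self.sigma_for(role) <= 0:
                raise InvalidSpecError("band_sigma must be positive")


def _band_offsets_um(spec: LoopSceneSpec) -> Dict[str, float]:
    a = spec.wall_thickness
    return {BASAL: 0.0, TARGET: spec.target_depth_fraction * a, APICAL: a}


def _distance_to_offset_curve(spec: LoopSceneSpec, offset_px: float) -> np.ndarray:
    """Per-pixel distance (px) to the centerline shifted by offset_px along
    the outward normal."""
    rows, cols = spec.image_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    cl = spec.centerline
    if isinstance(cl, CircleCenterline):
        radial = np.hypot(rr - cl.center[0], cc - cl.center[1])
        return np.abs(radial - (cl.radius_px + offset_px))
    pts, nrm = _resample_polyline(np.asarray(cl.points), cl.closed)
    offset_pts = pts + offset_px * nrm
    tree = cKDTree(offset_pts)
    d, _ = tree.query(np.column_stack([rr.ravel(), cc.ravel()]))
    return d.reshape(rows, cols)


def _check_curve_in_bounds(spec: LoopSceneSpec, offset_px: float, margin_px: float):
    rows, cols = spec.image_shape
    cl = spec.centerline
    if isinstance(cl, CircleCenterline):
        reach = cl.radius_px + offset_px + margin_px
        r0, c0 = cl.center
        if r0 - reach < 0 or r0 + reach > rows - 1 or c0 - reach < 0 or c0 + reach > cols - 1:
            raise SceneOutOfBoundsError(
                f"band at offset {offset_px:.1f} px exceeds image bounds"
            )
    else:
        pts, nrm = _resample_polyline(np.asarray(cl.points), cl.closed)
        op = pts + offset_px * nrm
        if (
            op[:, 0].min() - margin_px < 0
            or op[:, 0].max() + margin_px > rows - 1
            or op[:, 1].min() - margin_px < 0
            or op[:, 1].max() + margin_px > cols - 1
        ):
            raise SceneOutOfBoundsError(
                f"band at offset {offset_px:.1f} px exceeds image bounds"
            )


def generate_loop_scene(spec: LoopSceneSpec) -> Tuple[MultiChannelImage, SceneGroundTruth]:
    """Render a three-band capillary-loop scene with its ground truth.

    Each channel is ``background + amplitude * exp(-d²/2σ²)`` where ``d`` is
    the distance to that marker's offset centerline. Raises
    ``scene_out_of_bounds`` if any band (center ± 3σ) leaves the image.
    """
    spec.validate()
    offsets_um = _band_offsets_um(spec)
    rng = np.random.default_rng(spec.seed)
    channels: Dict[str, np.ndarray] = {}
    for role in LOOP_ROLES:
        off_px = offsets_um[role] / spec.pixel_size
        sigma_px = spec.sigma_for(role) / spec.pixel_size
        _check_curve_in_bounds(spec, off_px, 3.0 * sigma_px)
        d = _distance_to_offset_curve(spec, off_px)
        img = spec.background + spec.amplitudes[role] * np.exp(-(d**2) / (2.0 * sigma_px**2))
        channels[role] = spec.noise_model.apply(img, rng)
    truth = SceneGroundTruth(
        marker_depth_fractions={BASAL: 0.0, TARGET: spec.target_depth_fraction, APICAL: 1.0},
        wall_thickness=spec.wall_thickness,
    )
    image = MultiChannelImage(channels, spec.pixel_size, provenance="loop_scene")
    return image, truth


# ---------------------------------------------------------------------------
# cell scenes
# ---------------------------------------------------------------------------


def default_cell_polygons(image_shape: Tuple[int, int]) -> List[np.ndarray]:
    """Two side-by-side rectangular cells sharing a vertical boundary."""
    rows, cols = image_shape
    m = 0.12  # fractional margin to the frame
    r0, r1 = m * rows, (1 - m) * rows
    c0, c1, c2 = m * cols, cols / 2.0, (1 - m) * cols
    left = np.array([[r0, c0], [r0, c1], [r1, c1], [r1, c0]])
    right = np.array([[r0, c1], [r0, c2], [r1, c2], [r1, c1]])
    return [left, right]


@dataclass(frozen=True)
class CellSceneSpec:
    """Parameters of a cultured-cell scene.

    ``junction_fraction`` q is the share of the target channel's integrated
    (above-background) intensity placed on boundaries shared between cells;
    the remainder goes to interior stress-fiber segments.
    """

    image_shape: Tuple[int, int] = (256, 256)
    pixel_size: float = 0.1  # µm/px
    cell_polygons: Optional[Sequence[np.ndarray]] = None  # default: two cells
    junction_fraction: float = 0.5
    fiber_count: int = 12
    fiber_sigma: float = 0.15  # µm
    junction_sigma: float = 0.15  # µm
    amplitude: float = 1000.0
    background: float = 50.0
    partner_junction_fraction: float = 1.0  # partner channel is junctional
    noise_model: NoiseModel = NO_NOISE
    seed: int = 0

    def polygons(self) -> List[np.ndarray]:
        if self.cell_polygons is None:
            return default_cell_polygons(self.image_shape)
        return [np.asarray(p, dtype=np.float64) for p in self.cell_polygons]

    def validate(self):
        if not (0.0 <= self.junction_fraction <= 1.0):
            raise InvalidSpecError("junction_fraction must be in [0, 1]")
        if not (0.0 <= self.partner_junction_fraction <= 1.0):
            raise InvalidSpecError("partner_junction_fraction must be in [0, 1]")
        if self.pixel_size <= 0 or self.fiber_sigma <= 0 or self.junction_sigma <= 0:
            raise InvalidSpecError("pixel_size and sigmas must be positive")
        if len(self.polygons()) < 2:
            raise InvalidSpecError("need >= 2 cell polygons")
        if not shared_boundary_segments(self.polygons()):
            raise InvalidSpecError("cell polygons share no boundary segment")


def _polygon_edges(poly: np.ndarray):
    n = len(poly)
    for i in range(n):
        yield poly[i], poly[(i + 1) % n]


def shared_boundary_segments(polygons: Sequence[np.ndarray], tol: float = 1e-6) -> List[np.ndarray]:
    """Edges shared (as point sets, either orientation) by two polygons."""
    segs: List[np.ndarray] = []
    for i in range(len(polygons)):
        for j in range(i + 1, len(polygons)):
            for a0, a1 in _polygon_edges(np.asarray(polygons[i])):
                for b0, b1 in _polygon_edges(np.asarray(polygons[j])):
                    same = np.allclose(a0, b0, atol=tol) and np.allclose(a1, b1, atol=tol)
                    swapped = np.allclose(a0, b1, atol=tol) and np.allclose(a1, b0, atol=tol)
                    if same or swapped:
                        segs.append(np.array([a0, a1]))
    return segs


def _tube_image(
    shape: Tuple[int, int], segments: Sequence[np.ndarray], sigma_px: float
) -> np.ndarray:
    """Gaussian-cross-section tubes along line segments, unit amplitude."""
    pts = []
    for seg in segments:
        p, _ = _resample_polyline(np.asarray(seg), closed=False, step_px=0.25)
        pts.append(p)
    allpts = np.vstack(pts)
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    tree = cKDTree(allpts)
    d, _ = tree.query(np.column_stack([rr.ravel(), cc.ravel()]))
    d = d.reshape(shape)
    return np.exp(-(d**2) / (2.0 * sigma_px**2))


def _point_in_polygon(pt: np.ndarray, poly: np.ndarray) -> bool:
    # ray casting in (row, col) coordinates
    r, c = pt
    inside = False
    n = len(poly)
    for i in range(n):
        r0, c0 = poly[i]
        r1, c1 = poly[(i + 1) % n]
        if (r0 > r) != (r1 > r):
            cx = c0 + (r - r0) / (r1 - r0) * (c1 - c0)
            if c < cx:
                inside = not inside
    return inside


def _random_fibers(
    poly: np.ndarray, count: int, margin_px: float, rng: np.random.Generator
) -> List[np.ndarray]:
    """Random chord segments strictly inside the polygon, >= margin from it."""
    lo = poly.min(axis=0) + margin_px
    hi = poly.max(axis=0) - margin_px
    if np.any(hi <= lo):
        raise InvalidSpecError("cell polygon too small for the fiber margin")

    def sample_point():
        for _ in range(1000):
            p = rng.uniform(lo, hi)
            if _point_in_polygon(p, poly) and _dist_to_polygon(p, poly) >= margin_px:
                return p
        raise InvalidSpecError("could not place fiber inside polygon")

    fibers = []
    for _ in range(count):
        a, b = sample_point(), sample_point()
        while np.hypot(*(a - b)) < 2 * margin_px:  # avoid degenerate stubs
            b = sample_point()
        fibers.append(np.array([a, b]))
    return fibers


def _dist_to_polygon(pt: np.ndarray, poly: np.ndarray) -> float:
    best = np.inf
    for a, b in _polygon_edges(poly):
        ab = b - a
        t = np.clip(np.dot(pt - a, ab) / np.dot(ab, ab), 0.0, 1.0)
        best = min(best, float(np.hypot(*(pt - (a + t * ab)))))
    return best


def generate_cell_scene(spec: CellSceneSpec) -> Tuple[MultiChannelImage, SceneGroundTruth]:
    """Render a cultured-cell scene: target split between interior fibers and
    shared-boundary junctions (fraction q), partner junctional by default.

    The fiber margin keeps stress fibers >= 3 junction-σ + 2 fiber-σ away
    from cell boundaries so the junctional energy fraction of the rendered
    target channel matches q to well under 1%.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    polygons = spec.polygons()
    boundary_segs = shared_boundary_segments(polygons)
    js_px = spec.junction_sigma / spec.pixel_size
    fs_px = spec.fiber_sigma / spec.pixel_size
    margin = 3.0 * js_px + 2.0 * fs_px

    junction_img = _tube_image(spec.image_shape, boundary_segs, js_px)
    fiber_segs: List[np.ndarray] = []
    for poly in polygons:
        fiber_segs.extend(_random_fibers(poly, spec.fiber_count, margin, rng))
    fiber_img = _tube_image(spec.image_shape, fiber_segs, fs_px)

    j_norm = junction_img / junction_img.sum()
    f_norm = fiber_img / fiber_img.sum()
    # Fixed energy scale across q: a channel that is fully junctional peaks at
    # `amplitude`, and the junctional band's brightness grows linearly with q.
    scale = spec.amplitude / j_norm.max()

    def mix(q: float) -> np.ndarray:
        s = q * j_norm + (1.0 - q) * f_norm
        return spec.background + scale * s

    q = spec.junction_fraction
    channels = {
        TARGET: spec.noise_model.apply(mix(q), rng),
        PARTNER: spec.noise_model.apply(mix(spec.partner_junction_fraction), rng),
    }
    truth = SceneGroundTruth(
        junction_fraction=q,
        boundary_polylines=[np.asarray(s) for s in boundary_segs],
    )
    return MultiChannelImage(channels, spec.pixel_size, provenance="cell_scene"), truth


def boundary_band_mask(
    image_shape: Tuple[int, int], boundary_polylines: Sequence[np.ndarray], width_px: float
) -> np.ndarray:
    """Boolean mask of pixels within width_px of any shared-boundary segment."""
    pts = []
    for seg in boundary_polylines:
        p, _ = _resample_polyline(np.asarray(seg), closed=False, step_px=0.25)
        pts.append(p)
    tree = cKDTree(np.vstack(pts))
    rr, cc = np.meshgrid(np.arange(image_shape[0]), np.arange(image_shape[1]), indexing="ij")
    d, _ = tree.query(np.column_stack([rr.ravel(), cc.ravel()]))
    return (d.reshape(image_shape) <= width_px)


# ---------------------------------------------------------------------------
# morphometry datasets
# ---------------------------------------------------------------------------

_DISTRIBUTIONS = ("constant", "lognormal", "normal", "gamma")


def generate_morphometry_dataset(
    n_sites: int,
    width_distribution: Tuple[str, Dict[str, float]],
    seed: int = 0,
) -> SceneGroundTruth:
    """Ordered junction positions whose gaps are i.i.d. foot-process widths.

    ``width_distribution`` is ``(name, params)``:

    - ``("constant",  {"width": w})``
    - ``("lognormal", {"mu": µ, "sigma": σ})`` — log-space parameters — or
      ``("lognormal", {"mean": m, "cv": c})`` for the arithmetic mean and
      coefficient of variation
    - ``("normal",    {"mean": m, "sd": s})`` — redrawn until positive
    - ``("gamma",     {"shape": k, "scale": θ})``
    """
    if n_sites < 1:
        raise InvalidSpecError("n_sites must be >= 1")
    name, params = width_distribution
    if name not in _DISTRIBUTIONS:
        raise InvalidSpecError(f"unknown width distribution {name!r}")
    if any(v <= 0 for k, v in params.items() if k != "mu"):
        raise InvalidSpecError("distribution parameters must be positive")
    rng = np.random.default_rng(seed)
    if name == "constant":
        widths = np.full(n_sites, float(params["width"]))
    elif name == "lognormal":
        if "mean" in params:
            cv = float(params["cv"])
            sigma = math.sqrt(math.log(1.0 + cv**2))
            mu = math.log(float(params["mean"])) - sigma**2 / 2.0
        else:
            mu, sigma = float(params["mu"]), float(params["sigma"])
        widths = rng.lognormal(mu, sigma, size=n_sites)
    elif name == "normal":
        widths = rng.normal(params["mean"], params["sd"], size=n_sites)
        while np.any(widths <= 0):  # truncate at 0 by redrawing
            bad = widths <= 0
            widths[bad] = rng.normal(params["mean"], params["sd"], size=int(bad.sum()))
    else:
        widths = rng.gamma(params["shape"], params["scale"], size=n_sites)
    positions = np.concatenate([[0.0], np.cumsum(widths)])
    return SceneGroundTruth(junction_positions=positions, foot_process_widths=widths)


# ---------------------------------------------------------------------------
# group experiments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlannedLine:
    scene_id: str
    line_id: str
    group_label: str
    p0: Tuple[float, float]
    p1: Tuple[float, float]
    step: float


@dataclass
class ExperimentBundle:
    """Labelled scenes plus a deterministic line-sampling plan."""

    scenes: Dict[str, Tuple[MultiChannelImage, SceneGroundTruth]]  # scene_id -> scene
    groups: Dict[str, str]  # scene_id -> group label
    plan: List[PlannedLine]
    seed: int


def _scene_seed(seed: int, group_idx: int, scene_idx: int) -> int:
    ss = np.random.SeedSequence([int(seed), group_idx, scene_idx])
    return int(ss.generate_state(1)[0] % (2**31))


def plan_perpendicular_lines(
    spec: LoopSceneSpec,
    n_lines: int,
    rng: np.random.Generator,
    scene_id: str,
    group_label: str,
    step_px: float = 0.5,
    half_length_um: Optional[float] = None,
) -> List[PlannedLine]:
    """Random measurement lines crossing the loop wall along its normal.

    Lines are centered mid-wall (offset a/2 from the basal band) and span
    ± half_length_um (default: the wall thickness), so each line covers all
    three bands and crosses the wall exactly once.
    """
    a_px = spec.wall_thickness / spec.pixel_size
    hl_px = (half_length_um or spec.wall_thickness) / spec.pixel_size
    cl = spec.centerline
    lines = []
    if isinstance(cl, CircleCenterline):
        thetas = rng.uniform(0.0, 2.0 * math.pi, size=n_lines)
        for i, th in enumerate(thetas):
            normal = np.array([math.sin(th), math.cos(th)])
            center = np.asarray(cl.center) + (cl.radius_px + a_px / 2.0) * normal
            p0 = center - hl_px * normal
            p1 = center + hl_px * normal
            lines.append(
                PlannedLine(scene_id, f"{scene_id}_L{i:03d}", group_label,
                            (float(p0[0]), float(p0[1])), (float(p1[0]), float(p1[1])), step_px)
            )
    else:
        pts, nrm = _resample_polyline(np.asarray(cl.points), cl.closed)
        idx = rng.integers(0, len(pts), size=n_lines)
        for i, k in enumerate(idx):
            center = pts[k] + (a_px / 2.0) * nrm[k]
            p0 = center - hl_px * nrm[k]
            p1 = center + hl_px * nrm[k]
            lines.append(
                PlannedLine(scene_id, f"{scene_id}_L{i:03d}", group_label,
                            (float(p0[0]), float(p0[1])), (float(p1[0]), float(p1[1])), step_px)
            )
    return lines


def generate_group_experiment(
    control_spec: LoopSceneSpec,
    ko_spec: LoopSceneSpec,
    n_scenes_per_group: int = 1,
    lines_per_scene: int = 30,
    seed: int = 0,
    group_labels: Tuple[str, str] = ("control", "ko"),
) -> ExperimentBundle:
    """Deterministic two-group bundle of scenes and planned measurement lines.

    Per-scene random streams are derived from the top-level seed, so any
    subset of scenes is reproducible in isolation.
    """
    if n_scenes_per_group < 1:
        raise InvalidSpecError("n_scenes_per_group must be >= 1")
    scenes: Dict[str, Tuple[MultiChannelImage, SceneGroundTruth]] = {}
    groups: Dict[str, str] = {}
    plan: List[PlannedLine] = []
    for g_idx, (label, spec) in enumerate(zip(group_labels, (control_spec, ko_spec))):
        for s_idx in range(n_scenes_per_group):
            sid = f"{label}_{s_idx:02d}"
            child_seed = _scene_seed(seed, g_idx, s_idx)
            scene_spec = replace(spec, seed=child_seed)
            scenes[sid] = generate_loop_scene(scene_spec)
            groups[sid] = label
            line_rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), g_idx, s_idx, 7])
            )
            plan.extend(
                plan_perpendicular_lines(scene_spec, lines_per_scene, line_rng, sid, label)
            )
    return ExperimentBundle(scenes=scenes, groups=groups, plan=plan, seed=seed)
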