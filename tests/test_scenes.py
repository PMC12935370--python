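"""Scene simulator: band geometry, energy partition, determinism, validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from podoquant.errors import InvalidSpecError, SceneOutOfBoundsError
from podoquant.scenes import (
    CellSceneSpec,
    CircleCenterline,
    LoopSceneSpec,
    NoiseModel,
    PolylineCenterline,
    boundary_band_mask,
    generate_cell_scene,
    generate_group_experiment,
    generate_loop_scene,
    generate_morphometry_dataset,
    plan_perpendicular_lines,
)
from podoquant.types import APICAL, BASAL, TARGET


def dense_normal_scan_peak_offsets(spec, image, n_angles=32, step_px=0.02):
    """Independent oracle: scan dense radial lines by direct sub-sampled
    nearest-pixel lookup and report mean argmax offsets (µm) from the basal
    peak for each channel."""
    cl = spec.centerline
    a_px = spec.wall_thickness / spec.pixel_size
    radii = np.arange(cl.radius_px - a_px, cl.radius_px + 2 * a_px, step_px)
    offsets = {TARGET: [], APICAL: []}
    for theta in np.linspace(0, 2 * np.pi, n_angles, endpoint=False):
        d = np.array([np.sin(theta), np.cos(theta)])
        pts = np.asarray(cl.center) + radii[:, None] * d[None, :]
        idx = np.round(pts).astype(int)
        basal_r = radii[np.argmax(image.channels[BASAL][idx[:, 0], idx[:, 1]])]
        for role in (TARGET, APICAL):
            r = radii[np.argmax(image.channels[role][idx[:, 0], idx[:, 1]])]
            offsets[role].append((r - basal_r) * spec.pixel_size)
    return {k: float(np.mean(v)) for k, v in offsets.items()}


class TestLoopScene:
    def test_coincident_bands_at_zero_depth(self):
        """f=0: target band coincides with the basal band up to amplitude."""
        spec = LoopSceneSpec(
            target_depth_fraction=0.0,
            amplitudes={BASAL: 500.0, TARGET: 1000.0, APICAL: 800.0},
        )
        image, truth = generate_loop_scene(spec)
        basal = image.channels[BASAL] - spec.background
        target = image.channels[TARGET] - spec.background
        np.testing.assert_allclose(target, 2.0 * basal, atol=1e-9)
        assert truth.marker_depth_fractions[TARGET] == 0.0

    def test_band_offsets_match_ground_truth(self):
        """Dense normal-line scan: argmax separations reproduce (f·a, a)
        within half a scan step."""
        spec = LoopSceneSpec(target_depth_fraction=0.5, wall_thickness=1.0)
        image, _ = generate_loop_scene(spec)
        off = dense_normal_scan_peak_offsets(spec, image)
        # nearest-pixel lookup quantizes at the pixel scale
        assert abs(off[TARGET] - 0.5) <= spec.pixel_size
        assert abs(off[APICAL] - 1.0) <= spec.pixel_size

    def test_seed_determinism(self):
        spec = LoopSceneSpec(noise_model=NoiseModel("gaussian", sd=50.0), seed=99)
        img1, _ = generate_loop_scene(spec)
        img2, _ = generate_loop_scene(spec)
        for role in img1.channels:
            np.testing.assert_array_equal(img1.channels[role], img2.channels[role])

    def test_out_of_bounds_band_raises(self):
        spec = LoopSceneSpec(centerline=CircleCenterline((128.0, 128.0), 125.0))
        with pytest.raises(SceneOutOfBoundsError):
            generate_loop_scene(spec)

    @pytest.mark.parametrize("bad", [-0.1, 1.1])
    def test_invalid_depth_fraction_rejected(self, bad):
        with pytest.raises(InvalidSpecError):
            generate_loop_scene(LoopSceneSpec(target_depth_fraction=bad))

    def test_polyline_centerline_renders_parallel_bands(self):
        """An open polyline centerline produces the same peak-offset geometry."""
        spec = LoopSceneSpec(
            centerline=PolylineCenterline(((60.0, 40.0), (60.0, 216.0))),
            target_depth_fraction=0.3,
        )
        image, _ = generate_loop_scene(spec)
        # vertical scan through the middle column crosses all bands
        col = 128
        rows = np.arange(40, 110)
        a_px = spec.wall_thickness / spec.pixel_size
        basal_r = rows[np.argmax(image.channels[BASAL][rows, col])]
        target_r = rows[np.argmax(image.channels[TARGET][rows, col])]
        apical_r = rows[np.argmax(image.channels[APICAL][rows, col])]
        assert abs(abs(apical_r - basal_r) - a_px) <= 1.0
        assert abs(abs(target_r - basal_r) - 0.3 * a_px) <= 1.0

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(f=st.floats(min_value=0.05, max_value=0.95))
    def test_noise_clipping_keeps_intensities_nonnegative(self, f):
        spec = LoopSceneSpec(
            image_shape=(128, 128),
            centerline=CircleCenterline((64.0, 64.0), 30.0),
            target_depth_fraction=f,
            noise_model=NoiseModel("gaussian", sd=300.0),
            seed=int(f * 1000),
        )
        image, _ = generate_loop_scene(spec)
        for chan in image.channels.values():
            assert chan.min() >= 0.0


class TestCellScene:
    @pytest.mark.parametrize("q,expected", [(0.0, 0.0), (0.5, 0.5), (1.0, 1.0)])
    def test_junctional_energy_partition(self, q, expected):
        """Boundary-band share of above-background target signal equals q."""
        spec = CellSceneSpec(junction_fraction=q, seed=3)
        image, truth = generate_cell_scene(spec)
        band = boundary_band_mask(
            spec.image_shape,
            truth.boundary_polylines,
            3.0 * spec.junction_sigma / spec.pixel_size,
        )
        signal = image.channels[TARGET] - spec.background
        frac = signal[band].sum() / signal.sum()
        assert abs(frac - expected) <= 0.01

    def test_zero_junction_fraction_leaves_boundary_at_background(self):
        spec = CellSceneSpec(junction_fraction=0.0, seed=3)
        image, truth = generate_cell_scene(spec)
        band = boundary_band_mask(spec.image_shape, truth.boundary_polylines, 2.0)
        mean_boundary = image.channels[TARGET][band].mean()
        assert abs(mean_boundary - spec.background) < 1.0

    def test_full_junction_fraction_empties_interior(self):
        spec = CellSceneSpec(junction_fraction=1.0, seed=3)
        image, truth = generate_cell_scene(spec)
        band = boundary_band_mask(
            spec.image_shape, truth.boundary_polylines,
            4.0 * spec.junction_sigma / spec.pixel_size,
        )
        interior = image.channels[TARGET][~band] - spec.background
        assert interior.sum() / (image.channels[TARGET] - spec.background).sum() < 0.01

    def test_invalid_fraction_rejected(self):
        with pytest.raises(InvalidSpecError):
            generate_cell_scene(CellSceneSpec(junction_fraction=1.5))

    def test_disjoint_polygons_rejected(self):
        far_apart = [
            np.array([[10.0, 10.0], [10.0, 40.0], [40.0, 40.0], [40.0, 10.0]]),
            np.array([[10.0, 100.0], [10.0, 140.0], [40.0, 140.0], [40.0, 100.0]]),
        ]
        with pytest.raises(InvalidSpecError):
            generate_cell_scene(CellSceneSpec(cell_polygons=far_apart))

    def test_seed_determinism(self):
        spec = CellSceneSpec(seed=11, noise_model=NoiseModel("gaussian", sd=30.0))
        img1, _ = generate_cell_scene(spec)
        img2, _ = generate_cell_scene(spec)
        np.testing.assert_array_equal(img1.channels[TARGET], img2.channels[TARGET])


class TestMorphometryDataset:
    def test_constant_widths(self):
        gt = generate_morphometry_dataset(20, ("constant", {"width": 0.25}), seed=0)
        np.testing.assert_array_equal(gt.foot_process_widths, np.full(20, 0.25))
        assert gt.junction_positions.size == 21

    def test_lognormal_mean_matches_closed_form(self):
        mu, sigma = np.log(0.25), 0.4
        gt = generate_morphometry_dataset(10_000, ("lognormal", {"mu": mu, "sigma": sigma}), seed=1)
        analytic = np.exp(mu + sigma**2 / 2.0)
        assert abs(gt.foot_process_widths.mean() - analytic) / analytic < 0.02

    def test_determinism(self):
        args = (20, ("lognormal", {"mean": 0.25, "cv": 0.3}))
        g1 = generate_morphometry_dataset(*args, seed=5)
        g2 = generate_morphometry_dataset(*args, seed=5)
        np.testing.assert_array_equal(g1.foot_process_widths, g2.foot_process_widths)

    def test_positions_telescope_to_widths(self):
        gt = generate_morphometry_dataset(50, ("gamma", {"shape": 4.0, "scale": 0.06}), seed=2)
        np.testing.assert_allclose(np.diff(gt.junction_positions), gt.foot_process_widths)

    @pytest.mark.parametrize(
        "dist", [("constant", {"width": -1.0}), ("lognormal", {"mean": 0.25, "cv": -0.3})]
    )
    def test_nonpositive_parameters_rejected(self, dist):
        with pytest.raises(InvalidSpecError):
            generate_morphometry_dataset(10, dist, seed=0)


class TestGroupExperiment:
    def test_bundle_counts(self):
        bundle = generate_group_experiment(
            LoopSceneSpec(target_depth_fraction=0.55),
            LoopSceneSpec(target_depth_fraction=0.35),
            n_scenes_per_group=1, lines_per_scene=1, seed=0,
        )
        assert len(bundle.scenes) == 2
        assert len(bundle.plan) == 2

    def test_manifest_determinism(self):
        specs = (LoopSceneSpec(target_depth_fraction=0.55),
                 LoopSceneSpec(target_depth_fraction=0.35))
        b1 = generate_group_experiment(*specs, n_scenes_per_group=2, lines_per_scene=5, seed=4)
        b2 = generate_group_experiment(*specs, n_scenes_per_group=2, lines_per_scene=5, seed=4)
        assert [(l.scene_id, l.line_id, l.p0, l.p1) for l in b1.plan] == [
            (l.scene_id, l.line_id, l.p0, l.p1) for l in b2.plan
        ]
        for sid in b1.scenes:
            np.testing.assert_array_equal(
                b1.scenes[sid][0].channels[TARGET], b2.scenes[sid][0].channels[TARGET]
            )
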