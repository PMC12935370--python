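"""Peak detection, positional-ratio arithmetic/QC, and scene measurement."""

import numpy as np
import pytest

from podoquant.errors import MismatchedProfilesError, NoPeakError, UnknownChannelError
from podoquant.ratio import (
    QCParams,
    accepted_ratios,
    compute_positional_ratio,
    detect_peak,
    measure_scene,
)
from podoquant.scenes import (
    PlannedLine,
    generate_loop_scene,
    plan_perpendicular_lines,
)
from podoquant.types import (
    APICAL,
    BASAL,
    TARGET,
    IntensityProfile,
    PeakEstimate,
)


def make_profile(values, distances=None, **kwargs):
    values = np.asarray(values, dtype=float)
    if distances is None:
        distances = np.arange(values.size, dtype=float)
    return IntensityProfile(distances, {"target": values}, **kwargs)


class TestDetectPeak:
    def test_simple_maximum(self):
        prof = make_profile([0, 1, 3, 1, 0])
        peak = detect_peak(prof, "target", refine=False)
        assert peak.position == 2.0
        assert peak.height == 3.0

    def test_tie_breaks_toward_smaller_distance(self):
        prof = make_profile([0, 2, 3, 3, 2, 0])
        peak = detect_peak(prof, "target", refine=False)
        assert peak.position == 2.0

    def test_parabolic_refinement_recovers_gaussian_center(self):
        """Analytic oracle: Gaussian centered between samples is recovered to
        within 0.05 px by three-point parabolic refinement."""
        step_px, pixel_size = 0.5, 0.1
        true_center_px = 10.37  # deliberately off-grid
        k = np.arange(41)
        d_px = k * step_px
        values = np.exp(-((d_px - true_center_px) ** 2) / (2 * 2.0**2))
        prof = IntensityProfile(d_px * pixel_size, {"target": values})
        peak = detect_peak(prof, "target", refine=True)
        assert peak.subpixel
        assert abs(peak.position / pixel_size - true_center_px) < 0.05

    def test_constant_profile_has_no_peak(self):
        with pytest.raises(NoPeakError):
            detect_peak(make_profile([5, 5, 5, 5]), "target")

    def test_unknown_channel(self):
        with pytest.raises(UnknownChannelError):
            detect_peak(make_profile([0, 1, 0]), "apical")


def peak(role, pos, line_id="L0", scene_id="S0"):
    return PeakEstimate(role, pos, height=1.0, line_id=line_id, scene_id=scene_id)


class TestComputePositionalRatio:
    def test_basic_arithmetic(self):
        m = compute_positional_ratio(peak(BASAL, 0.0), peak(TARGET, 0.3), peak(APICAL, 1.0))
        assert m.accepted
        assert m.a == pytest.approx(1.0)
        assert m.b == pytest.approx(0.3)
        assert m.ratio == pytest.approx(0.30)

    def test_target_on_basal_membrane_gives_zero(self):
        m = compute_positional_ratio(peak(BASAL, 0.5), peak(TARGET, 0.5), peak(APICAL, 1.5))
        assert m.accepted
        assert m.ratio == 0.0

    def test_misordered_target_rejected(self):
        m = compute_positional_ratio(peak(BASAL, 0.0), peak(TARGET, 1.2), peak(APICAL, 1.0))
        assert m.qc_status == "rejected"
        assert m.reason == "misordered"

    def test_degenerate_separation_rejected(self):
        m = compute_positional_ratio(
            peak(BASAL, 0.50), peak(TARGET, 0.51), peak(APICAL, 0.52),
            min_separation_um=0.1,
        )
        assert m.reason == "degenerate"

    def test_reversed_axis_is_symmetric(self):
        """A profile drawn apical→basal gives the same ratio."""
        m = compute_positional_ratio(peak(BASAL, 2.0), peak(TARGET, 1.4), peak(APICAL, 0.0))
        assert m.accepted
        assert m.ratio == pytest.approx(0.3)

    def test_peaks_from_different_lines_rejected(self):
        with pytest.raises(MismatchedProfilesError):
            compute_positional_ratio(
                peak(BASAL, 0.0, line_id="L0"),
                peak(TARGET, 0.3, line_id="L1"),
                peak(APICAL, 1.0, line_id="L0"),
            )


class TestMeasureScene:
    def test_ground_truth_recovery(self, loop_scene_half):
        """30 perpendicular lines on a noiseless f=0.5 scene: nearly all
        accepted, mean ratio within 0.02 of truth."""
        spec, image, _ = loop_scene_half
        plan = plan_perpendicular_lines(spec, 30, np.random.default_rng(2), "s0", "ctl")
        measurements = measure_scene(image, plan)
        ratios = accepted_ratios(measurements)
        assert ratios.size >= 29
        assert abs(ratios.mean() - 0.5) <= 0.02

    def test_bad_line_is_isolated(self, loop_scene_half):
        """One line missing the loop is rejected; the others are unaffected."""
        spec, image, _ = loop_scene_half
        good = plan_perpendicular_lines(spec, 5, np.random.default_rng(3), "s0", "ctl")
        bad = PlannedLine("s0", "bad", "ctl", (3.0, 3.0), (10.0, 10.0), 0.5)
        out = measure_scene(image, [bad] + good, QCParams(check_alignment=False))
        assert out[0].qc_status == "rejected"
        assert out[0].reason in ("no_peak", "line_out_of_bounds")
        assert all(m.accepted for m in out[1:])

    def test_rerun_is_deterministic(self, loop_scene_half):
        spec, image, _ = loop_scene_half
        plan = plan_perpendicular_lines(spec, 10, np.random.default_rng(4), "s0", "ctl")
        m1 = measure_scene(image, plan)
        m2 = measure_scene(image, plan)
        assert [(m.line_id, m.ratio, m.qc_status) for m in m1] == [
            (m.line_id, m.ratio, m.qc_status) for m in m2
        ]

    def test_intensity_scale_invariance(self, loop_scene_half):
        """Multiplying all channels by a positive constant leaves every
        accepted ratio unchanged."""
        spec, image, _ = loop_scene_half
        plan = plan_perpendicular_lines(spec, 10, np.random.default_rng(5), "s0", "ctl")
        base = accepted_ratios(measure_scene(image, plan))
        scaled = type(image)(
            {k: 3.7 * v for k, v in image.channels.items()}, image.pixel_size
        )
        np.testing.assert_allclose(
            accepted_ratios(measure_scene(scaled, plan)), base, atol=1e-12
        )

    def test_accepted_ratios_bounded(self, noisy_spec):
        """Accepted ratios stay in [0, 1] on noisy lines (QC enforced)."""
        ratios = []
        for seed in range(6):
            spec = noisy_spec(0.5, seed=seed)
            image, _ = generate_loop_scene(spec)
            plan = plan_perpendicular_lines(
                spec, 50, np.random.default_rng(seed), f"s{seed}", "g"
            )
            ratios.append(accepted_ratios(measure_scene(image, plan)))
        ratios = np.concatenate(ratios)
        assert ratios.size > 100
        assert np.all((ratios >= 0.0) & (ratios <= 1.0))

    def test_translation_along_line_direction(self, loop_scene_half):
        """Sliding the segment along its own direction (all bands still
        covered) barely changes the ratio."""
        spec, image, _ = loop_scene_half
        [line] = plan_perpendicular_lines(
            spec, 1, np.random.default_rng(6), "s0", "g", half_length_um=1.2
        )
        direction = (np.asarray(line.p1) - np.asarray(line.p0))
        direction = direction / np.hypot(*direction)
        shift = 0.1 / spec.pixel_size * direction  # 0.1 µm slide
        shifted = PlannedLine(
            "s0", "shifted", "g",
            tuple(np.asarray(line.p0) + shift), tuple(np.asarray(line.p1) + shift), line.step,
        )
        r0 = measure_scene(image, [line])[0].ratio
        r1 = measure_scene(image, [shifted])[0].ratio
        assert abs(r0 - r1) < 0.01
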