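"""Reproducible end-to-end pipeline: simulate → QC → profiles → ratios →
group comparison, with TIFF/CSV/YAML I/O and a manifest that records the
configuration, seed and software version of every run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .errors import InvalidSpecError, MissingChannelError
from .ratio import QCParams, accepted_ratios, measure_scene
from .scenes import (
    CircleCenterline,
    LoopSceneSpec,
    NoiseModel,
    PlannedLine,
    generate_group_experiment,
)
from .stats import mann_whitney_u, mean_sem, significance_flag, t_test
from .types import MultiChannelImage, SceneGroundTruth

log = logging.getLogger("podoquant")

# ---------------------------------------------------------------------------
# image I/O
# ---------------------------------------------------------------------------


def save_scene(
    image: MultiChannelImage,
    truth: Optional[SceneGroundTruth],
    out_dir: Union[str, Path],
    scene_id: str,
) -> Path:
    """Write a scene as a multi-page 16-bit TIFF (one channel per page, role
    order recorded in the image description) plus a JSON ground-truth sidecar.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    roles = list(image.channels)
    stack = np.stack(
        [np.clip(np.round(image.channels[r]), 0, 65535).astype(np.uint16) for r in roles]
    )
    meta = {"channel_roles": roles, "pixel_size_um": image.pixel_size}
    tif_path = out_dir / f"{scene_id}.tif"
    tifffile.imwrite(
        tif_path, stack, photometric="minisblack", description=json.dumps(meta)
    )
    if truth is not None:
        sidecar = {
            "marker_depth_fractions": truth.marker_depth_fractions,
            "wall_thickness_um": truth.wall_thickness,
            "junction_fraction": truth.junction_fraction,
            "junction_positions_um": (
                truth.junction_positions.tolist()
                if truth.junction_positions is not None else None
            ),
            "foot_process_widths_um": (
                truth.foot_process_widths.tolist()
                if truth.foot_process_widths is not None else None
            ),
        }
        (out_dir / f"{scene_id}.truth.json").write_text(json.dumps(sidecar, indent=2))
    return tif_path


def load_image(
    path: Union[str, Path],
    channel_map: Optional[Dict[str, int]] = None,
    pixel_size: Optional[float] = None,
) -> MultiChannelImage:
    """Read a multi-page TIFF into a role-keyed image.

    Channel roles come from ``channel_map`` (role → page index) or, absent
    that, from the writer's image description. Pixel size from an explicit
    argument/config wins over file metadata (a warning is logged when both
    are present and disagree).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        desc = tif.pages[0].description
    pages = [arr] if arr.ndim == 2 else [arr[i] for i in range(arr.shape[0])]
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if channel_map is None:
        roles = meta.get("channel_roles")
        if not roles:
            raise MissingChannelError("no channel_map given and no roles in metadata")
        channel_map = {role: i for i, role in enumerate(roles)}
    channels = {}
    for role, idx in channel_map.items():
        if idx >= len(pages):
            raise MissingChannelError(
                f"role {role!r} maps to page {idx} but file has {len(pages)} pages"
            )
        channels[role] = pages[idx].astype(np.float64)
    meta_px = meta.get("pixel_size_um")
    if pixel_size is not None:
        if meta_px is not None and not np.isclose(meta_px, pixel_size):
            log.warning(
                "pixel size %.4g from config overrides %.4g from metadata", pixel_size, meta_px
            )
        px = pixel_size
    elif meta_px is not None:
        px = float(meta_px)
    else:
        raise InvalidSpecError("pixel size found neither in metadata nor config")
    return MultiChannelImage(channels, px, provenance=str(path))


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------

LINE_CSV_COLUMNS = ["scene_id", "line_id", "group", "p0_row", "p0_col", "p1_row", "p1_col", "step_px"]


def read_line_annotations(path: Union[str, Path]) -> List[PlannedLine]:
    df = pd.read_csv(path, float_precision="round_trip")
    lines = []
    for _, row in df.iterrows():
        lines.append(
            PlannedLine(
                scene_id=str(row["scene_id"]),
                line_id=str(row.get("line_id", f"L{_:03d}")),
                group_label=str(row.get("group", "")),
                p0=(float(row["p0_row"]), float(row["p0_col"])),
                p1=(float(row["p1_row"]), float(row["p1_col"])),
                step=float(row.get("step_px", 0.5)),
            )
        )
    return lines


def write_line_annotations(lines: List[PlannedLine], path: Union[str, Path]):
    df = pd.DataFrame(
        [
            {
                "scene_id": ln.scene_id, "line_id": ln.line_id, "group": ln.group_label,
                "p0_row": ln.p0[0], "p0_col": ln.p0[1],
                "p1_row": ln.p1[0], "p1_col": ln.p1[1], "step_px": ln.step,
            }
            for ln in lines
        ],
        columns=LINE_CSV_COLUMNS,
    )
    # %.17g round-trips IEEE doubles exactly through the CSV
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Full-experiment configuration; unknown keys are rejected on load."""

    mode: str = "full-experiment"  # simulate | ratio | coloc | morpho | full-experiment
    seed: int = 0
    out_dir: str = "results"
    image_shape: Tuple[int, int] = (256, 256)
    pixel_size: float = 0.05  # µm/px
    wall_thickness: float = 1.0  # µm
    band_sigma: float = 0.08  # µm
    control_depth_fraction: float = 0.55
    ko_depth_fraction: float = 0.35
    noise_kind: str = "none"  # none | gaussian | poisson_gaussian
    noise_sd: float = 0.0
    noise_gain: float = 1.0
    n_scenes_per_group: int = 1
    lines_per_scene: int = 30
    max_angle_deg: float = 15.0
    min_separation_steps: float = 3.0
    test: str = "mannwhitney"  # mannwhitney | t
    write_scenes: bool = False
    input_paths: List[str] = field(default_factory=list)

    @classmethod
    def from_dict(cls, d: Dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise InvalidSpecError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if isinstance(cfg.image_shape, list):
            cfg.image_shape = tuple(cfg.image_shape)
        return cfg

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def loop_spec(self, depth_fraction: float) -> LoopSceneSpec:
        rows, cols = self.image_shape
        radius = 0.31 * min(rows, cols)
        return LoopSceneSpec(
            image_shape=tuple(self.image_shape),
            pixel_size=self.pixel_size,
            centerline=CircleCenterline((rows / 2.0, cols / 2.0), radius),
            wall_thickness=self.wall_thickness,
            target_depth_fraction=depth_fraction,
            band_sigma=self.band_sigma,
            noise_model=NoiseModel(self.noise_kind, sd=self.noise_sd, gain=self.noise_gain),
            seed=self.seed,
        )

    def qc_params(self) -> QCParams:
        return QCParams(
            min_separation_steps=self.min_separation_steps,
            max_angle_deg=self.max_angle_deg,
        )


# ---------------------------------------------------------------------------
# experiment runner
# ---------------------------------------------------------------------------


@dataclass
class ExperimentResult:
    per_line: pd.DataFrame
    group_summary: pd.DataFrame
    comparison: Optional[object]
    manifest: Dict


def measurements_to_frame(measurements) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scene_id": m.scene_id, "line_id": m.line_id, "group": m.group_label,
                "a_um": m.a, "b_um": m.b, "ratio": m.ratio,
                "qc_status": m.qc_status, "reason": m.reason,
            }
            for m in measurements
        ],
        columns=["scene_id", "line_id", "group", "a_um", "b_um", "ratio", "qc_status", "reason"],
    )


def run_experiment(config: PipelineConfig, out_dir: Optional[Union[str, Path]] = None) -> ExperimentResult:
    """Simulate a two-group experiment, measure every planned line, compare
    the groups, and write per-line/summary/report CSVs plus a manifest."""
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    bundle = generate_group_experiment(
        config.loop_spec(config.control_depth_fraction),
        config.loop_spec(config.ko_depth_fraction),
        n_scenes_per_group=config.n_scenes_per_group,
        lines_per_scene=config.lines_per_scene,
        seed=config.seed,
    )
    qc = config.qc_params()
    measurements = []
    for sid, (image, _) in bundle.scenes.items():
        plan = [ln for ln in bundle.plan if ln.scene_id == sid]
        measurements.extend(measure_scene(image, plan, qc))
        if config.write_scenes:
            save_scene(image, bundle.scenes[sid][1], out / "scenes", sid)

    per_line = measurements_to_frame(measurements)
    if per_line.empty:
        log.warning("experiment produced zero measurement lines")

    groups = sorted(set(m.group_label for m in measurements if m.group_label))
    summary_rows, comparison = [], None
    by_group = {
        g: accepted_ratios([m for m in measurements if m.group_label == g]) for g in groups
    }
    for g in groups:
        vals = by_group[g]
        if vals.size >= 2:
            mu, sem = mean_sem(vals)
        else:
            mu, sem = (float(vals.mean()) if vals.size else float("nan")), float("nan")
        summary_rows.append(
            {"group": g, "n_accepted": int(vals.size), "mean_ratio": mu, "sem_ratio": sem}
        )
    group_summary = pd.DataFrame(
        summary_rows, columns=["group", "n_accepted", "mean_ratio", "sem_ratio"]
    )

    if len(groups) == 2 and all(by_group[g].size >= 2 for g in groups):
        a, b = by_group[groups[0]], by_group[groups[1]]
        if config.test == "mannwhitney":
            comparison = mann_whitney_u(a, b, group_labels=(groups[0], groups[1]))
        else:
            comparison = t_test(a, b, group_labels=(groups[0], groups[1]))

    per_line.to_csv(out / "per_line.csv", index=False)
    group_summary.to_csv(out / "group_summary.csv", index=False)
    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "software_version": __version__,
        "n_lines_planned": len(bundle.plan),
        "n_lines_accepted": int((per_line["qc_status"] == "accepted").sum()) if not per_line.empty else 0,
    }
    if comparison is not None:
        report = comparison_frame(comparison)
        report.to_csv(out / "test_report.csv", index=False)
        (out / "test_report.txt").write_text(comparison_text(comparison))
        manifest["p_value"] = comparison.p_value
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return ExperimentResult(per_line, group_summary, comparison, manifest)


def comparison_frame(c) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_a": c.group_labels[0], "group_b": c.group_labels[1],
                "n_a": c.n_per_group[0], "n_b": c.n_per_group[1],
                "statistic": c.statistic_name, "value": c.statistic_value,
                "p_value": c.p_value, "variant": c.test_variant,
                "mean_a": c.means[0], "sem_a": c.sems[0],
                "mean_b": c.means[1], "sem_b": c.sems[1],
                "significant": significance_flag(c.p_value),
            }
        ]
    )


def comparison_text(c) -> str:
    sig = "significant" if significance_flag(c.p_value) else "not significant"
    return (
        f"{c.statistic_name} test ({c.test_variant}): "
        f"{c.group_labels[0]} (n={c.n_per_group[0]}) mean±SEM = "
        f"{c.means[0]:.4f}±{c.sems[0]:.4f}; "
        f"{c.group_labels[1]} (n={c.n_per_group[1]}) mean±SEM = "
        f"{c.means[1]:.4f}±{c.sems[1]:.4f}; "
        f"{c.statistic_name} = {c.statistic_value:.4g}, P = {c.p_value:.4g} ({sig}, α=0.05)\n"
    )
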