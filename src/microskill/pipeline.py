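"""End-to-end orchestration: read -> filter -> geometry -> temporal ->
metrics, plus the microscope and comparison runs.

Stage order follows the video-analysis pipeline the metrics were designed
for: per-frame instances are confidence-filtered, each instance is reduced
to a tip and an orientation, per-class presence is cleaned by the
run-length temporal filter (suppressing short spurious runs and filling
short dropouts), the cleaned detections are linked into tracks, and the
motion/handling metrics are computed per recording.

Every run writes a manifest naming the configuration hash, so outputs are
traceable and reruns with identical inputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geometry import Detection, analyze_mask
from .io import (
    FrameRecord,
    RecordingConfig,
    read_instances,
    read_laser,
    read_metrics,
    write_coco,
    write_metrics,
)
from .kinematics import (
    KinematicSummary,
    inter_tip_distance,
    pooled_kinematic_summary,
)
from .microscope import AdjustmentReport, adjustment_metrics, extract_adjustment_events
from .stats import compare_groups
from .temporal import (
    PresenceSeries,
    ToolTrack,
    filter_by_confidence,
    link_instances_to_tracks,
    smooth_presence,
)

__all__ = [
    "PipelineConfig",
    "AnalysisResult",
    "analyze_frames",
    "run_analyze",
    "run_scope",
    "run_compare",
    "run_simulate",
    "parse_scene_spec",
]

#: Canonical metric names in report order: 11 tool metrics.
TOOL_METRICS = (
    "mean_velocity",
    "sd_velocity",
    "mean_acceleration",
    "sd_acceleration",
    "mean_jerk",
    "sd_jerk",
    "path_length",
    "normalized_angular_displacement",
    "idle_fraction",
    "bimanual_fraction",
    "mean_inter_tip_distance",
)
MICROSCOPE_METRICS = ("n_adjustments", "max_interval_s", "median_interval_s")


@dataclass
class PipelineConfig:
    """Everything that, together with the inputs, determines a run."""

    recording: RecordingConfig = field(default_factory=RecordingConfig)
    seed: int = 0
    output_format: str = "csv"

    def as_dict(self) -> dict:
        return {
            "recording": dataclasses.asdict(self.recording),
            "seed": self.seed,
            "output_format": self.output_format,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:8]

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            if path.suffix.lower() in (".yaml", ".yml"):
                import yaml

                doc = yaml.safe_load(fh)
            else:
                doc = json.load(fh)
        rec = RecordingConfig(**doc.get("recording", {}))
        return cls(
            recording=rec,
            seed=int(doc.get("seed", 0)),
            output_format=doc.get("output_format", "csv"),
        )


@dataclass
class AnalysisResult:
    """Everything one recording analysis produces."""

    detections: list[list[Detection]]
    tracks: list[ToolTrack]
    kinematics: KinematicSummary
    idle_fraction: float
    bimanual_fraction: float
    mean_inter_tip_distance: float | None
    duration_s: float
    presence_raw: dict[str, np.ndarray]
    presence_smoothed: dict[str, np.ndarray]
    stage_counts: dict[str, int]

    def metrics_row(self) -> dict[str, float | None]:
        row = self.kinematics.as_dict()
        row["idle_fraction"] = self.idle_fraction
        row["bimanual_fraction"] = self.bimanual_fraction
        row["mean_inter_tip_distance"] = self.mean_inter_tip_distance
        pl = row.get("path_length")
        # Raw path length is in px over the whole segment; the per-second
        # rate is also reported since segment durations differ.
        row["path_length_per_s"] = (
            pl / self.duration_s if pl is not None and self.duration_s > 0 else None
        )
        return row


def analyze_frames(
    frames: list[FrameRecord], config: RecordingConfig
) -> AnalysisResult:
    """Run the full per-recording tool analysis on in-memory frames."""
    n = len(frames)
    filtered = filter_by_confidence(frames, config.score_threshold)
    n_inst_raw = sum(len(f.instances) for f in frames)
    n_inst_kept = sum(len(f.instances) for f in filtered)

    # Per-instance geometry.
    detections: list[list[Detection]] = []
    for f in filtered:
        dets = []
        for inst in f.instances:
            tip, theta = analyze_mask(
                inst.mask, config.shape, spur_px=config.spur_px
            )
            dets.append(
                Detection(
                    frame_index=f.frame_index,
                    tool_class=inst.tool_class,
                    score=inst.score,
                    x=tip[0],
                    y=tip[1],
                    theta=theta,
                )
            )
        detections.append(dets)

    # Temporal cleaning: per-class presence smoothing gates detections.
    classes = sorted({d.tool_class for dets in detections for d in dets})
    presence_raw: dict[str, np.ndarray] = {}
    presence_smoothed: dict[str, np.ndarray] = {}
    for cls in classes:
        raw = np.array(
            [any(d.tool_class == cls for d in dets) for dets in detections],
            dtype=bool,
        )
        presence_raw[cls] = raw
        presence_smoothed[cls] = smooth_presence(
            raw, config.min_on_frames, config.min_off_frames
        )
    gated: list[list[Detection]] = [
        [d for d in dets if presence_smoothed[d.tool_class][i]]
        for i, dets in enumerate(detections)
    ]

    # Effective per-frame tool count: detected instances of each class, or
    # one when the smoothed presence bridges a dropout frame.
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        for cls in classes:
            n_cls = sum(1 for d in gated[i] if d.tool_class == cls)
            if presence_smoothed[cls][i]:
                n_cls = max(n_cls, 1)
            counts[i] += n_cls

    idle = float((counts == 0).mean()) if n else 1.0
    bimanual = float((counts >= 2).mean()) if n else 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ttd = inter_tip_distance(gated)

    tracks = link_instances_to_tracks(
        gated, config.max_gap_frames, config.max_jump_px
    )
    kin = pooled_kinematic_summary(tracks, config.dt, signed=config.signed)

    return AnalysisResult(
        detections=gated,
        tracks=tracks,
        kinematics=kin,
        idle_fraction=idle,
        bimanual_fraction=bimanual,
        mean_inter_tip_distance=ttd,
        duration_s=n / config.fps,
        presence_raw=presence_raw,
        presence_smoothed=presence_smoothed,
        stage_counts={
            "frames": n,
            "instances_raw": n_inst_raw,
            "instances_confident": n_inst_kept,
            "instances_gated": sum(len(d) for d in gated),
            "tracks": len(tracks),
        },
    )


def _write_manifest(
    out_dir: Path, config: PipelineConfig, extra: dict
) -> Path:
    manifest = {
        "config": config.as_dict(),
        "config_hash": config.config_hash(),
        "package_version": __version__,
        **extra,
    }
    path = out_dir / f"manifest_{config.config_hash()}.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=_jsonable)
        fh.write("\n")
    return path


def _input_ref(path: str | Path) -> dict:
    """Manifest reference to an input: file name plus content hash (not the
    absolute path, so identical runs are byte-identical wherever they live)."""
    path = Path(path)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
    return {"name": path.name, "sha256": digest}


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.astype(int).tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_analyze(
    config: PipelineConfig,
    instance_path: str | Path,
    out_dir: str | Path,
    recording_id: str = "recording",
    input_format: str = "coco_json",
    n_frames: int | None = None,
) -> AnalysisResult:
    """Analyse one recording's instance file and write metrics + manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = read_instances(instance_path, format=input_format, n_frames=n_frames)
    if not any(f.instances for f in frames):
        warnings.warn(
            f"{instance_path}: no instances; metrics will be undefined",
            RuntimeWarning,
            stacklevel=2,
        )
    result = analyze_frames(frames, config.recording)
    row = result.metrics_row()
    ext = "json" if config.output_format == "json" else "csv"
    metrics_path = out_dir / f"metrics_{config.config_hash()}.{ext}"
    write_metrics({recording_id: row}, metrics_path, format=config.output_format)
    _write_manifest(
        out_dir,
        config,
        {
            "stage_counts": result.stage_counts,
            "inputs": {"instances": _input_ref(instance_path)},
            "outputs": [metrics_path.name],
            "presence_raw": {k: v for k, v in result.presence_raw.items()},
            "presence_smoothed": {
                k: v for k, v in result.presence_smoothed.items()
            },
        },
    )
    return result


def run_scope(
    config: PipelineConfig,
    laser_path: str | Path,
    out_dir: str | Path,
    recording_id: str = "recording",
) -> AdjustmentReport:
    """Laser presence file -> adjustment metrics file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rc = config.recording
    series = PresenceSeries(values=read_laser(laser_path), fps=rc.fps)
    events = extract_adjustment_events(
        series, rc.min_on_frames, rc.min_off_frames
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        report = adjustment_metrics(events, window_s=rc.window_s)
    ext = "json" if config.output_format == "json" else "csv"
    path = out_dir / f"scope_{config.config_hash()}.{ext}"
    write_metrics({recording_id: report.as_dict()}, path, config.output_format)
    _write_manifest(
        out_dir,
        config,
        {
            "stage_counts": {
                "frames": len(series),
                "events": len(events),
            },
            "inputs": {"laser": _input_ref(laser_path)},
            "outputs": [path.name],
        },
    )
    return report


def run_compare(
    config: PipelineConfig,
    metrics_a: str | Path,
    metrics_b: str | Path,
    out_dir: str | Path,
    labels: tuple[str, str] = ("expert", "novice"),
    method: str = "auto",
    plot: bool = False,
) -> pd.DataFrame:
    """Two metric files -> per-metric median/U/p comparison table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = []
    for path, label in ((metrics_a, labels[0]), (metrics_b, labels[1])):
        table = pd.DataFrame.from_dict(read_metrics(path), orient="index")
        table["group"] = label
        frames.append(table)
    table = pd.concat(frames)
    metrics = [c for c in table.columns if c != "group"]
    rows = compare_groups(table, group_col="group", metrics=metrics, method=method)
    out = pd.DataFrame([r.as_dict() for r in rows])
    out = out.rename(
        columns={"median_a": f"median_{labels[0]}", "median_b": f"median_{labels[1]}"}
    )
    ext = "json" if config.output_format == "json" else "csv"
    path = out_dir / f"comparison_{config.config_hash()}.{ext}"
    if ext == "json":
        out.to_json(path, orient="records", indent=1)
    else:
        out.to_csv(path, index=False)
    if plot:
        _boxplots(table, metrics, out_dir, config.config_hash())
    _write_manifest(
        out_dir,
        config,
        {
            "inputs": {"metrics_a": _input_ref(metrics_a), "metrics_b": _input_ref(metrics_b)},
            "outputs": [path.name],
        },
    )
    return out


def _boxplots(table: pd.DataFrame, metrics: list[str], out_dir: Path, tag: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = list(dict.fromkeys(table["group"]))
    for metric in metrics:
        data = [
            table.loc[table["group"] == g, metric].dropna().to_numpy()
            for g in groups
        ]
        if not any(len(d) for d in data):
            continue
        fig, ax = plt.subplots(figsize=(3.2, 3.2))
        ax.boxplot(data, tick_labels=groups)
        ax.set_title(metric)
        fig.tight_layout()
        fig.savefig(out_dir / f"box_{metric}_{tag}.png", dpi=100)
        plt.close(fig)


# ---------------------------------------------------------------------------
# Simulation entry point
# ---------------------------------------------------------------------------

def parse_scene_spec(doc: dict, seed: int | None = None) -> "SceneSpec":
    """Build a SceneSpec from a config-file dictionary.

    Either a full scene description (duration/tools/laser_schedule/...) or
    the shorthand ``{"skill": "expert"|"novice", ...}`` which generates a
    scripted cohort scene.
    """
    from . import synthetic as syn

    if "skill" in doc:
        return syn.make_skill_scene(
            doc["skill"],
            seed=int(doc.get("seed", 0) if seed is None else seed),
            duration=float(doc.get("duration", 15.0)),
            width=int(doc.get("width", 640)),
            height=int(doc.get("height", 480)),
            fps=float(doc.get("fps", 12.0)),
        )
    traj_types = {
        "linear": syn.LinearTrajectory,
        "circular": syn.CircularTrajectory,
        "polyline": syn.PolylineTrajectory,
        "stationary": syn.StationaryTrajectory,
    }
    tools = []
    for td in doc.get("tools", []):
        shape = syn.ToolShape(**td["shape"])
        traj_doc = dict(td["trajectory"])
        kind = traj_doc.pop("type")
        for key in ("start", "velocity", "center", "point"):
            if key in traj_doc:
                traj_doc[key] = tuple(traj_doc[key])
        if "points" in traj_doc:
            traj_doc["points"] = tuple(tuple(p) for p in traj_doc["points"])
        traj = traj_types[kind](**traj_doc)
        tools.append(
            syn.ToolScript(
                tool_class=td["tool_class"],
                shape=shape,
                trajectory=traj,
                presence=[tuple(w) for w in td.get("presence", [])],
                tremor_px=float(td.get("tremor_px", 0.0)),
            )
        )
    return syn.SceneSpec(
        duration=float(doc["duration"]),
        tools=tools,
        laser_schedule=[tuple(w) for w in doc.get("laser_schedule", [])],
        width=int(doc.get("width", 640)),
        height=int(doc.get("height", 480)),
        fps=float(doc.get("fps", 12.0)),
        seed=int(doc.get("seed", 0) if seed is None else seed),
    )


def run_simulate(
    spec_path: str | Path,
    out_dir: str | Path,
    seed: int | None = None,
    write_masks: bool = False,
) -> "SceneData":
    """Generate a synthetic scene from a spec file and write its outputs:
    COCO instance JSON, laser CSV, ground-truth JSON, and (optionally)
    per-frame label PNGs."""
    spec_path = Path(spec_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(spec_path) as fh:
        if spec_path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            doc = yaml.safe_load(fh)
        else:
            doc = json.load(fh)
    from .synthetic import generate_scene

    spec = parse_scene_spec(doc, seed=seed)
    scene = generate_scene(spec)

    write_coco(
        scene.frames, out_dir / "instances.json", spec.width, spec.height
    )
    with open(out_dir / "laser.csv", "w") as fh:
        fh.write("frame,flag\n")
        for i, flag in enumerate(scene.laser):
            fh.write(f"{i},{int(flag)}\n")
    truth = scene.truth
    gt_doc = {
        "tool_classes": truth.tool_classes,
        "fps": truth.fps,
        "tips": [
            [None if np.isnan(p[0]) else [float(p[0]), float(p[1])] for p in tool]
            for tool in truth.tips
        ],
        "theta": [
            [None if np.isnan(v) else float(v) for v in tool]
            for tool in truth.theta
        ],
        "present": truth.present.astype(int).tolist(),
        "overlap": truth.overlap.astype(int).tolist(),
        "laser": truth.laser.astype(int).tolist(),
    }
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(gt_doc, fh)
        fh.write("\n")

    if write_masks:
        import imageio.v3 as iio

        mask_dir = out_dir / "masks"
        mask_dir.mkdir(exist_ok=True)
        classmap = {
            str(i + 1): cls for i, cls in enumerate(truth.tool_classes)
        }
        with open(mask_dir / "classmap.json", "w") as fh:
            json.dump(classmap, fh)
        cls_value = {cls: i + 1 for i, cls in enumerate(truth.tool_classes)}
        for rec in scene.frames:
            label = np.zeros((spec.height, spec.width), dtype=np.uint8)
            for inst in rec.instances:
                label[inst.mask] = cls_value[inst.tool_class]
            iio.imwrite(
                mask_dir / f"frame_{rec.frame_index:06d}.png", label
            )
    return scene
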