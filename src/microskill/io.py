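"""Data model and file formats for per-frame tool instance streams.

The pipeline operates on per-frame instance segmentations of five
micro-neurosurgical tools plus an optional per-frame laser-dot presence
channel.  Instances arrive either as COCO-style instance-segmentation JSON
(polygon or uncompressed RLE masks) or as 8-bit label PNGs with a sidecar
class map.  Coordinates are 0-based pixel indices, origin at the top-left,
x rightward, y downward.
"""

from __future__ import annotations

import csv
import json
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "TOOL_CLASSES",
    "normalize_class_name",
    "InstanceMask",
    "FrameRecord",
    "RecordingConfig",
    "read_instances",
    "read_laser",
    "write_metrics",
    "read_metrics",
    "rle_encode",
    "rle_decode",
    "polygon_to_mask",
    "write_coco",
]

#: Canonical labels of the five instruments the segmentation model emits.
TOOL_CLASSES = (
    "Bipolar Forceps",
    "Suction",
    "Straight Microscissors",
    "Straight Needle Holder",
    "Dural Tooth Forceps",
)

# The source material spells some instruments inconsistently; normalise to
# the canonical five labels.
_CLASS_ALIASES = {
    "bipolar forceps": "Bipolar Forceps",
    "suction": "Suction",
    "straight microscissors": "Straight Microscissors",
    "straight micro scissor": "Straight Microscissors",
    "straight micro scissors": "Straight Microscissors",
    "straight microscissor": "Straight Microscissors",
    "microscissors": "Straight Microscissors",
    "straight needle holder": "Straight Needle Holder",
    "needle holder": "Straight Needle Holder",
    "dural tooth forceps": "Dural Tooth Forceps",
    "dural toothed forceps": "Dural Tooth Forceps",
}


def normalize_class_name(name: str) -> str:
    """Map a (possibly variant) instrument label to its canonical form.

    Raises ``ValueError`` for labels that match none of the known tools.
    """
    key = re.sub(r"\s+", " ", name.strip().lower())
    try:
        return _CLASS_ALIASES[key]
    except KeyError:
        raise ValueError(f"unknown tool class {name!r}") from None


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class InstanceMask:
    """One detected tool instance in one frame."""

    frame_index: int
    tool_class: str
    score: float
    mask: np.ndarray  # bool, H x W

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be a 2-D raster")
        if not self.mask.any():
            raise ValueError("instance mask has no foreground pixels")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class FrameRecord:
    """All instances detected in one frame, plus the laser channel."""

    frame_index: int
    instances: list[InstanceMask] = field(default_factory=list)
    laser_on: bool | None = None

    def timestamp_s(self, fps: float) -> float:
        return self.frame_index / fps


@dataclass
class RecordingConfig:
    """Geometry, timing and filter parameters of one recording.

    ``fps`` is the *extracted* frame rate (frames are assumed already
    resampled upstream); ``dt = 1/fps`` is the time step used by every
    kinematic derivative.
    """

    fps: float = 12.0
    width: int = 640
    height: int = 480
    score_threshold: float = 0.5
    min_on_frames: int = 3
    min_off_frames: int = 3
    max_gap_frames: int = 3
    max_jump_px: float = 60.0
    spur_px: int = 5
    signed: bool = False
    window_s: float = 3000.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("frame dimensions must be positive")
        if not 0.0 <= self.score_threshold <= 1.0:
            raise ValueError("score_threshold outside [0, 1]")

    @property
    def dt(self) -> float:
        return 1.0 / self.fps

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)


# ---------------------------------------------------------------------------
# Mask codecs
# ---------------------------------------------------------------------------

def rle_encode(mask: np.ndarray) -> dict:
    """Encode a binary mask as COCO uncompressed RLE.

    Counts are column-major (Fortran order) and start with the number of
    leading zeros, following the COCO convention.
    """
    mask = np.asarray(mask, dtype=bool)
    flat = mask.ravel(order="F").astype(np.int8)
    changes = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate(([0], changes, [flat.size]))
    counts = np.diff(bounds).tolist()
    if flat.size and flat[0] == 1:
        counts = [0] + counts
    return {"size": [int(mask.shape[0]), int(mask.shape[1])], "counts": counts}


def rle_decode(rle: Mapping) -> np.ndarray:
    """Decode COCO uncompressed RLE to a boolean raster."""
    h, w = rle["size"]
    counts = rle["counts"]
    if not isinstance(counts, (list, tuple)):
        raise FormatError(
            "compressed RLE strings are not supported; use uncompressed "
            "counts lists or polygons"
        )
    total = int(sum(counts))
    if total != h * w:
        raise FormatError(f"RLE counts sum to {total}, expected {h * w}")
    flat = np.zeros(h * w, dtype=bool)
    pos = 0
    val = False
    for c in counts:
        if val:
            flat[pos : pos + c] = True
        pos += c
        val = not val
    return flat.reshape((h, w), order="F")


def polygon_to_mask(
    polygons: Sequence[Sequence[float]], height: int, width: int
) -> np.ndarray:
    """Rasterise COCO polygon segmentation (flat [x0,y0,x1,y1,...] lists).

    COCO coordinates live on the pixel-corner grid: a pixel belongs to the
    polygon when its centre lies inside, so a 10x10 axis-aligned square
    decodes to exactly 100 pixels.  The half-pixel shift maps that
    convention onto skimage's centre-based rasteriser.
    """
    from skimage.draw import polygon as draw_polygon

    mask = np.zeros((height, width), dtype=bool)
    for poly in polygons:
        xs = np.asarray(poly[0::2], dtype=float) - 0.5
        ys = np.asarray(poly[1::2], dtype=float) - 0.5
        rr, cc = draw_polygon(ys, xs, shape=(height, width))
        mask[rr, cc] = True
    return mask


def _decode_segmentation(seg, height: int, width: int) -> np.ndarray:
    if isinstance(seg, Mapping):
        mask = rle_decode(seg)
        if mask.shape != (height, width):
            raise FormatError(
                f"mask size {mask.shape} does not match frame {(height, width)}"
            )
        return mask
    return polygon_to_mask(seg, height, width)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_instances(
    path: str | Path,
    format: str = "coco_json",
    n_frames: int | None = None,
) -> list[FrameRecord]:
    """Read per-frame instances into a contiguous list of ``FrameRecord``.

    Frames absent from the input are materialised as empty records so the
    output always covers indices ``0 .. n_frames-1`` contiguously.  For
    ``coco_json`` the frame count defaults to the number of declared images;
    for ``label_png_dir`` to the number of PNGs.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "coco_json":
        frames = _read_coco(path)
    elif format == "label_png_dir":
        frames = _read_label_pngs(path)
    else:
        raise ValueError(f"unknown format {format!r}")

    count = n_frames
    if count is None:
        count = (max(frames) + 1) if frames else 0
    out = []
    for i in range(count):
        rec = frames.get(i, FrameRecord(frame_index=i))
        out.append(rec)
    return out


def _read_coco(path: Path) -> dict[int, FrameRecord]:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"malformed JSON in {path}: {exc}") from exc

    categories = {}
    for cat in doc.get("categories", []):
        categories[cat["id"]] = normalize_class_name(cat["name"])

    images = {}
    for img in doc.get("images", []):
        idx = img.get("frame_index", img["id"])
        images[img["id"]] = (int(idx), int(img["height"]), int(img["width"]))

    frames: dict[int, FrameRecord] = {
        idx: FrameRecord(frame_index=idx) for idx, _, _ in images.values()
    }
    for ann in doc.get("annotations", []):
        try:
            frame_idx, h, w = images[ann["image_id"]]
            mask = _decode_segmentation(ann["segmentation"], h, w)
            inst = InstanceMask(
                frame_index=frame_idx,
                tool_class=categories[ann["category_id"]],
                score=float(ann.get("score", 1.0)),
                mask=mask,
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise FormatError(
                f"bad annotation id={ann.get('id')!r} in {path}: {exc}"
            ) from exc
        frames.setdefault(frame_idx, FrameRecord(frame_index=frame_idx))
        frames[frame_idx].instances.append(inst)
    return frames


def _read_label_pngs(path: Path) -> dict[int, FrameRecord]:
    import imageio.v3 as iio

    classmap_path = path / "classmap.json"
    if not classmap_path.exists():
        raise FormatError(f"missing sidecar class map {classmap_path}")
    with open(classmap_path) as fh:
        raw_map = json.load(fh)
    classmap = {int(k): normalize_class_name(v) for k, v in raw_map.items()}

    frames: dict[int, FrameRecord] = {}
    for png in sorted(path.glob("*.png")):
        m = re.search(r"(\d+)", png.stem)
        if m is None:
            raise FormatError(f"cannot parse frame index from {png.name}")
        idx = int(m.group(1))
        label = iio.imread(png)
        if label.ndim != 2:
            raise FormatError(f"{png.name}: label PNG must be single-channel")
        rec = FrameRecord(frame_index=idx)
        for value in np.unique(label):
            if value == 0:
                continue
            if int(value) not in classmap:
                raise FormatError(f"{png.name}: label {value} not in class map")
            rec.instances.append(
                InstanceMask(
                    frame_index=idx,
                    tool_class=classmap[int(value)],
                    score=1.0,
                    mask=label == value,
                )
            )
        frames[idx] = rec
    return frames


def read_laser(path: str | Path, n_frames: int | None = None) -> np.ndarray:
    """Read a laser-dot presence series.

    Accepts CSV with ``frame,flag`` columns, a JSON list of booleans/0-1, or
    a JSON list of per-frame detection-box lists (one or more boxes in a
    frame means the laser is on — presence is all the downstream metrics
    use).
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            doc = json.load(fh)
        values = [bool(v) if not isinstance(v, list) else len(v) > 0 for v in doc]
        series = np.asarray(values, dtype=bool)
    else:
        flags: dict[int, bool] = {}
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            rows = list(reader)
        start = 1 if rows and not rows[0][0].strip().lstrip("-").isdigit() else 0
        for row in rows[start:]:
            if not row:
                continue
            flags[int(row[0])] = bool(int(float(row[1])))
        count = (max(flags) + 1) if flags else 0
        series = np.zeros(count, dtype=bool)
        for idx, val in flags.items():
            series[idx] = val
    if n_frames is not None:
        out = np.zeros(n_frames, dtype=bool)
        out[: min(n_frames, series.size)] = series[:n_frames]
        series = out
    return series


# ---------------------------------------------------------------------------
# Metric tables
# ---------------------------------------------------------------------------

def write_metrics(
    results: Mapping[str, Mapping[str, float | None]],
    path: str | Path,
    format: str = "csv",
) -> None:
    """Write per-recording metrics, one row per (recording, metric).

    ``results`` maps recording id -> {metric name -> value}; ``None`` marks
    a metric undefined for that recording and round-trips as an empty cell
    (CSV) or ``null`` (JSON).
    """
    path = Path(path)
    if format == "json":
        doc = {
            rid: {k: (None if v is None else float(v)) for k, v in row.items()}
            for rid, row in results.items()
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["recording", "metric", "value"])
            for rid, row in results.items():
                for name, value in row.items():
                    writer.writerow(
                        [rid, name, "" if value is None else repr(float(value))]
                    )
    else:
        raise ValueError(f"unknown format {format!r}")


def read_metrics(path: str | Path) -> dict[str, dict[str, float | None]]:
    """Inverse of :func:`write_metrics` (format inferred from extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            doc = json.load(fh)
        return {
            rid: {k: (None if v is None else float(v)) for k, v in row.items()}
            for rid, row in doc.items()
        }
    out: dict[str, dict[str, float | None]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            value = row["value"]
            out.setdefault(row["recording"], {})[row["metric"]] = (
                None if value == "" else float(value)
            )
    return out


# ---------------------------------------------------------------------------
# COCO writer (used by the simulator and for round-trip tests)
# ---------------------------------------------------------------------------

def write_coco(
    frames: Iterable[FrameRecord],
    path: str | Path,
    width: int,
    height: int,
) -> None:
    """Serialise frames as COCO-style instance-segmentation JSON."""
    frames = list(frames)
    cat_ids = {name: i + 1 for i, name in enumerate(TOOL_CLASSES)}
    images = []
    annotations = []
    ann_id = 1
    for rec in frames:
        images.append(
            {
                "id": rec.frame_index + 1,
                "frame_index": rec.frame_index,
                "file_name": f"frame_{rec.frame_index:06d}.png",
                "width": width,
                "height": height,
            }
        )
        for inst in rec.instances:
            seg = rle_encode(inst.mask)
            ys, xs = np.nonzero(inst.mask)
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": rec.frame_index + 1,
                    "category_id": cat_ids[inst.tool_class],
                    "segmentation": seg,
                    "score": float(inst.score),
                    "area": int(inst.mask.sum()),
                    "bbox": [
                        float(xs.min()),
                        float(ys.min()),
                        float(xs.max() - xs.min() + 1),
                        float(ys.max() - ys.min() + 1),
                    ],
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [
            {"id": cid, "name": name} for name, cid in cat_ids.items()
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
        fh.write("\n")
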