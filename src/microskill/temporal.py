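"""Temporal cleaning of per-frame detection streams and track linking.

Frame-wise segmentation of video produces flicker: spurious short-lived
detections and brief dropouts of genuinely present tools.  A two-parameter
run-length filter repairs both — short off-runs flanked by on-runs are
filled first, then short on-runs are deleted — standing in for heavier
video post-processing while keeping exactly specified semantics.  A greedy
nearest-tip linker then assembles per-instance geometry results into
per-tool tracks, using an optimal per-frame assignment when two same-class
instances coexist (bimanual handling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import Detection
from .io import FrameRecord

__all__ = [
    "PresenceSeries",
    "TrackSample",
    "ToolTrack",
    "filter_by_confidence",
    "smooth_presence",
    "presence_from_frames",
    "link_instances_to_tracks",
]


@dataclass
class PresenceSeries:
    """Boolean per-frame presence of one channel (a tool class or laser)."""

    values: np.ndarray
    fps: float = 12.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class TrackSample:
    frame_index: int
    x: float
    y: float
    theta: float | None
    score: float


@dataclass
class ToolTrack:
    """Time-ordered tip/orientation samples of one tool; may contain gaps."""

    tool_class: str
    samples: list[TrackSample] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = [s.frame_index for s in self.samples]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("track frame indices must be strictly increasing")

    @property
    def frame_indices(self) -> np.ndarray:
        return np.array([s.frame_index for s in self.samples], dtype=int)

    @property
    def positions(self) -> np.ndarray:
        return np.array([(s.x, s.y) for s in self.samples], dtype=float)

    def __len__(self) -> int:
        return len(self.samples)


def filter_by_confidence(
    frames: list[FrameRecord], min_score: float
) -> list[FrameRecord]:
    """Drop instances scoring below ``min_score``; frame structure kept."""
    if not 0.0 <= min_score <= 1.0:
        raise ValueError("min_score outside [0, 1]")
    return [
        FrameRecord(
            frame_index=f.frame_index,
            instances=[i for i in f.instances if i.score >= min_score],
            laser_on=f.laser_on,
        )
        for f in frames
    ]


def _runs(values: np.ndarray) -> list[tuple[int, int, bool]]:
    """Run-length encode: list of (start, length, value)."""
    out = []
    n = len(values)
    i = 0
    while i < n:
        j = i
        while j < n and values[j] == values[i]:
            j += 1
        out.append((i, j - i, bool(values[i])))
        i = j
    return out


def smooth_presence(
    series: PresenceSeries | np.ndarray,
    min_on_frames: int,
    min_off_frames: int,
) -> PresenceSeries | np.ndarray:
    """Run-length temporal filter for an on/off presence series.

    First, off-runs shorter than ``min_off_frames`` that are flanked by
    on-runs on both sides are filled; then on-runs shorter than
    ``min_on_frames`` are deleted.  The operation is idempotent at fixed
    parameters.  Accepts and returns either a bare boolean array or a
    :class:`PresenceSeries`.
    """
    if min_on_frames < 1 or min_off_frames < 1:
        raise ValueError("run-length thresholds must be >= 1")
    is_series = isinstance(series, PresenceSeries)
    values = np.asarray(series.values if is_series else series, dtype=bool).copy()

    runs = _runs(values)
    for k, (start, length, val) in enumerate(runs):
        if (
            not val
            and length < min_off_frames
            and 0 < k < len(runs) - 1
        ):
            values[start : start + length] = True
    for start, length, val in _runs(values):
        if val and length < min_on_frames:
            values[start : start + length] = False

    if is_series:
        return PresenceSeries(values=values, fps=series.fps)
    return values


def presence_from_frames(
    frames: list[FrameRecord],
    tool_class: str | None = None,
    fps: float = 12.0,
) -> PresenceSeries:
    """Per-frame presence of a tool class (or of any tool if None)."""
    values = np.array(
        [
            any(
                tool_class is None or inst.tool_class == tool_class
                for inst in f.instances
            )
            for f in frames
        ],
        dtype=bool,
    )
    return PresenceSeries(values=values, fps=fps)


def link_instances_to_tracks(
    detections: list[list[Detection]],
    max_gap_frames: int = 3,
    max_jump_px: float = 60.0,
) -> list[ToolTrack]:
    """Link per-frame detections into per-tool tracks.

    Greedy per-class nearest-tip linking: within each frame and class, open
    tracks (last sample within ``max_gap_frames``) and detections are
    matched by minimum-total-distance assignment; pairs farther apart than
    ``max_jump_px`` are rejected and start new tracks.  Each track gains at
    most one sample per frame.  The result is invariant to the ordering of
    instances within a frame.
    """
    from scipy.optimize import linear_sum_assignment

    open_tracks: list[ToolTrack] = []
    done: list[ToolTrack] = []

    for frame_idx, dets in enumerate(detections):
        # Retire tracks whose gap exceeded the limit.
        still_open = []
        for tr in open_tracks:
            if frame_idx - tr.samples[-1].frame_index > max_gap_frames:
                done.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open

        by_class: dict[str, list[Detection]] = {}
        for det in sorted(dets, key=lambda d: (d.tool_class, d.y, d.x)):
            by_class.setdefault(det.tool_class, []).append(det)

        for cls, cls_dets in by_class.items():
            cands = [t for t in open_tracks if t.tool_class == cls]
            assigned: dict[int, ToolTrack] = {}
            if cands:
                cost = np.full((len(cls_dets), len(cands)), np.inf)
                for i, det in enumerate(cls_dets):
                    for j, tr in enumerate(cands):
                        last = tr.samples[-1]
                        d = float(np.hypot(det.x - last.x, det.y - last.y))
                        if d <= max_jump_px:
                            cost[i, j] = d
                finite = np.where(np.isinf(cost), max_jump_px * 1e6, cost)
                rows, cols = linear_sum_assignment(finite)
                for i, j in zip(rows, cols):
                    if np.isfinite(cost[i, j]):
                        assigned[i] = cands[j]
            for i, det in enumerate(cls_dets):
                sample = TrackSample(
                    frame_index=det.frame_index,
                    x=det.x,
                    y=det.y,
                    theta=det.theta,
                    score=det.score,
                )
                if i in assigned:
                    assigned[i].samples.append(sample)
                else:
                    tr = ToolTrack(tool_class=cls, samples=[sample])
                    open_tracks.append(tr)

    done.extend(open_tracks)
    done.sort(key=lambda t: (t.samples[0].frame_index, t.tool_class))
    return done
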