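"""Tool-motion and tool-handling metrics from tip tracks.

Implements the per-recording motion metrics used for psychomotor skill
assessment: speed, acceleration and jerk statistics of the tool tip, total
path length, angular displacement accumulated per unit path length, and the
handling metrics (idle-time fraction, bimanual fraction, inter-tip
distance).

Conventions
-----------
* Speed is ``v_i = |p(i+1) - p(i)| / dt``; acceleration and jerk are
  successive finite differences of the speed series divided by ``dt``.
  Differences are taken only between consecutive frame indices: a gap in a
  track splits the series into independent segments.
* By default the mean acceleration, mean jerk and the angular accumulation
  use magnitudes (``|a_i|``, ``|j_i|``, ``|dtheta_i|``): signed means
  telescope towards zero on any back-and-forth motion and carry no
  smoothness information.  ``signed=True`` restores the literal signed
  sums.
* Standard deviations use population normalisation (divide by N).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import Detection
from .temporal import ToolTrack

__all__ = [
    "DerivativeSeries",
    "KinematicSummary",
    "HandlingSummary",
    "track_segments",
    "derivative_series",
    "path_length",
    "normalized_angular_displacement",
    "kinematic_summary",
    "pooled_kinematic_summary",
    "handling_fractions",
    "handling_summary",
    "inter_tip_distance",
    "wrap_angle_deg",
]


@dataclass
class DerivativeSeries:
    """Finite-difference series of one order (1 = velocity ... 3 = jerk)."""

    order: int
    values: np.ndarray  # px/s^order; one entry per difference
    frame_indices: np.ndarray  # frame index of the leading sample
    dt: float


@dataclass
class KinematicSummary:
    """The per-recording (or per-track) motion metrics.

    Fields are ``None`` when the track is too short for that derivative
    order — never silently zero.  Units: px/s, px/s^2, px/s^3, px, and
    deg/(s*px) for ``normalized_angular_displacement``.
    """

    mean_velocity: float | None = None
    sd_velocity: float | None = None
    mean_acceleration: float | None = None
    sd_acceleration: float | None = None
    mean_jerk: float | None = None
    sd_jerk: float | None = None
    path_length: float | None = None
    normalized_angular_displacement: float | None = None
    n_samples: int = 0

    def as_dict(self) -> dict[str, float | None]:
        return {
            "mean_velocity": self.mean_velocity,
            "sd_velocity": self.sd_velocity,
            "mean_acceleration": self.mean_acceleration,
            "sd_acceleration": self.sd_acceleration,
            "mean_jerk": self.mean_jerk,
            "sd_jerk": self.sd_jerk,
            "path_length": self.path_length,
            "normalized_angular_displacement": self.normalized_angular_displacement,
        }


@dataclass
class HandlingSummary:
    """Idle, bimanual and inter-tip metrics for one recording."""

    idle_fraction: float
    bimanual_fraction: float
    mean_inter_tip_distance: float | None

    def __post_init__(self) -> None:
        assert 0.0 <= self.idle_fraction <= 1.0
        assert 0.0 <= self.bimanual_fraction <= 1.0
        # Idle counts 0-tool frames, bimanual counts >=2-tool frames:
        # disjoint conditions, so the fractions can never sum above 1.
        assert self.idle_fraction + self.bimanual_fraction <= 1.0 + 1e-12

    def as_dict(self) -> dict[str, float | None]:
        return {
            "idle_fraction": self.idle_fraction,
            "bimanual_fraction": self.bimanual_fraction,
            "mean_inter_tip_distance": self.mean_inter_tip_distance,
        }


def wrap_angle_deg(delta: float | np.ndarray) -> float | np.ndarray:
    """Wrap an angle difference into (-180, 180] degrees."""
    return -((-np.asarray(delta) + 180.0) % 360.0 - 180.0)


def track_segments(track: ToolTrack) -> list[list]:
    """Split a track into maximal runs of consecutive frame indices."""
    segments: list[list] = []
    for s in track.samples:
        if segments and s.frame_index == segments[-1][-1].frame_index + 1:
            segments[-1].append(s)
        else:
            segments.append([s])
    return segments


def _speed_per_segment(track: ToolTrack, dt: float) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per gap-free segment: (speeds px/s, leading frame indices)."""
    out = []
    for seg in track_segments(track):
        if len(seg) < 2:
            continue
        pos = np.array([(s.x, s.y) for s in seg])
        d = np.diff(pos, axis=0)
        v = np.hypot(d[:, 0], d[:, 1]) / dt
        idx = np.array([s.frame_index for s in seg[:-1]], dtype=int)
        out.append((v, idx))
    return out


def derivative_series(track: ToolTrack, dt: float, order: int) -> DerivativeSeries:
    """Velocity (1), acceleration (2) or jerk (3) series of a track.

    Each gap-free segment contributes independently; segments too short for
    the requested order contribute nothing.  Values are signed for orders
    2 and 3 (speed itself is non-negative); callers apply the magnitude
    convention when summarising.
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    if dt <= 0:
        raise ValueError("dt must be positive")
    values: list[np.ndarray] = []
    indices: list[np.ndarray] = []
    for v, idx in _speed_per_segment(track, dt):
        for _ in range(order - 1):
            if len(v) < 2:
                v = v[:0]
                idx = idx[:0]
                break
            v = np.diff(v) / dt
            idx = idx[:-1]
        if len(v):
            values.append(v)
            indices.append(idx)
    vals = np.concatenate(values) if values else np.empty(0)
    idxs = np.concatenate(indices) if indices else np.empty(0, dtype=int)
    return DerivativeSeries(order=order, values=vals, frame_indices=idxs, dt=dt)


def path_length(track: ToolTrack) -> float:
    """Total tip travel in px; gap-spanning pairs excluded."""
    total = 0.0
    for seg in track_segments(track):
        if len(seg) < 2:
            continue
        pos = np.array([(s.x, s.y) for s in seg])
        d = np.diff(pos, axis=0)
        total += float(np.hypot(d[:, 0], d[:, 1]).sum())
    return total


def _angular_accumulation(track: ToolTrack, dt: float, signed: bool) -> float:
    """Sum of wrapped orientation steps divided by dt, over gap-free pairs."""
    acc = 0.0
    for seg in track_segments(track):
        thetas = [(s.frame_index, s.theta) for s in seg if s.theta is not None]
        for (i0, t0), (i1, t1) in zip(thetas, thetas[1:]):
            if i1 != i0 + 1:
                continue  # orientation undefined on an intermediate frame
            step = float(wrap_angle_deg(t1 - t0))
            acc += step / dt if signed else abs(step) / dt
    return acc


def normalized_angular_displacement(
    track: ToolTrack, dt: float, signed: bool = False
) -> float | None:
    """Accumulated orientation change per unit path length, deg/(s*px).

    ``A = (sum |dtheta_i| / dt) / PL`` with each ``dtheta`` wrapped into
    (-180, 180].  Returns ``None`` (with a warning) when the path length is
    zero or no orientation pair exists.
    """
    pl = path_length(track)
    if pl == 0.0:
        warnings.warn(
            "path length is zero; normalized angular displacement undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return None
    return _angular_accumulation(track, dt, signed) / pl


def _mean_sd(values: np.ndarray, use_abs: bool) -> tuple[float, float]:
    v = np.abs(values) if use_abs else values
    mean = float(np.mean(v))
    sd = float(np.sqrt(np.mean((v - mean) ** 2)))  # population normalisation
    return mean, sd


def kinematic_summary(
    track: ToolTrack, dt: float, signed: bool = False
) -> KinematicSummary:
    """All Table-style motion metrics of one track.

    Higher-order fields are ``None`` when no gap-free run is long enough
    (jerk needs 4 consecutive samples).  ``signed=True`` uses the literal
    signed means for acceleration, jerk and angular accumulation.
    """
    out = KinematicSummary(n_samples=len(track.samples))
    v = derivative_series(track, dt, 1).values
    if len(v):
        out.mean_velocity, out.sd_velocity = _mean_sd(v, use_abs=False)
        out.path_length = path_length(track)
    a = derivative_series(track, dt, 2).values
    if len(a):
        out.mean_acceleration, out.sd_acceleration = _mean_sd(a, use_abs=not signed)
    j = derivative_series(track, dt, 3).values
    if len(j):
        out.mean_jerk, out.sd_jerk = _mean_sd(j, use_abs=not signed)
    if out.path_length and out.path_length > 0:
        out.normalized_angular_displacement = normalized_angular_displacement(
            track, dt, signed
        )
    return out


def pooled_kinematic_summary(
    tracks: list[ToolTrack], dt: float, signed: bool = False
) -> KinematicSummary:
    """Recording-level summary pooling derivative samples over all tracks.

    Path length sums over tracks; the angular accumulation is likewise
    summed and normalised by the total path length.
    """
    vs, accs, js = [], [], []
    total_pl = 0.0
    total_ang = 0.0
    n = 0
    for tr in tracks:
        n += len(tr.samples)
        vs.append(derivative_series(tr, dt, 1).values)
        accs.append(derivative_series(tr, dt, 2).values)
        js.append(derivative_series(tr, dt, 3).values)
        total_pl += path_length(tr)
        total_ang += _angular_accumulation(tr, dt, signed)
    out = KinematicSummary(n_samples=n)
    v = np.concatenate(vs) if vs else np.empty(0)
    a = np.concatenate(accs) if accs else np.empty(0)
    j = np.concatenate(js) if js else np.empty(0)
    if len(v):
        out.mean_velocity, out.sd_velocity = _mean_sd(v, use_abs=False)
        out.path_length = total_pl
    if len(a):
        out.mean_acceleration, out.sd_acceleration = _mean_sd(a, use_abs=not signed)
    if len(j):
        out.mean_jerk, out.sd_jerk = _mean_sd(j, use_abs=not signed)
    if total_pl > 0:
        out.normalized_angular_displacement = total_ang / total_pl
    return out


def handling_fractions(frames) -> tuple[float, float]:
    """(idle fraction, bimanual fraction) over post-filter frames.

    ``frames`` may be ``FrameRecord`` objects or bare per-frame instance
    lists; only the instance count per frame matters.  Idle counts frames
    with no tool, bimanual counts frames with two or more tools.
    """
    counts = [
        len(f.instances) if hasattr(f, "instances") else len(f) for f in frames
    ]
    if not counts:
        raise ValueError("handling_fractions requires at least one frame")
    n = len(counts)
    idle = sum(1 for c in counts if c == 0) / n
    bimanual = sum(1 for c in counts if c >= 2) / n
    return idle, bimanual


def inter_tip_distance(detections: list[list[Detection]]) -> float | None:
    """Mean distance between the two highest-scoring tips per frame.

    Only frames with >= 2 detections qualify; with more than two present
    the two highest-scoring instances are used (stable tie-break by
    position).  Returns ``None`` when no frame qualifies.
    """
    dists = []
    for dets in detections:
        if len(dets) < 2:
            continue
        top = sorted(dets, key=lambda d: (-d.score, d.y, d.x))[:2]
        dists.append(float(np.hypot(top[0].x - top[1].x, top[0].y - top[1].y)))
    if not dists:
        warnings.warn(
            "no frame with two tools; inter-tip distance undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return None
    return float(np.mean(dists))


def handling_summary(
    frames, detections: list[list[Detection]]
) -> HandlingSummary:
    """Bundle idle/bimanual fractions with the inter-tip distance."""
    import warnings as _w

    idle, bimanual = handling_fractions(frames)
    with _w.catch_warnings():
        _w.simplefilter("ignore", RuntimeWarning)
        ttd = inter_tip_distance(detections)
    return HandlingSummary(
        idle_fraction=idle,
        bimanual_fraction=bimanual,
        mean_inter_tip_distance=ttd,
    )
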