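"""Synthetic surgical scenes with exact ground truth.

Renders elongated tool silhouettes moving along prescribed trajectories in
640x480 frames at 12 fps — the video geometry of the intraoperative
recordings this toolkit targets — so that every downstream stage (tip
detection, orientation, temporal filtering, kinematics, cohort statistics)
can be tested against an analytic oracle instead of surgical video.

Tool templates are tapered isosceles polygons: the downstream mathematics
only needs topology and elongation, not photorealism.  All randomness flows
from one seeded generator per scene; identical specs and seeds yield
bit-identical scenes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import TOOL_CLASSES, FrameRecord, InstanceMask, normalize_class_name

__all__ = [
    "ToolShape",
    "LinearTrajectory",
    "CircularTrajectory",
    "PolylineTrajectory",
    "StationaryTrajectory",
    "ToolScript",
    "SceneSpec",
    "GroundTruth",
    "SceneData",
    "render_tool_mask",
    "generate_scene",
    "corrupt_detections",
    "schedule_to_series",
    "make_skill_scene",
    "make_skill_laser_schedule",
]


@dataclass(frozen=True)
class ToolShape:
    """Tapered elongated polygon template; the tip is the pointed end.

    ``taper`` is the fraction of the length over which the silhouette
    widens from the tip point to the full width (0 gives a rectangle whose
    tip is the midpoint of the leading edge).
    """

    length: float
    width: float
    taper: float = 0.3

    def __post_init__(self) -> None:
        if self.length <= self.width:
            raise ValueError("shape must be elongated (length > width)")
        if not 0.0 <= self.taper < 1.0:
            raise ValueError("taper must lie in [0, 1)")

    def local_polygon(self) -> np.ndarray:
        """Vertices in a local frame: tip at origin, body along +x, y up."""
        L, w, t = self.length, self.width, self.taper * self.length
        if t == 0:
            return np.array(
                [(0, w / 2), (L, w / 2), (L, -w / 2), (0, -w / 2)], float
            )
        return np.array(
            [(0.0, 0.0), (t, w / 2), (L, w / 2), (L, -w / 2), (t, -w / 2)],
            float,
        )


# ---------------------------------------------------------------------------
# Trajectories: each maps time t (s) -> (tip_x, tip_y, theta_deg) where
# theta is the pointing direction of the tip, CCW from +x with image y
# negated (mathematical convention).
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinearTrajectory:
    """Constant-velocity motion; velocity is in image coords (px/s)."""

    start: tuple[float, float]
    velocity: tuple[float, float]
    theta: float | None = None  # None: point along the motion direction

    def pose(self, t: float) -> tuple[float, float, float]:
        x = self.start[0] + self.velocity[0] * t
        y = self.start[1] + self.velocity[1] * t
        if self.theta is not None:
            th = self.theta
        else:
            th = math.degrees(math.atan2(-self.velocity[1], self.velocity[0]))
        return x, y, th % 360.0


@dataclass(frozen=True)
class CircularTrajectory:
    """Uniform circular motion; ``omega`` rad/s, CCW in the y-up frame."""

    center: tuple[float, float]
    radius: float
    omega: float
    phase: float = 0.0
    theta: float | None = None  # None: tangent direction

    def pose(self, t: float) -> tuple[float, float, float]:
        phi = self.phase + self.omega * t
        x = self.center[0] + self.radius * math.cos(phi)
        y = self.center[1] - self.radius * math.sin(phi)
        if self.theta is not None:
            th = self.theta
        else:
            th = math.degrees(phi) + (90.0 if self.omega >= 0 else -90.0)
        return x, y, th % 360.0

    @property
    def speed(self) -> float:
        return abs(self.omega) * self.radius


@dataclass(frozen=True)
class PolylineTrajectory:
    """Constant-speed motion along a polyline, looping when exhausted."""

    points: tuple[tuple[float, float], ...]
    speed: float
    theta: float | None = None  # None: segment direction
    loop: bool = True

    def _segments(self):
        pts = np.asarray(self.points, float)
        deltas = np.diff(pts, axis=0)
        lengths = np.hypot(deltas[:, 0], deltas[:, 1])
        return pts, deltas, lengths

    def pose(self, t: float) -> tuple[float, float, float]:
        pts, deltas, lengths = self._segments()
        total = float(lengths.sum())
        s = self.speed * t
        if self.loop:
            s = s % total if total > 0 else 0.0
        else:
            s = min(s, total)
        acc = 0.0
        for i, seg_len in enumerate(lengths):
            if s <= acc + seg_len or i == len(lengths) - 1:
                f = (s - acc) / seg_len if seg_len > 0 else 0.0
                x = pts[i, 0] + f * deltas[i, 0]
                y = pts[i, 1] + f * deltas[i, 1]
                if self.theta is not None:
                    th = self.theta
                else:
                    th = math.degrees(math.atan2(-deltas[i, 1], deltas[i, 0]))
                return x, y, th % 360.0
            acc += seg_len
        raise RuntimeError("unreachable")


@dataclass(frozen=True)
class StationaryTrajectory:
    """Fixed tip position, optionally rotating in place (deg/s)."""

    point: tuple[float, float]
    theta: float = 0.0
    theta_rate: float = 0.0

    def pose(self, t: float) -> tuple[float, float, float]:
        return (
            self.point[0],
            self.point[1],
            (self.theta + self.theta_rate * t) % 360.0,
        )


@dataclass
class ToolScript:
    """One scripted tool: class, silhouette, pose path, visibility windows.

    ``tremor_px`` adds i.i.d. Gaussian per-frame displacement to the true
    pose (real motion, reflected in the ground truth), emulating unsteady
    handling.
    """

    tool_class: str
    shape: ToolShape
    trajectory: object
    presence: list[tuple[float, float]] = field(default_factory=list)
    tremor_px: float = 0.0

    def __post_init__(self) -> None:
        self.tool_class = normalize_class_name(self.tool_class)
        windows = sorted(self.presence)
        for (a0, a1), (b0, b1) in zip(windows, windows[1:]):
            if b0 < a1:
                raise ValueError("presence windows overlap")
        for a0, a1 in windows:
            if a1 <= a0:
                raise ValueError("empty presence window")

    def visible(self, t: float) -> bool:
        return any(a <= t < b for a, b in self.presence)


@dataclass
class SceneSpec:
    """Full description of one synthetic recording."""

    duration: float
    tools: list[ToolScript] = field(default_factory=list)
    laser_schedule: list[tuple[float, float]] = field(default_factory=list)
    width: int = 640
    height: int = 480
    fps: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0 or self.fps <= 0:
            raise ValueError("invalid frame geometry or fps")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        sched = sorted(self.laser_schedule)
        for (a0, a1), (b0, b1) in zip(sched, sched[1:]):
            if b0 < a1:
                raise ValueError("laser intervals overlap")
        for a0, a1 in sched:
            if a0 < 0 or a1 > self.duration or a1 <= a0:
                raise ValueError("laser interval outside [0, duration]")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration))


@dataclass
class GroundTruth:
    """Per-frame truth for every scripted tool plus the laser channel.

    Arrays are indexed ``[tool, frame]``; positions are NaN where the tool
    is absent.  ``theta`` follows the orientation-estimator convention
    (anchored at the midline end nearer the image centre), so estimates can
    be compared to it directly; ``theta_pose`` is the raw scripted pointing
    direction.
    """

    tool_classes: list[str]
    tips: np.ndarray  # (n_tools, n_frames, 2) float, NaN when absent
    theta_pose: np.ndarray  # (n_tools, n_frames) float
    theta: np.ndarray  # (n_tools, n_frames) float, estimator convention
    present: np.ndarray  # (n_tools, n_frames) bool
    overlap: np.ndarray  # (n_frames,) bool: any two masks intersect
    laser: np.ndarray  # (n_frames,) bool
    fps: float

    @property
    def n_frames(self) -> int:
        return self.present.shape[1] if self.present.ndim == 2 else 0

    def counts(self) -> np.ndarray:
        return self.present.sum(axis=0)

    def idle_fraction(self) -> float:
        c = self.counts()
        return float((c == 0).mean()) if c.size else 1.0

    def bimanual_fraction(self) -> float:
        c = self.counts()
        return float((c >= 2).mean()) if c.size else 0.0

    def mean_inter_tip_distance(self) -> float | None:
        """Mean tip distance over frames where exactly two tools show."""
        c = self.counts()
        frames = np.flatnonzero(c == 2)
        if frames.size == 0:
            return None
        dists = []
        for f in frames:
            idx = np.flatnonzero(self.present[:, f])
            p, q = self.tips[idx[0], f], self.tips[idx[1], f]
            dists.append(float(np.hypot(*(p - q))))
        return float(np.mean(dists))


@dataclass
class SceneData:
    """A generated scene: rendered frames, laser series and ground truth."""

    frames: list[FrameRecord]
    laser: np.ndarray
    truth: GroundTruth
    spec: SceneSpec


def _pose_transform(local: np.ndarray, pose: tuple[float, float, float]) -> np.ndarray:
    """Place local polygon (tip at origin, body +x, y up) at an image pose.

    The body extends along direction ``theta + 180`` so the tip is the
    distal end pointing along ``theta``.
    """
    x0, y0, theta = pose
    alpha = math.radians(theta + 180.0)
    c, s = math.cos(alpha), math.sin(alpha)
    dx = local[:, 0] * c - local[:, 1] * s
    dy = local[:, 0] * s + local[:, 1] * c
    return np.column_stack([x0 + dx, y0 - dy])  # image y is down


def render_tool_mask(
    shape: ToolShape,
    pose: tuple[float, float, float],
    width: int = 640,
    height: int = 480,
) -> np.ndarray:
    """Rasterise a tool template at ``pose = (tip_x, tip_y, theta_deg)``.

    The mask is clipped at the frame border; the tip pixel itself is
    stamped when inside the frame so the rendered tip never falls between
    pixel centres.  Raises ``ValueError`` when nothing survives clipping.
    """
    from skimage.draw import polygon as draw_polygon

    verts = _pose_transform(shape.local_polygon(), pose)
    mask = np.zeros((height, width), dtype=bool)
    rr, cc = draw_polygon(verts[:, 1], verts[:, 0], shape=(height, width))
    mask[rr, cc] = True
    tx, ty = int(round(pose[0])), int(round(pose[1]))
    if 0 <= ty < height and 0 <= tx < width:
        mask[ty, tx] = True
    if not mask.any():
        raise ValueError("tool shape has zero area after clipping")
    return mask


def _gt_theta(
    tip: tuple[float, float],
    theta_pose: float,
    length: float,
    width: int,
    height: int,
) -> float:
    """Orientation under the estimator's centre-anchored convention."""
    rad = math.radians(theta_pose)
    base = (tip[0] - length * math.cos(rad), tip[1] + length * math.sin(rad))
    cx, cy = (width - 1) / 2.0, (height - 1) / 2.0
    d_tip = (tip[0] - cx) ** 2 + (tip[1] - cy) ** 2
    d_base = (base[0] - cx) ** 2 + (base[1] - cy) ** 2
    if d_tip <= d_base:
        return (theta_pose + 180.0) % 360.0
    return theta_pose % 360.0


def schedule_to_series(
    schedule: list[tuple[float, float]], fps: float, duration: float
) -> np.ndarray:
    """Boolean per-frame series from [onset, offset) second intervals."""
    n = int(round(fps * duration))
    t = np.arange(n) / fps
    series = np.zeros(n, dtype=bool)
    for a, b in schedule:
        series |= (t >= a) & (t < b)
    return series


def generate_scene(spec: SceneSpec) -> SceneData:
    """Render a full scene per its spec; deterministic under the seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    n_tools = len(spec.tools)

    # Tremor offsets are drawn up-front per tool so presence schedules do
    # not perturb the random stream.
    tremor = np.zeros((n_tools, n, 2))
    for k, tool in enumerate(spec.tools):
        if tool.tremor_px > 0:
            tremor[k] = rng.normal(0.0, tool.tremor_px, size=(n, 2))

    tips = np.full((n_tools, n, 2), np.nan)
    theta_pose = np.full((n_tools, n), np.nan)
    theta = np.full((n_tools, n), np.nan)
    present = np.zeros((n_tools, n), dtype=bool)
    overlap = np.zeros(n, dtype=bool)

    frames: list[FrameRecord] = []
    for i in range(n):
        t = i / spec.fps
        rec = FrameRecord(frame_index=i)
        masks = []
        for k, tool in enumerate(spec.tools):
            if not tool.visible(t):
                continue
            x, y, th = tool.trajectory.pose(t)
            x += tremor[k, i, 0]
            y += tremor[k, i, 1]
            mask = render_tool_mask(
                tool.shape, (x, y, th), spec.width, spec.height
            )
            rec.instances.append(
                InstanceMask(
                    frame_index=i,
                    tool_class=tool.tool_class,
                    score=1.0,
                    mask=mask,
                )
            )
            masks.append(mask)
            present[k, i] = True
            tips[k, i] = (x, y)
            theta_pose[k, i] = th % 360.0
            theta[k, i] = _gt_theta(
                (x, y), th, tool.shape.length, spec.width, spec.height
            )
        for a in range(len(masks)):
            for b in range(a + 1, len(masks)):
                if (masks[a] & masks[b]).any():
                    overlap[i] = True
        laser_flag = any(a <= t < b for a, b in spec.laser_schedule)
        rec.laser_on = laser_flag
        frames.append(rec)

    laser = schedule_to_series(spec.laser_schedule, spec.fps, spec.duration)
    truth = GroundTruth(
        tool_classes=[tool.tool_class for tool in spec.tools],
        tips=tips,
        theta_pose=theta_pose,
        theta=theta,
        present=present,
        overlap=overlap,
        laser=laser,
        fps=spec.fps,
    )
    return SceneData(frames=frames, laser=laser, truth=truth, spec=spec)


def _shift_mask(mask: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Rigidly translate a mask, cropping at the borders."""
    out = np.zeros_like(mask)
    h, w = mask.shape
    ys, xs = np.nonzero(mask)
    ys = ys + dy
    xs = xs + dx
    keep = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
    out[ys[keep], xs[keep]] = True
    return out


def corrupt_detections(
    frames: list[FrameRecord],
    fp_rate: float = 0.0,
    fn_rate: float = 0.0,
    tip_jitter_px: float = 0.0,
    score_noise: float = 0.0,
    seed: int = 0,
    width: int = 640,
    height: int = 480,
) -> list[FrameRecord]:
    """Inject detection noise into a rendered scene.

    False negatives drop instances i.i.d. per frame; false positives insert
    spurious instances of a random class persisting 1-3 frames (uniform);
    tip jitter displaces masks rigidly by a rounded Gaussian offset; score
    noise adds Gaussian jitter to confidence scores.  Deterministic under
    the seed; with all rates zero the output equals the input.
    """
    for name, rate in (("fp_rate", fp_rate), ("fn_rate", fn_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} outside [0, 1]")
    rng = np.random.default_rng(seed)
    out = [
        FrameRecord(frame_index=f.frame_index, laser_on=f.laser_on)
        for f in frames
    ]

    for f, rec in zip(frames, out):
        for inst in f.instances:
            if fn_rate > 0 and rng.random() < fn_rate:
                continue
            mask = inst.mask
            if tip_jitter_px > 0:
                dx, dy = np.rint(rng.normal(0.0, tip_jitter_px, 2)).astype(int)
                shifted = _shift_mask(mask, int(dx), int(dy))
                if shifted.any():
                    mask = shifted
            score = inst.score
            if score_noise > 0:
                score = float(
                    np.clip(score + rng.normal(0.0, score_noise), 0.01, 1.0)
                )
            rec.instances.append(
                InstanceMask(
                    frame_index=f.frame_index,
                    tool_class=inst.tool_class,
                    score=score,
                    mask=mask,
                )
            )

    if fp_rate > 0:
        for i in range(len(out)):
            if rng.random() >= fp_rate:
                continue
            lifespan = int(rng.integers(1, 4))  # 1-3 frames
            cls = TOOL_CLASSES[int(rng.integers(0, len(TOOL_CLASSES)))]
            shape = ToolShape(
                length=float(rng.uniform(40, 80)),
                width=float(rng.uniform(6, 12)),
                taper=0.3,
            )
            x = float(rng.uniform(width * 0.15, width * 0.85))
            y = float(rng.uniform(height * 0.15, height * 0.85))
            th = float(rng.uniform(0, 360))
            score = float(rng.uniform(0.2, 1.0))
            for j in range(i, min(i + lifespan, len(out))):
                out[j].instances.append(
                    InstanceMask(
                        frame_index=j,
                        tool_class=cls,
                        score=score,
                        mask=render_tool_mask(shape, (x, y, th), width, height),
                    )
                )
    return out


# ---------------------------------------------------------------------------
# Skill cohorts: scripted "expert" vs "novice" recordings whose ground
# truth realises the qualitative contrasts reported for experienced vs
# novice operators (slower, smoother, more bimanual, more frequent
# microscope adjustments for the expert).
# ---------------------------------------------------------------------------

def make_skill_scene(
    skill: str,
    seed: int,
    duration: float = 15.0,
    width: int = 640,
    height: int = 480,
    fps: float = 12.0,
) -> SceneSpec:
    """Scripted two-tool suturing-like scene for one skill level.

    Expert: slow, steady circular needle-holder motion with continuous
    rotation, a second forceps held near the field centre most of the time,
    minimal idle time and close tip spacing.  Novice: fast jittery motion
    (2.5 px tremor), fixed orientation, long idle windows, brief bimanual
    phase, widely separated tools.
    """
    rng = np.random.default_rng(seed)
    if skill == "expert":
        omega = rng.uniform(0.40, 0.55)
        radius = rng.uniform(45, 60)
        tool_a = ToolScript(
            tool_class="Straight Needle Holder",
            shape=ToolShape(length=90, width=12, taper=0.3),
            trajectory=CircularTrajectory(
                center=(310.0, 240.0),
                radius=radius,
                omega=omega,
                phase=rng.uniform(0, 2 * math.pi),
            ),
            presence=[(rng.uniform(0.0, 0.04) * duration, duration)],
        )
        angle = rng.uniform(0, 2 * math.pi)
        dist = rng.uniform(75, 95)
        bx = 310.0 + dist * math.cos(angle)
        by = 240.0 + dist * math.sin(angle)
        # Point the tip toward the field centre so the orientation anchor
        # (midline end nearer the centre) is stable frame to frame; the
        # slow rotation rocks the tool around that heading.
        toward = math.degrees(math.atan2(-(240.0 - by), 310.0 - bx))
        tool_b = ToolScript(
            tool_class="Dural Tooth Forceps",
            shape=ToolShape(length=80, width=10, taper=0.3),
            trajectory=StationaryTrajectory(
                point=(bx, by),
                theta=toward + rng.uniform(-15, 15),
                theta_rate=rng.uniform(6, 14),
            ),
            presence=[(0.05 * duration, rng.uniform(0.88, 0.95) * duration)],
        )
        return SceneSpec(
            duration=duration,
            tools=[tool_a, tool_b],
            width=width,
            height=height,
            fps=fps,
            seed=seed,
        )
    if skill == "novice":
        speed = rng.uniform(70, 95)
        waypoints = (
            (360.0 + rng.uniform(-15, 15), 140.0 + rng.uniform(-10, 10)),
            (540.0 + rng.uniform(-15, 15), 200.0 + rng.uniform(-10, 10)),
            (420.0 + rng.uniform(-15, 15), 250.0 + rng.uniform(-10, 10)),
            (520.0 + rng.uniform(-15, 15), 130.0 + rng.uniform(-10, 10)),
            (370.0 + rng.uniform(-15, 15), 220.0 + rng.uniform(-10, 10)),
        )
        a_on = rng.uniform(0.08, 0.12) * duration
        a_off = rng.uniform(0.48, 0.52) * duration
        a_on2 = rng.uniform(0.63, 0.67) * duration
        a_off2 = rng.uniform(0.93, 0.97) * duration
        # Fixed heading from the waypoint region toward the image centre:
        # keeps the tip the centre-nearer end so the orientation anchor
        # never flips as the tool wanders.
        wx = sum(p[0] for p in waypoints) / len(waypoints)
        wy = sum(p[1] for p in waypoints) / len(waypoints)
        heading = math.degrees(math.atan2(-(239.5 - wy), 319.5 - wx))
        tool_a = ToolScript(
            tool_class="Straight Needle Holder",
            shape=ToolShape(length=90, width=12, taper=0.3),
            trajectory=PolylineTrajectory(
                points=waypoints, speed=speed, theta=heading + rng.uniform(-10, 10)
            ),
            presence=[(a_on, a_off), (a_on2, a_off2)],
            tremor_px=2.5,
        )
        bpx = 120.0 + rng.uniform(-10, 10)
        bpy = 395.0 + rng.uniform(-10, 10)
        tool_b = ToolScript(
            tool_class="Dural Tooth Forceps",
            shape=ToolShape(length=80, width=10, taper=0.3),
            trajectory=StationaryTrajectory(
                point=(bpx, bpy),
                theta=math.degrees(math.atan2(-(239.5 - bpy), 319.5 - bpx)),
            ),
            presence=[
                (
                    rng.uniform(0.14, 0.16) * duration,
                    rng.uniform(0.44, 0.46) * duration,
                )
            ],
            tremor_px=2.0,
        )
        return SceneSpec(
            duration=duration,
            tools=[tool_a, tool_b],
            width=width,
            height=height,
            fps=fps,
            seed=seed,
        )
    raise ValueError(f"unknown skill level {skill!r}")


def make_skill_laser_schedule(
    skill: str, seed: int, window_s: float = 3000.0
) -> list[tuple[float, float]]:
    """Laser on/off schedule: frequent short focusing episodes for the
    expert, sparse ones for the novice."""
    rng = np.random.default_rng(seed)
    if skill == "expert":
        gap_lo, gap_hi = 50.0, 90.0
    elif skill == "novice":
        gap_lo, gap_hi = 150.0, 300.0
    else:
        raise ValueError(f"unknown skill level {skill!r}")
    schedule = []
    t = rng.uniform(5.0, 15.0)
    while True:
        dur = rng.uniform(2.0, 5.0)
        if t + dur >= window_s:
            break
        schedule.append((t, t + dur))
        t += dur + rng.uniform(gap_lo, gap_hi)
    return schedule
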