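"""Scene generator: rendering, ground truth, corruption, determinism."""

import numpy as np
import pytest
from scipy import stats
from scipy.ndimage import label

from microskill import RecordingConfig, analyze_frames
from microskill.geometry import analyze_mask
from microskill.synthetic import (
    CircularTrajectory,
    LinearTrajectory,
    SceneSpec,
    StationaryTrajectory,
    ToolScript,
    ToolShape,
    corrupt_detections,
    generate_scene,
    make_skill_laser_schedule,
    make_skill_scene,
    render_tool_mask,
    schedule_to_series,
)

S8 = np.ones((3, 3), dtype=int)


def _simple_spec(duration=2.0, presence=None, seed=0, tremor=0.0, speed=24.0):
    tool = ToolScript(
        tool_class="Suction",
        shape=ToolShape(length=80, width=10, taper=0.3),
        trajectory=LinearTrajectory(start=(200.0, 240.0), velocity=(speed, 0.0)),
        presence=presence if presence is not None else [(0.0, duration)],
        tremor_px=tremor,
    )
    return SceneSpec(duration=duration, tools=[tool], seed=seed)


# ---------------------------------------------------------------------------
# render_tool_mask
# ---------------------------------------------------------------------------

def test_render_horizontal_bar_area_and_tip():
    mask = render_tool_mask(ToolShape(100, 10, taper=0.0), (320, 240, 0.0))
    assert 900 <= mask.sum() <= 1150  # ~1000 px for a 100x10 bar
    ys, xs = np.nonzero(mask)
    assert abs(int(xs.max()) - 320) <= 1  # rightmost extremity at the tip
    assert label(mask, structure=S8)[1] == 1


def test_render_rotation_symmetry_about_tip():
    """theta=90 mask equals the theta=0 mask rotated 90 deg about the tip
    within 1 px of boundary rasterisation."""
    from scipy.ndimage import distance_transform_edt

    shape = ToolShape(60, 8, taper=0.25)
    m0 = render_tool_mask(shape, (240, 240, 0.0))
    m90 = render_tool_mask(shape, (240, 240, 90.0))
    # rotate m0 by +90 deg (math convention) about the tip (240, 240)
    ys, xs = np.nonzero(m0)
    dx, dy = xs - 240, ys - 240
    rx, ry = 240 + dy, 240 - dx  # (x,y) -> (y, -x) with image y down
    rot = np.zeros_like(m0)
    rot[ry, rx] = True
    # symmetric difference stays within 1 px of the other mask's boundary
    for a, b in ((rot, m90), (m90, rot)):
        extra = a & ~b
        if extra.any():
            dist_to_b = distance_transform_edt(~b)
            assert dist_to_b[extra].max() <= 1.5


def test_render_clipped_at_border_still_connected():
    shape = ToolShape(100, 10, taper=0.0)
    full = render_tool_mask(shape, (320, 240, 0.0))
    clipped = render_tool_mask(shape, (630, 240, 180.0))  # body extends right
    assert clipped.sum() < full.sum()
    assert label(clipped, structure=S8)[1] == 1


def test_render_zero_area_rejected():
    with pytest.raises(ValueError):
        render_tool_mask(ToolShape(50, 8), (-500, -500, 0.0))


# ---------------------------------------------------------------------------
# generate_scene
# ---------------------------------------------------------------------------

def test_empty_scene_all_idle():
    scene = generate_scene(SceneSpec(duration=2.0, tools=[], seed=1))
    assert len(scene.frames) == 24
    assert all(not f.instances for f in scene.frames)
    assert scene.truth.idle_fraction() == 1.0


def test_presence_schedule_flags():
    scene = generate_scene(_simple_spec(duration=2.0, presence=[(0.0, 1.0)]))
    present = scene.truth.present[0]
    assert present[:12].all() and not present[12:].any()
    assert [bool(f.instances) for f in scene.frames] == present.tolist()


def test_linear_trajectory_step_is_speed_over_fps():
    scene = generate_scene(_simple_spec(duration=2.0, speed=24.0))
    tips = scene.truth.tips[0]
    steps = np.diff(tips, axis=0)
    assert np.allclose(np.hypot(steps[:, 0], steps[:, 1]), 2.0)


def test_ground_truth_tip_inside_mask():
    scene = generate_scene(_simple_spec(duration=1.0))
    for i, f in enumerate(scene.frames):
        x, y = scene.truth.tips[0, i]
        assert f.instances[0].mask[int(round(y)), int(round(x))]


def test_seed_determinism_byte_identical():
    spec_a = _simple_spec(duration=1.0, seed=7, tremor=1.5)
    spec_b = _simple_spec(duration=1.0, seed=7, tremor=1.5)
    sa, sb = generate_scene(spec_a), generate_scene(spec_b)
    assert np.array_equal(sa.truth.tips, sb.truth.tips, equal_nan=True)
    for fa, fb in zip(sa.frames, sb.frames):
        for ia, ib in zip(fa.instances, fb.instances):
            assert ia.mask.tobytes() == ib.mask.tobytes()
            assert ia.score == ib.score


def test_overlapping_tools_flagged():
    tools = [
        ToolScript(
            tool_class=c,
            shape=ToolShape(length=80, width=10),
            trajectory=StationaryTrajectory(point=(320.0, 240.0), theta=th),
            presence=[(0.0, 1.0)],
        )
        for c, th in (("Suction", 0.0), ("Bipolar Forceps", 10.0))
    ]
    scene = generate_scene(SceneSpec(duration=1.0, tools=tools))
    assert scene.truth.overlap.all()


def test_laser_schedule_validation_and_series():
    with pytest.raises(ValueError):
        SceneSpec(duration=2.0, laser_schedule=[(0.0, 1.0), (0.5, 1.5)])
    with pytest.raises(ValueError):
        SceneSpec(duration=2.0, laser_schedule=[(1.0, 3.0)])
    series = schedule_to_series([(0.0, 1.0), (1.5, 2.0)], fps=12, duration=2.0)
    assert series.sum() == 12 + 6


# ---------------------------------------------------------------------------
# corrupt_detections
# ---------------------------------------------------------------------------

def test_corrupt_identity_when_no_noise():
    scene = generate_scene(_simple_spec(duration=1.0))
    out = corrupt_detections(scene.frames, 0.0, 0.0, 0.0, 0.0, seed=3)
    assert sum(len(f.instances) for f in out) == sum(
        len(f.instances) for f in scene.frames
    )
    for fa, fb in zip(scene.frames, out):
        for ia, ib in zip(fa.instances, fb.instances):
            assert ia.score == ib.score
            assert (ia.mask == ib.mask).all()


def test_corrupt_fn_rate_one_empties_everything():
    scene = generate_scene(_simple_spec(duration=1.0))
    out = corrupt_detections(scene.frames, fn_rate=1.0, seed=3)
    assert all(not f.instances for f in out)


def test_corrupt_fn_removal_count_binomial():
    # 1000 instance-frames at fn=0.2: removals within the binomial 99% CI
    spec = _simple_spec(duration=1000 / 12.0, speed=0.3)
    scene = generate_scene(spec)
    n_in = sum(len(f.instances) for f in scene.frames)
    assert n_in == 1000
    out = corrupt_detections(scene.frames, fn_rate=0.2, seed=11)
    removed = n_in - sum(len(f.instances) for f in out)
    lo, hi = stats.binom.interval(0.99, n_in, 0.2)
    assert lo <= removed <= hi


def test_corrupt_false_positives_short_lived():
    scene = generate_scene(_simple_spec(duration=4.0))
    out = corrupt_detections(scene.frames, fp_rate=0.5, fn_rate=1.0, seed=5)
    runs = [len(f.instances) for f in out]
    assert sum(runs) > 0
    # every spurious instance persists 1-3 frames: no run of identical
    # spurious masks longer than 3
    seen = {}
    for f in out:
        for inst in f.instances:
            key = inst.mask.tobytes()
            seen[key] = seen.get(key, 0) + 1
    assert max(seen.values()) <= 3


def test_corrupt_determinism():
    scene = generate_scene(_simple_spec(duration=2.0))
    a = corrupt_detections(scene.frames, 0.1, 0.1, 1.0, 0.05, seed=9)
    b = corrupt_detections(scene.frames, 0.1, 0.1, 1.0, 0.05, seed=9)
    assert [len(f.instances) for f in a] == [len(f.instances) for f in b]
    for fa, fb in zip(a, b):
        for ia, ib in zip(fa.instances, fb.instances):
            assert ia.score == ib.score and (ia.mask == ib.mask).all()


# ---------------------------------------------------------------------------
# self-consistency: geometry on clean renders recovers the ground truth
# ---------------------------------------------------------------------------

def test_pipeline_recovers_ground_truth_tips_and_angles():
    spec = make_skill_scene("expert", seed=5, duration=2.0)
    scene = generate_scene(spec)
    truth = scene.truth
    for i, frame in enumerate(scene.frames):
        for inst in frame.instances:
            k = truth.tool_classes.index(inst.tool_class)
            (tx, ty), theta = analyze_mask(inst.mask, (480, 640))
            gx, gy = truth.tips[k, i]
            assert np.hypot(tx - gx, ty - gy) <= 3.0
            err = abs((theta - truth.theta[k, i] + 180) % 360 - 180)
            assert err <= 3.0


def test_cohort_scenes_are_valid_and_distinct():
    e = make_skill_scene("expert", seed=1)
    n = make_skill_scene("novice", seed=1)
    assert e.n_frames == n.n_frames == 180
    assert {t.tremor_px for t in e.tools} == {0.0}
    assert all(t.tremor_px > 0 for t in n.tools)
    with pytest.raises(ValueError):
        make_skill_scene("intermediate", seed=1)


def test_skill_laser_schedules_frequency_contrast():
    e = make_skill_laser_schedule("expert", seed=2)
    n = make_skill_laser_schedule("novice", seed=2)
    assert len(e) > 2 * len(n)
    for sched in (e, n):
        for (a0, a1), (b0, b1) in zip(sched, sched[1:]):
            assert a1 < b0  # disjoint, ordered
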