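import numpy as np
import pytest

from microskill.temporal import ToolTrack, TrackSample


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_track(
    positions,
    thetas=None,
    frame_indices=None,
    tool_class="Straight Needle Holder",
    score=1.0,
):
    """Build a ToolTrack from position (and optional orientation) lists."""
    n = len(positions)
    if thetas is None:
        thetas = [None] * n
    if frame_indices is None:
        frame_indices = list(range(n))
    samples = [
        TrackSample(frame_index=f, x=float(p[0]), y=float(p[1]),
                    theta=th, score=score)
        for f, p, th in zip(frame_indices, positions, thetas)
    ]
    return ToolTrack(tool_class=tool_class, samples=samples)


@pytest.fixture
def track_factory():
    return make_track
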