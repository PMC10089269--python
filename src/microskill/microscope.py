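"""Microscope-adjustment metrics from the laser-dot presence channel.

Operating microscopes project two red laser dots while the focusing aid is
active, so an adjustment episode is visible in video as a contiguous run of
laser-on frames.  After run-length smoothing, each maximal on-run counts as
one adjustment; the metrics are the number of adjustments inside an
analysis window (default the first 50 minutes) and the maximum and median
onset-to-onset interval in seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .temporal import PresenceSeries, smooth_presence, _runs

__all__ = ["AdjustmentEvent", "AdjustmentReport", "extract_adjustment_events", "adjustment_metrics"]


@dataclass(frozen=True)
class AdjustmentEvent:
    """One focusing episode: inclusive frame span plus derived times."""

    onset_frame: int
    offset_frame: int
    fps: float

    def __post_init__(self) -> None:
        if self.offset_frame < self.onset_frame:
            raise ValueError("event offset before onset")

    @property
    def onset_s(self) -> float:
        return self.onset_frame / self.fps

    @property
    def duration_s(self) -> float:
        return (self.offset_frame - self.onset_frame + 1) / self.fps


@dataclass
class AdjustmentReport:
    """Adjustment count and interval statistics for one recording window."""

    n_adjustments: int
    max_interval_s: float | None
    median_interval_s: float | None
    window_s: float = 3000.0

    def as_dict(self) -> dict[str, float | None]:
        return {
            "n_adjustments": float(self.n_adjustments),
            "max_interval_s": self.max_interval_s,
            "median_interval_s": self.median_interval_s,
        }


def extract_adjustment_events(
    laser_series: PresenceSeries,
    min_on_frames: int = 3,
    min_off_frames: int = 3,
) -> list[AdjustmentEvent]:
    """Smooth the laser presence series, then one maximal on-run = one event."""
    smoothed = smooth_presence(laser_series, min_on_frames, min_off_frames)
    events = []
    for start, length, val in _runs(smoothed.values):
        if val:
            events.append(
                AdjustmentEvent(
                    onset_frame=start,
                    offset_frame=start + length - 1,
                    fps=laser_series.fps,
                )
            )
    return events


def adjustment_metrics(
    events: list[AdjustmentEvent],
    window_s: float = 3000.0,
    fps: float | None = None,
) -> AdjustmentReport:
    """Count events starting inside the window and their onset intervals.

    Intervals are differences between consecutive onset times in seconds;
    with fewer than two in-window events they are reported as undefined
    (``None``), never 0.  The median of an even-length interval list is the
    mean of the middle two.
    """
    onsets = sorted(e.onset_s for e in events if e.onset_s < window_s)
    n = len(onsets)
    if n < 2:
        if n == 1:
            warnings.warn(
                "single adjustment event; intervals undefined",
                RuntimeWarning,
                stacklevel=2,
            )
        return AdjustmentReport(
            n_adjustments=n,
            max_interval_s=None,
            median_interval_s=None,
            window_s=window_s,
        )
    intervals = np.diff(onsets)
    return AdjustmentReport(
        n_adjustments=n,
        max_interval_s=float(intervals.max()),
        median_interval_s=float(np.median(intervals)),
        window_s=window_s,
    )
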