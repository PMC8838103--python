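"""Foot-flat (zero-velocity) interval detection.

During each gait cycle the foot is flat and still on the ground for a
short period; sensor velocity is then known to be zero, which is what
makes drift-free strapdown dead reckoning possible. The detector is a
windowed energy test on the raw signals: a sample is stationary when the
gyroscope magnitude and the deviation of the accelerometer magnitude
from 1 g are both below threshold over a sliding window centred on it.
Runs of stationary samples become intervals; short gaps are merged and
too-short intervals dropped (debounce). Each interval gets a
representative foot-flat time ``t_rep`` at its midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import minimum_filter1d

from .errors import ValidationError
from .orientation import STANDARD_GRAVITY
from .sensor_io import ImuRecording


@dataclass
class DetectorParams:
    """Stationarity-test settings.

    gyro_threshold : rad/s, max gyroscope magnitude for a still sample.
    accel_threshold : m/s², max deviation of |accel| from g.
    window_s : sliding-window length over which both tests must hold.
    min_duration_s : shortest accepted interval; also the merge gap.
    """

    gyro_threshold: float = 0.5
    accel_threshold: float = 0.5
    window_s: float = 0.05
    min_duration_s: float = 0.05


@dataclass(frozen=True)
class StationaryInterval:
    """One foot-flat period, closed sample-index interval."""

    start_index: int
    end_index: int
    t_rep: float

    def __post_init__(self) -> None:
        if self.start_index > self.end_index:
            raise ValidationError("start_index must be <= end_index")


@dataclass
class FootFlatSequence:
    """Time-ordered, disjoint foot-flat intervals for one foot."""

    intervals: list[StationaryInterval]

    @property
    def N(self) -> int:
        """Number of foot-flat periods."""
        return len(self.intervals)

    @property
    def t_reps(self) -> np.ndarray:
        return np.array([iv.t_rep for iv in self.intervals])

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)


def stationary_mask(rec: ImuRecording, params: DetectorParams | None = None) -> np.ndarray:
    """Boolean per-sample stationarity mask (before run extraction)."""
    if params is None:
        params = DetectorParams()
    fs = rec.meta.sample_rate_hz
    window = max(1, int(round(params.window_s * fs)))
    if len(rec) < window:
        raise ValidationError(
            f"recording ({len(rec)} samples) shorter than detector window ({window})"
        )
    gyro_mag = np.linalg.norm(rec.gyro, axis=1)
    accel_dev = np.abs(np.linalg.norm(rec.accel, axis=1) - STANDARD_GRAVITY)
    point = (gyro_mag < params.gyro_threshold) & (accel_dev < params.accel_threshold)
    # all samples in the centred window must pass
    return minimum_filter1d(point.astype(np.uint8), size=window, mode="nearest").astype(bool)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Closed-interval (start, end) index pairs of True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [(int(s), int(e) - 1) for s, e in zip(idx[::2], idx[1::2])]


def detect_foot_flat(rec: ImuRecording, params: DetectorParams | None = None) -> FootFlatSequence:
    """Detect foot-flat periods and assign representative times.

    Returns an ordered, disjoint sequence; empty if the foot never rests.
    """
    if params is None:
        params = DetectorParams()
    mask = stationary_mask(rec, params)
    t = rec.timestamps
    runs = _runs(mask)

    # merge runs separated by less than min_duration_s
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and t[s] - t[merged[-1][1]] < params.min_duration_s:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))

    intervals = [
        StationaryInterval(s, e, t_rep=0.5 * (t[s] + t[e]))
        for s, e in merged
        if t[e] - t[s] >= params.min_duration_s
    ]
    return FootFlatSequence(intervals)
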