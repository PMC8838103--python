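"""End-to-end walk-distance pipeline for one walk (one or two feet).

Per foot: orientation fusion → foot-flat detection → gyro-bias
refinement (mean gyro over detected stationary samples, one iteration)
→ Earth-frame gravity removal → ZUPT-aided double integration →
per-stride chords. The bilateral average of the per-foot totals is the
reported distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distance import WalkDistanceResult, walk_distance
from .orientation import FilterParams, earth_frame_free_acceleration, estimate_orientation
from .sensor_io import ImuRecording
from .trajectory import FootTrajectory, integrate_trajectory
from .zupt_detection import DetectorParams, FootFlatSequence, detect_foot_flat, stationary_mask


@dataclass
class PipelineParams:
    """All tunables of the distance pipeline in one place."""

    filter: FilterParams = field(default_factory=FilterParams)
    detector: DetectorParams = field(default_factory=DetectorParams)
    refine_gyro_bias: bool = True


@dataclass
class FootResult:
    """Intermediate per-foot products, kept for diagnostics/plotting."""

    trajectory: FootTrajectory
    flats: FootFlatSequence
    gyro_bias: np.ndarray


def process_foot(rec: ImuRecording, params: PipelineParams | None = None) -> FootResult:
    """Run the per-foot chain from raw recording to trajectory + foot-flats."""
    if params is None:
        params = PipelineParams()
    flats = detect_foot_flat(rec, params.detector)

    bias = np.asarray(params.filter.gyro_bias, dtype=float)
    if params.refine_gyro_bias and len(flats) > 0:
        # median over stationary samples: robust to slow-rotation tails
        # (pivot-turn onsets) that leak through the stationarity test
        mask = stationary_mask(rec, params.detector)
        bias = bias + np.median(rec.gyro[mask], axis=0)
    fp = FilterParams(
        kp=params.filter.kp,
        gate_low=params.filter.gate_low,
        gate_high=params.filter.gate_high,
        init_window_s=params.filter.init_window_s,
        gyro_bias=bias,
    )
    track = estimate_orientation(rec, fp)
    free = earth_frame_free_acceleration(rec, track)
    traj = integrate_trajectory(free, flats)
    return FootResult(traj, flats, bias)


def estimate_walk_distance(
    left: ImuRecording | None = None,
    right: ImuRecording | None = None,
    params: PipelineParams | None = None,
) -> WalkDistanceResult:
    """Estimate the total distance walked from one or both foot recordings."""
    feet = {}
    for side, rec in (("left", left), ("right", right)):
        if rec is not None:
            res = process_foot(rec, params)
            feet[side] = (res.trajectory, res.flats)
    return walk_distance(feet)
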