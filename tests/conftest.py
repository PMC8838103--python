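"""Shared fixtures: small simulated walks and hand-built trajectories."""

import numpy as np
import pytest

from walkdist.orientation import STANDARD_GRAVITY as G
from walkdist.sensor_io import ImuRecording, SensorMeta
from walkdist.synthetic_gait import GaitProtocol, NoiseModel, simulate_walk
from walkdist.trajectory import FootTrajectory
from walkdist.zupt_detection import FootFlatSequence, StationaryInterval

FS = 128.0


def make_static_recording(duration_s=5.0, accel=(0.0, 0.0, G), accel_sd=0.0, gyro_sd=0.0, seed=0):
    n = int(duration_s * FS)
    t = np.arange(n) / FS
    rng = np.random.default_rng(seed)
    a = np.tile(accel, (n, 1)) + rng.normal(0, accel_sd, (n, 3))
    g = rng.normal(0, gyro_sd, (n, 3))
    return ImuRecording(t, a, g, SensorMeta(sample_rate_hz=FS))


def make_trajectory_from_flats(points, stance_s=0.3, swing_s=0.4, fs=FS):
    """Piecewise trajectory dwelling at each point, moving linearly between.

    Returns (FootTrajectory, FootFlatSequence) with t_rep at each dwell
    midpoint — a geometric fixture for chord computations.
    """
    points = np.asarray(points, dtype=float).reshape(len(points), -1)
    if points.shape[1] == 2:
        points = np.column_stack([points, np.zeros(len(points))])
    dt = 1.0 / fs
    n_st = int(round(stance_s * fs))
    n_sw = int(round(swing_s * fs))
    pos_rows, intervals = [], []
    idx = 0
    for i, p in enumerate(points):
        pos_rows.append(np.tile(p, (n_st, 1)))
        intervals.append((idx, idx + n_st - 1))
        idx += n_st
        if i + 1 < len(points):
            u = (np.arange(1, n_sw + 1) / (n_sw + 1))[:, None]
            pos_rows.append(p + u * (points[i + 1] - p))
            idx += n_sw
    pos = np.vstack(pos_rows)
    t = np.arange(len(pos)) * dt
    vel = np.gradient(pos, dt, axis=0)
    traj = FootTrajectory(t, pos, vel)
    flats = FootFlatSequence(
        [StationaryInterval(s, e, 0.5 * (t[s] + t[e])) for s, e in intervals]
    )
    return traj, flats


@pytest.fixture(scope="session")
def short_walk():
    """Noise-free 10-stride straight walk (no turns), with ground truth."""
    protocol = GaitProtocol(walkway_length=13.0, mode="fixed_distance", target=13.0)
    left, right, truth = simulate_walk(protocol, NoiseModel(seed=42))
    return protocol, left, right, truth


@pytest.fixture(scope="session")
def lap_walk():
    """Noise-free 2-length (out-and-back) walk with one pivot turn."""
    protocol = GaitProtocol(walkway_length=20.0, mode="fixed_distance", target=40.0)
    left, right, truth = simulate_walk(protocol, NoiseModel(seed=7))
    return protocol, left, right, truth
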