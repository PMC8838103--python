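"""Body-to-Earth orientation estimation and gravity removal.

Orientation is tracked as a unit quaternion (Hamilton convention,
scalar-first, passive body→Earth). The Earth frame has z up (antiparallel
to gravity); x/y are arbitrary but fixed per recording — yaw is
unobservable without a magnetometer, and every downstream distance is
invariant to a global yaw offset.

The estimator is a gated complementary filter: the quaternion is
propagated by gyroscope strapdown integration, and its tilt is nudged
toward the accelerometer's gravity direction with a proportional gain,
but only while the accelerometer magnitude is close to 1 g (so the
correction is not polluted by swing-phase dynamics). Initial tilt comes
from the mean accelerometer vector over a short quasi-static window at
the start of the recording (walking tests begin standing still);
initial yaw is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError, ValidationError
from .sensor_io import ImuRecording

STANDARD_GRAVITY = 9.80665  # m/s²


@dataclass
class FilterParams:
    """Complementary-filter settings.

    Attributes
    ----------
    kp : proportional tilt-correction gain, 1/s.
    gate_low, gate_high : accelerometer-magnitude gate as multiples of g;
        the tilt correction is applied only when ``gate_low*g <= |a| <=
        gate_high*g``.
    gate_gyro : rad/s; the correction is additionally gated to
        quasi-static samples with gyro magnitude below this, so swing
        dynamics that transit the 1 g band cannot corrupt the tilt.
    gate_window_s : both gates must hold over this sliding window, not
        just instantaneously (a swing sample can momentarily satisfy
        both while the foot is anything but still).
    init_window_s : leading quasi-static window used for tilt
        initialization, seconds.
    gyro_bias : constant rad/s bias subtracted from the gyroscope before
        integration (estimated externally from stationary intervals).
    """

    kp: float = 0.5
    gate_low: float = 0.9
    gate_high: float = 1.1
    gate_gyro: float = 0.3
    gate_window_s: float = 0.1
    init_window_s: float = 0.25
    gyro_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))


@dataclass
class OrientationTrack:
    """Per-sample body→Earth unit quaternions aligned with a recording."""

    timestamps: np.ndarray
    quaternions: np.ndarray  # (N, 4) scalar-first [w, x, y, z]

    def __post_init__(self) -> None:
        if self.quaternions.shape != (self.timestamps.shape[0], 4):
            raise ValidationError("quaternions must be (N, 4) aligned with timestamps")

    def __len__(self) -> int:
        return self.timestamps.shape[0]


@dataclass
class FreeAcceleration:
    """Earth-frame, gravity-free acceleration aligned with a recording."""

    timestamps: np.ndarray
    accel_earth: np.ndarray  # (N, 3), m/s², z up

    def __len__(self) -> int:
        return self.timestamps.shape[0]


def _quat_mult(aw, ax, ay, az, bw, bx, by, bz):
    return (
        aw * bw - ax * bx - ay * by - az * bz,
        aw * bx + ax * bw + ay * bz - az * by,
        aw * by - ax * bz + ay * bw + az * bx,
        aw * bz + ax * by - ay * bx + az * bw,
    )


def _quat_from_axis_angle(axis: np.ndarray, angle: float) -> tuple[float, float, float, float]:
    half = 0.5 * angle
    s = math.sin(half)
    return (math.cos(half), axis[0] * s, axis[1] * s, axis[2] * s)


def _tilt_quaternion_from_accel(a_mean: np.ndarray) -> tuple[float, float, float, float]:
    """Zero-yaw quaternion rotating the measured up direction onto Earth z."""
    v = a_mean / np.linalg.norm(a_mean)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(v, z))
    axis = np.cross(v, z)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        if c > 0:
            return (1.0, 0.0, 0.0, 0.0)
        return (0.0, 1.0, 0.0, 0.0)  # upside down: 180° about x
    return _quat_from_axis_angle(axis / n, math.atan2(n, c))


def rotate_vectors(quaternions: np.ndarray, vectors: np.ndarray) -> np.ndarray:
    """Rotate body-frame vectors into the Earth frame, vectorized.

    ``v' = v + 2 q_v × (q_v × v + w v)`` for each (quaternion, vector) pair.
    """
    w = quaternions[:, :1]
    qv = quaternions[:, 1:]
    t = np.cross(qv, vectors) + w * vectors
    return vectors + 2.0 * np.cross(qv, t)


def quat_angle(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Rotation angle (rad) between paired quaternions."""
    dots = np.abs(np.sum(q1 * q2, axis=-1))
    return 2.0 * np.arccos(np.clip(dots, -1.0, 1.0))


def estimate_orientation(rec: ImuRecording, params: FilterParams | None = None) -> OrientationTrack:
    """Run the gated complementary filter over a recording.

    Requires uniform sampling (fixed-step strapdown integration).
    """
    if params is None:
        params = FilterParams()
    if not rec.is_uniform():
        raise ValidationError(
            "recording is not uniformly sampled; resample_uniform() it first"
        )
    dt = rec.dt_nominal
    n = len(rec)
    n_init = max(1, min(n, int(round(params.init_window_s / dt))))
    qw, qx, qy, qz = _tilt_quaternion_from_accel(rec.accel[:n_init].mean(axis=0))

    gyro = rec.gyro - np.asarray(params.gyro_bias, dtype=np.float64)
    accel = rec.accel
    g = STANDARD_GRAVITY
    lo, hi = params.gate_low * g, params.gate_high * g
    kp = params.kp

    # windowed quasi-static gate for the tilt correction
    from scipy.ndimage import minimum_filter1d

    amag_all = np.linalg.norm(accel, axis=1)
    wmag_all = np.linalg.norm(gyro, axis=1)
    point = (amag_all >= lo) & (amag_all <= hi) & (wmag_all < params.gate_gyro)
    win = max(1, int(round(params.gate_window_s * rec.meta.sample_rate_hz)))
    quasi_static = minimum_filter1d(point.astype(np.uint8), size=win, mode="nearest").astype(bool)

    quats = np.empty((n, 4))
    quats[0] = (qw, qx, qy, qz)
    for k in range(1, n):
        # midpoint (trapezoidal) gyro sample over the step
        wx = 0.5 * (gyro[k - 1, 0] + gyro[k, 0])
        wy = 0.5 * (gyro[k - 1, 1] + gyro[k, 1])
        wz = 0.5 * (gyro[k - 1, 2] + gyro[k, 2])

        if quasi_static[k - 1]:
            ax, ay, az = accel[k - 1, 0], accel[k - 1, 1], accel[k - 1, 2]
            amag = math.sqrt(ax * ax + ay * ay + az * az)
            # estimated up direction in the body frame: R(q)^T e_z
            vx = 2.0 * (qx * qz - qw * qy)
            vy = 2.0 * (qy * qz + qw * qx)
            vz = qw * qw - qx * qx - qy * qy + qz * qz
            mx, my, mz = ax / amag, ay / amag, az / amag
            # correction rate: kp * (measured × estimated)
            wx += kp * (my * vz - mz * vy)
            wy += kp * (mz * vx - mx * vz)
            wz += kp * (mx * vy - my * vx)

        # q <- q ⊗ exp(ω dt / 2)
        theta = math.sqrt(wx * wx + wy * wy + wz * wz) * dt
        if theta > 1e-12:
            half = 0.5 * theta
            s = math.sin(half) / (theta / dt)  # sin(θ/2)/|ω|
            dw, dx, dy, dz = math.cos(half), wx * s, wy * s, wz * s
            qw, qx, qy, qz = _quat_mult(qw, qx, qy, qz, dw, dx, dy, dz)
            norm = math.sqrt(qw * qw + qx * qx + qy * qy + qz * qz)
            qw, qx, qy, qz = qw / norm, qx / norm, qy / norm, qz / norm
        quats[k] = (qw, qx, qy, qz)
    return OrientationTrack(rec.timestamps, quats)


def earth_frame_free_acceleration(
    rec: ImuRecording, track: OrientationTrack, g: float = STANDARD_GRAVITY
) -> FreeAcceleration:
    """Rotate body accelerations to Earth frame and subtract gravity.

    ``a_earth[i] = R(q_i)·a_body[i] − (0, 0, g)``.
    """
    if len(track) != len(rec):
        raise AlignmentError(
            f"orientation track has {len(track)} samples, recording {len(rec)}"
        )
    accel_earth = rotate_vectors(track.quaternions, rec.accel)
    accel_earth[:, 2] -= g
    return FreeAcceleration(rec.timestamps, accel_earth)
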