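"""Forward gait simulator with exact kinematic ground truth.

Emulates back-and-forth walking on a straight walkway — either a
fixed-distance protocol (laps between cones, e.g. 10 × 20 m out-and-back
= 400 m) or a fixed-time protocol (e.g. a 6-minute walk on a 15 m or
20 m walkway) — and maps the foot kinematics through an inverse sensor
model to body-frame accelerometer and gyroscope signals at the nominal
sample rate.

Kinematic model (all pieces closed-form and twice differentiable):

* Each foot alternates stance dwells (position fixed, velocity zero) and
  swings. Swing horizontal displacement follows a minimum-jerk quintic;
  vertical lift is a smooth sin⁴ bump, so position, velocity and
  acceleration are all continuous and velocity is exactly zero throughout
  stance. The foot pitches in the sagittal plane during swing.
* Both feet land at the same along-walkway stations, offset laterally by
  half the step width and temporally by half a gait cycle.
* Turns at the walkway ends are either ``pivot`` (a stationary heading
  reversal during an extended dwell — the foot does not translate) or
  ``arc`` (a few short strides along a semicircle).

Inverse sensor model: with body→Earth rotation R = Rz(ψ)·Ry(θ) (yaw ψ,
sagittal pitch θ), the gyroscope reads the body-frame angular rate
ω = (−ψ̇ sinθ, θ̇, ψ̇ cosθ) and the accelerometer reads
Rᵀ·(a_earth + (0,0,g)) plus bias and white noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .orientation import STANDARD_GRAVITY
from .pipeline import PipelineParams, estimate_walk_distance
from .sensor_io import ImuRecording, SensorMeta


@dataclass
class GaitProtocol:
    """Walking-test protocol and gait parameters.

    mode "fixed_distance": target is metres of straight walking (e.g.
    400); mode "fixed_time": target is seconds (e.g. 360 for a 6MWT).
    cadence is strides per second per foot; stance_fraction is the
    fraction of the gait cycle the foot is flat and still.
    """

    walkway_length: float = 20.0
    mode: str = "fixed_distance"
    target: float = 400.0
    stride_length: float = 1.3
    cadence: float = 0.9
    stance_fraction: float = 0.35
    turn_style: str = "pivot"
    turn_radius: float = 0.5
    turn_duration_s: float = 1.0
    step_width: float = 0.2
    swing_apex: float = 0.05
    foot_pitch_max: float = 0.35  # rad, sagittal swing pitch amplitude
    initial_quiet_s: float = 2.0
    final_quiet_s: float = 1.5
    sample_rate_hz: float = 128.0
    bandwidth_limit_hz: float | None = None  # e.g. 48.0 to emulate sensor rolloff

    def __post_init__(self) -> None:
        if self.walkway_length < 5:
            raise ValidationError("walkway_length must be >= 5 m")
        if not 0.3 < self.stride_length < 2.5:
            raise ValidationError("stride_length must be in (0.3, 2.5) m")
        if not 0.2 < self.stance_fraction < 0.8:
            raise ValidationError("stance_fraction must be in (0.2, 0.8)")
        if self.stride_length >= self.walkway_length:
            raise ValidationError("stride_length must be smaller than the walkway")
        if self.mode not in ("fixed_distance", "fixed_time"):
            raise ValidationError("mode must be 'fixed_distance' or 'fixed_time'")
        if self.turn_style not in ("pivot", "arc"):
            raise ValidationError("turn_style must be 'pivot' or 'arc'")


@dataclass
class NoiseModel:
    """Additive sensor imperfections; bit-reproducible for a given seed."""

    accel_noise_sd: float = 0.0
    gyro_noise_sd: float = 0.0
    accel_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))
    gyro_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.accel_noise_sd < 0 or self.gyro_noise_sd < 0:
            raise ValidationError("noise SDs must be >= 0")


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    timestamps: np.ndarray
    positions: dict[str, np.ndarray]  # side -> (N, 3) true foot path
    accel_earth: dict[str, np.ndarray]  # side -> (N, 3) true free acceleration
    stance_intervals: dict[str, list[tuple[float, float]]]  # side -> (t0, t1)
    chords: dict[str, np.ndarray]  # side -> per-stride horizontal chords
    per_foot_total: dict[str, float]
    d_total: float
    straight_distance: float  # along-walkway distance excluding turn chords

    def to_dict(self) -> dict:
        return {
            "d_total_m": self.d_total,
            "straight_distance_m": self.straight_distance,
            "per_foot_total_m": dict(self.per_foot_total),
            "n_foot_flats": {s: len(v) for s, v in self.stance_intervals.items()},
            "chords_m": {s: list(map(float, v)) for s, v in self.chords.items()},
            "stance_intervals_s": {
                s: [[float(a), float(b)] for a, b in v]
                for s, v in self.stance_intervals.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# closed-form motion primitives

def _minjerk(u: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Minimum-jerk profile s(u) on [0,1] and its first two derivatives."""
    s = 10 * u**3 - 15 * u**4 + 6 * u**5
    ds = 30 * u**2 - 60 * u**3 + 30 * u**4
    dds = 60 * u - 180 * u**2 + 120 * u**3
    return s, ds, dds


def _lift(u: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smooth bump sin⁴(πu): zero value, velocity AND acceleration at
    both ends, so the foot path is C² across stance/swing boundaries."""
    s, c = np.sin(np.pi * u), np.cos(np.pi * u)
    z = s**4
    dz = 4 * np.pi * s**3 * c
    ddz = 4 * np.pi**2 * s**2 * (3 * c**2 - s**2)
    return z, dz, ddz


def _pitch(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sagittal pitch shape sin(2πu)·sin²(πu) and derivative: zero value
    and rate at the swing boundaries."""
    f = np.sin(2 * np.pi * u) * np.sin(np.pi * u) ** 2
    df = 2 * np.pi * np.cos(2 * np.pi * u) * np.sin(np.pi * u) ** 2 + np.pi * np.sin(
        2 * np.pi * u
    ) ** 2
    return f, df


# ---------------------------------------------------------------------------
# per-foot timeline construction

@dataclass
class _Seg:
    kind: str  # "stance" | "swing" | "pivot"
    t0: float
    t1: float
    p0: np.ndarray  # (2,) horizontal position at start
    p1: np.ndarray  # (2,) at end (== p0 for stance/pivot)
    psi0: float
    psi1: float


def _lateral(psi: float, side: str, half_width: float) -> np.ndarray:
    """World offset of a foot from the walkway centreline."""
    sign = 1.0 if side == "left" else -1.0
    return sign * half_width * np.array([-math.sin(psi), math.cos(psi)])


def _build_timeline(protocol: GaitProtocol, side: str, phase: float) -> tuple[list[_Seg], float]:
    """Segments for one foot; returns (segments, straight_distance)."""
    L = protocol.walkway_length
    n_str = max(1, round(L / protocol.stride_length))
    s = L / n_str
    T = 1.0 / protocol.cadence
    t_stance = protocol.stance_fraction * T
    t_swing = T - t_stance
    half_w = 0.5 * protocol.step_width

    if protocol.mode == "fixed_distance":
        n_lengths = max(1, round(protocol.target / L))
        t_limit = math.inf
    else:
        n_lengths = 10**6
        t_limit = protocol.initial_quiet_s + protocol.target

    segs: list[_Seg] = []
    t = 0.0
    psi = 0.0
    x = 0.0  # along-walkway coordinate of the current footfall station
    direction = 1.0
    pos = np.array([x, 0.0]) + _lateral(psi, side, half_w)

    def stance(duration: float) -> None:
        nonlocal t
        if segs and segs[-1].kind == "stance":  # coalesce adjacent dwells
            segs[-1] = _Seg("stance", segs[-1].t0, segs[-1].t1 + duration, pos.copy(), pos.copy(), psi, psi)
        else:
            segs.append(_Seg("stance", t, t + duration, pos.copy(), pos.copy(), psi, psi))
        t += duration

    def swing_to(new_pos: np.ndarray, new_psi: float | None = None) -> None:
        # heading may rotate during the swing (arc turns); min-jerk blend
        nonlocal t, pos, psi
        psi1 = psi if new_psi is None else new_psi
        segs.append(_Seg("swing", t, t + t_swing, pos.copy(), new_pos.copy(), psi, psi1))
        t += t_swing
        pos = new_pos
        psi = psi1

    stance(protocol.initial_quiet_s + phase)
    straight = 0.0
    done = False
    for leg in range(n_lengths):
        for _ in range(n_str):
            if t >= t_limit:
                done = True
                break
            x += direction * s
            swing_to(np.array([x, 0.0]) + _lateral(psi, side, half_w))
            stance(t_stance)
            straight += s
        if done or leg == n_lengths - 1 or t >= t_limit:
            break
        # 180° turn at the walkway end (counterclockwise)
        direction = -direction
        if protocol.turn_style == "pivot":
            new_psi = psi + math.pi
            segs.append(_Seg("pivot", t, t + protocol.turn_duration_s, pos.copy(), pos.copy(), psi, new_psi))
            t += protocol.turn_duration_s
            psi = new_psi
            stance(t_stance)
        else:
            # arc turn: a few short strides bulging beyond the walkway end
            # along a semicircle of turn_radius, heading rotating with them
            n_arc = 4
            d_hat = np.array([math.cos(psi), math.sin(psi)])
            end_station = np.array([x, 0.0])
            psi_start = psi
            for j in range(1, n_arc + 1):
                phi = math.pi * j / (n_arc + 1)
                psi_j = psi_start + phi
                fp = end_station + protocol.turn_radius * math.sin(phi) * d_hat + _lateral(psi_j, side, half_w)
                swing_to(fp, psi_j)
                stance(t_stance)
            swing_to(end_station + _lateral(psi_start + math.pi, side, half_w), psi_start + math.pi)
            stance(t_stance)
    stance(protocol.final_quiet_s)
    return segs, straight


# ---------------------------------------------------------------------------
# sampling the timeline through the inverse sensor model

def _sample_foot(
    segs: list[_Seg], t: np.ndarray, protocol: GaitProtocol
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate pose and derivatives on the grid.

    Returns (pos3, a_earth, psi, dpsi, theta, dtheta).
    """
    n = t.shape[0]
    pos = np.zeros((n, 3))
    acc = np.zeros((n, 3))
    psi = np.zeros(n)
    dpsi = np.zeros(n)
    theta = np.zeros(n)
    dtheta = np.zeros(n)
    for seg in segs:
        i0 = np.searchsorted(t, seg.t0, side="left")
        i1 = np.searchsorted(t, seg.t1, side="left")
        if i1 <= i0:
            continue
        sl = slice(i0, i1)
        dur = seg.t1 - seg.t0
        u = (t[sl] - seg.t0) / dur
        if seg.kind == "stance":
            pos[sl, :2] = seg.p0
            psi[sl] = seg.psi0
        elif seg.kind == "pivot":
            pos[sl, :2] = seg.p0
            s, ds, _ = _minjerk(u)
            psi[sl] = seg.psi0 + (seg.psi1 - seg.psi0) * s
            dpsi[sl] = (seg.psi1 - seg.psi0) * ds / dur
        else:  # swing
            s, ds, dds = _minjerk(u)
            z, dz, ddz = _lift(u)
            delta = seg.p1 - seg.p0
            pos[sl, 0] = seg.p0[0] + delta[0] * s
            pos[sl, 1] = seg.p0[1] + delta[1] * s
            pos[sl, 2] = protocol.swing_apex * z
            acc[sl, 0] = delta[0] * dds / dur**2
            acc[sl, 1] = delta[1] * dds / dur**2
            acc[sl, 2] = protocol.swing_apex * ddz / dur**2
            psi[sl] = seg.psi0 + (seg.psi1 - seg.psi0) * s
            dpsi[sl] = (seg.psi1 - seg.psi0) * ds / dur
            f, df = _pitch(u)
            theta[sl] = protocol.foot_pitch_max * f
            dtheta[sl] = protocol.foot_pitch_max * df / dur
    # grid may extend past the last segment (clock padding): hold last pose
    t_end = segs[-1].t1
    tail = t >= t_end
    if np.any(tail):
        pos[tail, :2] = segs[-1].p1
        psi[tail] = segs[-1].psi1
    return pos, acc, psi, dpsi, theta, dtheta


def _inverse_sensor(
    acc_earth: np.ndarray,
    psi: np.ndarray,
    dpsi: np.ndarray,
    theta: np.ndarray,
    dtheta: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Map Earth-frame kinematics to ideal body-frame accel and gyro."""
    total = acc_earth.copy()
    total[:, 2] += STANDARD_GRAVITY
    cp, sp = np.cos(psi), np.sin(psi)
    ct, st = np.cos(theta), np.sin(theta)
    # v1 = Rz(-psi) * total
    v1x = cp * total[:, 0] + sp * total[:, 1]
    v1y = -sp * total[:, 0] + cp * total[:, 1]
    v1z = total[:, 2]
    # accel_body = Ry(-theta) * v1
    accel_body = np.column_stack([ct * v1x - st * v1z, v1y, st * v1x + ct * v1z])
    gyro_body = np.column_stack([-dpsi * st, dtheta, dpsi * ct])
    return accel_body, gyro_body


def _bandlimit(signal: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    from scipy.signal import butter, filtfilt

    b, a = butter(4, cutoff / (fs / 2), btype="low")
    return filtfilt(b, a, signal, axis=0)


def simulate_walk(
    protocol: GaitProtocol | None = None,
    noise: NoiseModel | None = None,
    subject_id: str = "sim",
) -> tuple[ImuRecording, ImuRecording, GroundTruth]:
    """Simulate one walking test; returns (left, right, ground truth)."""
    if protocol is None:
        protocol = GaitProtocol()
    if noise is None:
        noise = NoiseModel()
    fs = protocol.sample_rate_hz
    T = 1.0 / protocol.cadence
    timelines = {
        "left": _build_timeline(protocol, "left", phase=0.0),
        "right": _build_timeline(protocol, "right", phase=0.5 * T),
    }
    t_end = max(segs[-1].t1 for segs, _ in timelines.values())
    if protocol.mode == "fixed_time":
        t_end = protocol.initial_quiet_s + protocol.target
    n = int(math.floor(t_end * fs)) + 1
    t = np.arange(n) / fs

    rng = np.random.default_rng(noise.seed)
    recordings: dict[str, ImuRecording] = {}
    positions: dict[str, np.ndarray] = {}
    accel_earth: dict[str, np.ndarray] = {}
    stance_ivs: dict[str, list[tuple[float, float]]] = {}
    chords: dict[str, np.ndarray] = {}
    totals: dict[str, float] = {}
    for side in ("left", "right"):
        segs, straight = timelines[side]
        pos, acc, psi, dpsi, theta, dtheta = _sample_foot(segs, t, protocol)
        accel_body, gyro_body = _inverse_sensor(acc, psi, dpsi, theta, dtheta)
        if protocol.bandwidth_limit_hz is not None:
            accel_body = _bandlimit(accel_body, fs, protocol.bandwidth_limit_hz)
            gyro_body = _bandlimit(gyro_body, fs, protocol.bandwidth_limit_hz)
        accel_body = accel_body + np.asarray(noise.accel_bias)
        gyro_body = gyro_body + np.asarray(noise.gyro_bias)
        if noise.accel_noise_sd > 0:
            accel_body = accel_body + rng.normal(0.0, noise.accel_noise_sd, accel_body.shape)
        if noise.gyro_noise_sd > 0:
            gyro_body = gyro_body + rng.normal(0.0, noise.gyro_noise_sd, gyro_body.shape)
        meta = SensorMeta(sample_rate_hz=fs, foot_side=side, subject_id=subject_id)
        recordings[side] = ImuRecording(t, accel_body, gyro_body, meta)
        positions[side] = pos
        accel_earth[side] = acc

        flats = [
            (seg.t0, min(seg.t1, t_end))
            for seg in segs
            if seg.kind == "stance" and seg.t0 < t_end
        ]
        stance_ivs[side] = flats
        flat_pos = np.array(
            [seg.p0 for seg in segs if seg.kind == "stance" and seg.t0 < t_end]
        )
        c = np.hypot(np.diff(flat_pos[:, 0]), np.diff(flat_pos[:, 1]))
        chords[side] = c
        totals[side] = float(c.sum())

    truth = GroundTruth(
        timestamps=t,
        positions=positions,
        accel_earth=accel_earth,
        stance_intervals=stance_ivs,
        chords=chords,
        per_foot_total=totals,
        d_total=0.5 * (totals["left"] + totals["right"]),
        straight_distance=timelines["left"][1],
    )
    return recordings["left"], recordings["right"], truth


def end_to_end_error(
    protocol: GaitProtocol,
    noise: NoiseModel,
    n_runs: int = 1,
    seeds: list[int] | None = None,
    params: PipelineParams | None = None,
) -> np.ndarray:
    """Absolute percentage error of the full pipeline vs. simulator truth.

    Runs simulate → orientation → ZUPT → trajectory → distance once per
    seed and returns the per-run error rates
    100·|d_total − true d_total|/true d_total.
    """
    if seeds is None:
        seeds = [noise.seed + k for k in range(n_runs)]
    if len(seeds) < 1:
        raise ValidationError("need at least one run")
    rates = []
    for seed in seeds:
        nm = NoiseModel(
            accel_noise_sd=noise.accel_noise_sd,
            gyro_noise_sd=noise.gyro_noise_sd,
            accel_bias=noise.accel_bias,
            gyro_bias=noise.gyro_bias,
            seed=seed,
        )
        left, right, truth = simulate_walk(protocol, nm)
        result = estimate_walk_distance(left, right, params)
        rates.append(100.0 * abs(result.d_total - truth.d_total) / truth.d_total)
    return np.array(rates)
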