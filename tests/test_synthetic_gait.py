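"""Gait simulator: determinism, self-consistency, inverse-sensor fidelity."""

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from walkdist.errors import ValidationError
from walkdist.synthetic_gait import (
    GaitProtocol,
    NoiseModel,
    end_to_end_error,
    simulate_walk,
)


class TestProtocolValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"walkway_length": 3.0},
            {"stride_length": 0.1},
            {"stance_fraction": 0.9},
            {"mode": "warp_speed"},
            {"turn_style": "teleport"},
        ],
    )
    def test_invalid_protocols_rejected(self, kwargs):
        base = dict(walkway_length=20.0, target=40.0)
        base.update(kwargs)
        with pytest.raises(ValidationError):
            GaitProtocol(**base)


class TestDeterminism:
    def test_same_seed_bitwise_identical(self):
        protocol = GaitProtocol(walkway_length=13.0, target=13.0)
        noise = NoiseModel(accel_noise_sd=0.05, gyro_noise_sd=0.005, seed=99)
        l1, r1, _ = simulate_walk(protocol, noise)
        l2, r2, _ = simulate_walk(protocol, noise)
        assert np.array_equal(l1.accel, l2.accel)
        assert np.array_equal(l1.gyro, l2.gyro)
        assert np.array_equal(r1.accel, r2.accel)

    def test_different_seed_differs(self):
        protocol = GaitProtocol(walkway_length=13.0, target=13.0)
        l1, _, _ = simulate_walk(protocol, NoiseModel(accel_noise_sd=0.05, seed=1))
        l2, _, _ = simulate_walk(protocol, NoiseModel(accel_noise_sd=0.05, seed=2))
        assert not np.array_equal(l1.accel, l2.accel)


class TestTruthSelfConsistency:
    def test_chords_match_stance_midpoint_positions(self, lap_walk):
        _, _, _, truth = lap_walk
        for side in ("left", "right"):
            tp, ts = truth.positions[side], truth.timestamps
            flat_pos = np.array(
                [tp[np.argmin(np.abs(ts - 0.5 * (a + b)))] for a, b in truth.stance_intervals[side]]
            )
            chords = np.hypot(np.diff(flat_pos[:, 0]), np.diff(flat_pos[:, 1]))
            assert chords == pytest.approx(truth.chords[side], abs=1e-6)
            assert truth.per_foot_total[side] == pytest.approx(truth.chords[side].sum())
        assert truth.d_total == pytest.approx(
            0.5 * (truth.per_foot_total["left"] + truth.per_foot_total["right"])
        )

    def test_400m_protocol_straight_distance_exact(self):
        protocol = GaitProtocol(walkway_length=20.0, mode="fixed_distance", target=400.0)
        _, _, truth = simulate_walk(protocol, NoiseModel(seed=0))
        assert truth.straight_distance == pytest.approx(400.0)
        # turn chords add a little on top
        assert truth.per_foot_total["left"] >= 400.0

    def test_fixed_time_6mwt_distance_in_plausible_envelope(self):
        for walkway in (15.0, 20.0):
            protocol = GaitProtocol(walkway_length=walkway, mode="fixed_time", target=360.0)
            _, _, truth = simulate_walk(protocol, NoiseModel(seed=1))
            assert 300.0 <= truth.d_total <= 700.0

    def test_stance_velocity_is_zero_in_truth(self, short_walk):
        _, _, _, truth = short_walk
        tp, ts = truth.positions["left"], truth.timestamps
        for a, b in truth.stance_intervals["left"]:
            sel = (ts >= a) & (ts <= b)
            seg = tp[sel]
            assert np.max(np.abs(seg - seg[0])) < 1e-12


class TestInverseSensorModel:
    def test_noise_free_double_integration_reproduces_truth(self):
        # dense-quadrature oracle: rotate the ideal accelerometer signal
        # with the true orientation, subtract gravity, double-integrate
        # with no ZUPT; at 1024 Hz the trapezoid error is sub-millimetre
        from walkdist.orientation import STANDARD_GRAVITY as G
        from walkdist.synthetic_gait import _build_timeline, _sample_foot

        protocol = GaitProtocol(walkway_length=13.0, target=13.0, sample_rate_hz=1024.0)
        left, _, truth = simulate_walk(protocol, NoiseModel(seed=42))
        segs, _ = _build_timeline(protocol, "left", 0.0)
        t = truth.timestamps
        _, _, psi, _, theta, _ = _sample_foot(segs, t, protocol)
        cp, sp, ct, st_ = np.cos(psi), np.sin(psi), np.cos(theta), np.sin(theta)
        ab = left.accel
        # Earth = Rz(psi) · Ry(theta) · body
        v1 = np.column_stack([ct * ab[:, 0] + st_ * ab[:, 2], ab[:, 1], -st_ * ab[:, 0] + ct * ab[:, 2]])
        ae = np.column_stack([cp * v1[:, 0] - sp * v1[:, 1], sp * v1[:, 0] + cp * v1[:, 1], v1[:, 2] - G])
        vel = cumulative_trapezoid(ae, t, axis=0, initial=0.0)
        pos = cumulative_trapezoid(vel, t, axis=0, initial=0.0)
        err = pos - (truth.positions["left"] - truth.positions["left"][0])
        rms = np.sqrt(np.mean(err**2))
        assert rms < 1e-3  # metres

    def test_accel_magnitude_is_g_during_stance(self, short_walk):
        _, left, _, truth = short_walk
        from walkdist.orientation import STANDARD_GRAVITY as G

        mag = np.linalg.norm(left.accel, axis=1)
        a, b = truth.stance_intervals["left"][0]
        sel = (left.timestamps >= a) & (left.timestamps < b)  # b opens the swing
        assert np.allclose(mag[sel], G, atol=1e-9)


class TestEndToEnd:
    def test_noise_free_straight_walk_under_one_percent(self):
        protocol = GaitProtocol(walkway_length=13.0, target=13.0)
        rates = end_to_end_error(protocol, NoiseModel(), seeds=[0, 1, 2, 3, 4])
        assert np.all(rates < 1.0)

    def test_doubling_gyro_noise_does_not_improve(self):
        protocol = GaitProtocol(walkway_length=20.0, target=60.0)
        seeds = list(range(20))
        lo = end_to_end_error(protocol, NoiseModel(accel_noise_sd=0.05, gyro_noise_sd=0.005), seeds=seeds)
        hi = end_to_end_error(protocol, NoiseModel(accel_noise_sd=0.05, gyro_noise_sd=0.01), seeds=seeds)
        assert hi.mean() >= lo.mean() * 0.9  # paired seeds; no improvement


def test_bandwidth_limiter_runs_and_degrades_gracefully():
    protocol = GaitProtocol(walkway_length=13.0, target=13.0, bandwidth_limit_hz=48.0)
    left, right, truth = simulate_walk(protocol, NoiseModel(seed=0))
    from walkdist import estimate_walk_distance

    res = estimate_walk_distance(left, right)
    assert res.d_total == pytest.approx(truth.d_total, rel=0.05)
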