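"""ZUPT-aided strapdown trajectory reconstruction.

Free (gravity-removed, Earth-frame) acceleration is integrated twice to
give the foot trajectory v(t) = [x(t), y(t), z(t)]ᵀ. Raw double
integration drifts rapidly; the zero-velocity updates bound it: velocity
is pinned to zero over every detected foot-flat interval, and within each
inter-stance segment the accumulated velocity error is removed by
subtracting a linear-in-time ramp so that velocity is zero at both
bounding stance intervals (classic linear de-drifting). Position then
comes from integrating the corrected velocity.

Samples before the first and after the last stance interval are
integrated as-is but carry unbounded one-sided drift; downstream distance
computations only use positions at foot-flat times, which avoids them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import AlignmentError
from .orientation import FreeAcceleration
from .zupt_detection import FootFlatSequence


@dataclass
class FootTrajectory:
    """Earth-frame foot path (z vertical), origin at the first sample."""

    timestamps: np.ndarray
    position: np.ndarray  # (N, 3), metres
    velocity: np.ndarray  # (N, 3), m/s

    def __len__(self) -> int:
        return self.timestamps.shape[0]

    def position_at(self, t: float) -> np.ndarray:
        """Position at the sample nearest time ``t`` (no interpolation)."""
        idx = int(np.argmin(np.abs(self.timestamps - t)))
        return self.position[idx]


def integrate_trajectory(free_acc: FreeAcceleration, flats: FootFlatSequence) -> FootTrajectory:
    """Trapezoidal double integration with zero-velocity updates.

    With no detected stance interval the raw (drifting) trajectory is
    returned and a warning is emitted.
    """
    t = free_acc.timestamps
    a = free_acc.accel_earth
    if flats is not None and len(flats) > 0:
        for iv in flats:
            if iv.end_index >= len(t):
                raise AlignmentError("stationary interval exceeds acceleration length")

    v = np.empty_like(a)
    v[0] = 0.0
    v[1:] = cumulative_trapezoid(a, t, axis=0)

    if flats is None or len(flats) == 0:
        warnings.warn("no stationary intervals: trajectory drift is unbounded", stacklevel=2)
    else:
        v = _apply_zupt(t, v, flats)

    p = np.empty_like(v)
    p[0] = 0.0
    p[1:] = cumulative_trapezoid(v, t, axis=0)
    return FootTrajectory(t, p, v)


def _apply_zupt(t: np.ndarray, v_raw: np.ndarray, flats: FootFlatSequence) -> np.ndarray:
    v = v_raw.copy()
    ivs = flats.intervals
    # inter-stance segments: re-reference to zero at departure, remove a
    # linear-in-time ramp ending at the arrival residual
    for k in range(len(ivs) - 1):
        s = ivs[k].end_index  # last stance sample before the swing
        e = ivs[k + 1].start_index  # first stance sample after it
        if e <= s:
            continue
        seg = slice(s, e + 1)
        v_seg = v_raw[seg] - v_raw[s]
        drift = v_seg[-1]
        tau = (t[seg] - t[s]) / (t[e] - t[s])
        v[seg] = v_seg - tau[:, None] * drift
    # one-sided segments: anchored to zero at the adjacent stance only
    first = ivs[0].start_index
    if first > 0:
        v[:first] = v_raw[:first] - v_raw[first]
    last = ivs[-1].end_index
    if last < len(t) - 1:
        v[last + 1 :] = v_raw[last + 1 :] - v_raw[last]
    # stance velocity is zero by definition
    for iv in ivs:
        v[iv.start_index : iv.end_index + 1] = 0.0
    return v
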