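"""Per-stride chord distances and the total distance walked.

The distance covered in one stride is the horizontal straight-line
(chord) displacement between consecutive foot-flat positions of the same
foot:

    d_i = sqrt((x(t_{i+1}) − x(t_i))² + (y(t_{i+1}) − y(t_i))²)

with the vertical coordinate excluded. The total distance is the sum of
chords over the walk, d_total = Σ d_i — turns are included as lateral
chords, never excluded. The final reported distance is the average of
the two per-foot totals. Chords make the estimate robust to missed
foot-flat detections: dropping a foot-flat merges two chords into one
chord no longer than their sum.

The horizontal arc length of the trajectory (integrated horizontal
speed) is also provided for comparison; it includes the curvature of the
swing path and therefore upper-bounds the chord total.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .trajectory import FootTrajectory
from .zupt_detection import FootFlatSequence

#: per-foot totals differing by more than this fraction trigger a QC warning
FOOT_DISCREPANCY_WARN = 0.10


@dataclass
class WalkDistanceResult:
    """Distance summary for one walk.

    per_stride maps foot side to that foot's chord list; d_total is the
    mean of the available per-foot totals.
    """

    per_stride: dict[str, np.ndarray]
    per_foot_total: dict[str, float]
    d_total: float
    N: dict[str, int]
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "d_total_m": self.d_total,
            "per_foot_total_m": dict(self.per_foot_total),
            "n_foot_flats": dict(self.N),
            "per_stride_m": {k: list(map(float, v)) for k, v in self.per_stride.items()},
            "warnings": list(self.warnings),
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def foot_flat_positions(traj: FootTrajectory, flats: FootFlatSequence) -> np.ndarray:
    """(N, 3) trajectory positions at each interval's representative time.

    Positions are taken from the sample nearest each t_rep; the foot is
    still during stance so no sub-sample interpolation is needed.
    """
    return np.array([traj.position_at(t) for t in flats.t_reps]).reshape(-1, 3)


def stride_distances(traj: FootTrajectory, flats: FootFlatSequence) -> np.ndarray:
    """Horizontal chord d_i between consecutive foot-flat positions.

    Empty when fewer than two foot-flats were found (no stride measurable).
    """
    if flats.N < 2:
        return np.empty(0)
    pos = foot_flat_positions(traj, flats)
    return np.hypot(np.diff(pos[:, 0]), np.diff(pos[:, 1]))


def total_distance(per_stride) -> float:
    """d_total = Σ d_i; zero for an empty walk."""
    return float(np.sum(per_stride)) if len(per_stride) else 0.0


def bilateral_total(
    left_total: float | None, right_total: float | None
) -> tuple[float, list[str]]:
    """Average the per-foot totals; fall back to one foot with a warning."""
    warns: list[str] = []
    if left_total is None and right_total is None:
        raise ValidationError("no per-foot totals available")
    if left_total is None or right_total is None:
        warns.append("single-foot result: only one usable foot recording")
        return float(left_total if left_total is not None else right_total), warns
    mean = 0.5 * (left_total + right_total)
    if mean > 0 and abs(left_total - right_total) > FOOT_DISCREPANCY_WARN * mean:
        warns.append(
            f"per-foot totals differ by more than {FOOT_DISCREPANCY_WARN:.0%}: "
            f"left={left_total:.2f} m, right={right_total:.2f} m"
        )
    return float(mean), warns


def arc_length_distance(traj: FootTrajectory) -> float:
    """Horizontal path length ∫‖(vx, vy)‖dt (the rejected alternative).

    Includes the curvature of the foot's swing path, so it is never
    smaller than the chord total.
    """
    speed = np.hypot(traj.velocity[:, 0], traj.velocity[:, 1])
    return float(np.trapezoid(speed, traj.timestamps))


def walk_distance(
    feet: dict[str, tuple[FootTrajectory, FootFlatSequence]]
) -> WalkDistanceResult:
    """Assemble the per-walk distance summary from per-foot inputs.

    ``feet`` maps "left"/"right" to that foot's trajectory and foot-flat
    sequence; either foot may be absent.
    """
    if not feet:
        raise ValidationError("at least one foot is required")
    per_stride: dict[str, np.ndarray] = {}
    per_foot_total: dict[str, float] = {}
    n_flats: dict[str, int] = {}
    for side, (traj, flats) in feet.items():
        d = stride_distances(traj, flats)
        per_stride[side] = d
        per_foot_total[side] = total_distance(d)
        n_flats[side] = flats.N
    d_total, warns = bilateral_total(
        per_foot_total.get("left"), per_foot_total.get("right")
    )
    for w in warns:
        warnings.warn(w, stacklevel=2)
    return WalkDistanceResult(per_stride, per_foot_total, d_total, n_flats, warns)
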