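"""Per-foot IMU recording container, readers/writers, and resampling.

A recording is a uniformly-sampled stream of body-frame triaxial
accelerometer (gravity-inclusive) and gyroscope signals from one
foot-mounted sensor. Canonical units are SI throughout: m/s² for
acceleration and rad/s for rotational rate; readers convert declared
g / deg/s inputs on ingest.

Interchange formats
-------------------
CSV: header ``t,ax,ay,az,gx,gy,gz``, comma-separated, UTF-8. Metadata is
carried in leading comment lines of the form ``# key: value`` (keys:
``sample_rate_hz``, ``foot_side``, ``subject_id``, ``accel_units``,
``gyro_units``).

HDF5: one group per foot (named after ``foot_side``) with datasets
``timestamps`` (N,), ``accel`` (N,3), ``gyro`` (N,3) and attributes
``sample_rate_hz``, ``foot_side``, ``subject_id``, ``accel_units``,
``gyro_units``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

from .errors import FormatError, UnitError, ValidationError

#: accepted unit declarations and the factor converting them to canonical SI
ACCEL_UNIT_FACTORS = {"m/s^2": 1.0, "m/s2": 1.0, "g": 9.80665}
GYRO_UNIT_FACTORS = {"rad/s": 1.0, "deg/s": math.pi / 180.0}

#: fraction of the nominal sample period tolerated as timestamp jitter
#: before downstream fixed-step processing demands resampling
JITTER_TOLERANCE = 0.10

_CSV_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]


@dataclass
class SensorMeta:
    """Metadata for one foot-worn sensor stream.

    Units here describe the data *as stored on disk*; in-memory recordings
    are always canonical (m/s², rad/s).
    """

    sample_rate_hz: float = 128.0
    foot_side: str = "left"
    subject_id: str = ""
    accel_units: str = "m/s^2"
    gyro_units: str = "rad/s"

    def __post_init__(self) -> None:
        if not self.sample_rate_hz > 0:
            raise ValidationError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")
        if self.foot_side not in ("left", "right"):
            raise ValidationError(f"foot_side must be 'left' or 'right', got {self.foot_side!r}")
        if self.accel_units not in ACCEL_UNIT_FACTORS:
            raise UnitError(
                f"unsupported accel units {self.accel_units!r}; "
                f"supported: {sorted(ACCEL_UNIT_FACTORS)}"
            )
        if self.gyro_units not in GYRO_UNIT_FACTORS:
            raise UnitError(
                f"unsupported gyro units {self.gyro_units!r}; "
                f"supported: {sorted(GYRO_UNIT_FACTORS)}"
            )


@dataclass
class ImuRecording:
    """Validated, canonical-unit IMU stream for one foot.

    Attributes
    ----------
    timestamps : (N,) float64, seconds, strictly increasing
    accel : (N, 3) float64, m/s², body frame, gravity-inclusive
    gyro : (N, 3) float64, rad/s, body frame
    meta : SensorMeta
    """

    timestamps: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    meta: SensorMeta = field(default_factory=SensorMeta)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        self.accel = np.asarray(self.accel, dtype=np.float64)
        self.gyro = np.asarray(self.gyro, dtype=np.float64)
        n = self.timestamps.shape[0]
        if n < 2:
            raise ValidationError(f"recording needs at least 2 samples, got {n}")
        if self.accel.shape != (n, 3) or self.gyro.shape != (n, 3):
            raise ValidationError(
                f"shape mismatch: timestamps {n}, accel {self.accel.shape}, gyro {self.gyro.shape}"
            )
        if not (
            np.all(np.isfinite(self.timestamps))
            and np.all(np.isfinite(self.accel))
            and np.all(np.isfinite(self.gyro))
        ):
            raise ValidationError("recording contains non-finite values")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValidationError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.timestamps.shape[0]

    @property
    def duration(self) -> float:
        """Span of the recording in seconds."""
        return float(self.timestamps[-1] - self.timestamps[0])

    @property
    def dt_nominal(self) -> float:
        return 1.0 / self.meta.sample_rate_hz

    def is_uniform(self, tolerance: float = JITTER_TOLERANCE) -> bool:
        """Whether timestamp jitter stays below ``tolerance`` × nominal period."""
        dt = np.diff(self.timestamps)
        return bool(np.max(np.abs(dt - self.dt_nominal)) <= tolerance * self.dt_nominal)


def _canonicalize(accel: np.ndarray, gyro: np.ndarray, meta: SensorMeta) -> tuple[np.ndarray, np.ndarray, SensorMeta]:
    accel = accel * ACCEL_UNIT_FACTORS[meta.accel_units]
    gyro = gyro * GYRO_UNIT_FACTORS[meta.gyro_units]
    meta = replace(meta, accel_units="m/s^2", gyro_units="rad/s")
    return accel, gyro, meta


def read_recording(path, format: str | None = None, foot_side: str | None = None) -> ImuRecording:
    """Read and validate a recording, converting declared units to SI.

    Parameters
    ----------
    path : str or Path
    format : {"csv", "hdf5"}, optional
        Inferred from the file extension when omitted.
    foot_side : str, optional
        For HDF5 files holding both feet, which group to read.
    """
    fmt = format or _infer_format(path)
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "hdf5":
        return _read_hdf5(path, foot_side)
    raise FormatError(f"unknown format {fmt!r}")


def write_recording(rec: ImuRecording, path, format: str | None = None) -> None:
    """Write a recording in canonical SI units.

    HDF5 round trips are bitwise lossless; CSV stores 9 significant digits.
    """
    fmt = format or _infer_format(path)
    if fmt == "csv":
        _write_csv(rec, path)
    elif fmt == "hdf5":
        _write_hdf5(rec, path)
    else:
        raise FormatError(f"unknown format {fmt!r}")


def _infer_format(path) -> str:
    s = str(path).lower()
    if s.endswith((".h5", ".hdf5", ".hdf")):
        return "hdf5"
    return "csv"


def _read_csv(path) -> ImuRecording:
    header: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            pos = fh.tell()
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                header[key.strip()] = value.strip()
        df = pd.read_csv(fh)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"CSV missing columns {missing}; expected {_CSV_COLUMNS}")
    meta = SensorMeta(
        sample_rate_hz=float(header.get("sample_rate_hz", 128.0)),
        foot_side=header.get("foot_side", "left"),
        subject_id=header.get("subject_id", ""),
        accel_units=header.get("accel_units", "m/s^2"),
        gyro_units=header.get("gyro_units", "rad/s"),
    )
    accel = df[["ax", "ay", "az"]].to_numpy(dtype=np.float64)
    gyro = df[["gx", "gy", "gz"]].to_numpy(dtype=np.float64)
    accel, gyro, meta = _canonicalize(accel, gyro, meta)
    return ImuRecording(df["t"].to_numpy(dtype=np.float64), accel, gyro, meta)


def _write_csv(rec: ImuRecording, path) -> None:
    m = rec.meta
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# sample_rate_hz: {m.sample_rate_hz}\n")
        fh.write(f"# foot_side: {m.foot_side}\n")
        fh.write(f"# subject_id: {m.subject_id}\n")
        fh.write("# accel_units: m/s^2\n")
        fh.write("# gyro_units: rad/s\n")
        fh.write(",".join(_CSV_COLUMNS) + "\n")
        data = np.column_stack([rec.timestamps, rec.accel, rec.gyro])
        np.savetxt(fh, data, fmt="%.9g", delimiter=",")


def _read_hdf5(path, foot_side: str | None) -> ImuRecording:
    with h5py.File(path, "r") as f:
        groups = [k for k in f.keys() if isinstance(f[k], h5py.Group)]
        if foot_side is not None:
            if foot_side not in f:
                raise FormatError(f"no group {foot_side!r} in {path}")
            g = f[foot_side]
        elif len(groups) == 1:
            g = f[groups[0]]
        else:
            raise FormatError(
                f"HDF5 file has groups {groups}; pass foot_side to select one"
            )
        for ds in ("timestamps", "accel", "gyro"):
            if ds not in g:
                raise FormatError(f"HDF5 group missing dataset {ds!r}")
        meta = SensorMeta(
            sample_rate_hz=float(g.attrs.get("sample_rate_hz", 128.0)),
            foot_side=str(g.attrs.get("foot_side", "left")),
            subject_id=str(g.attrs.get("subject_id", "")),
            accel_units=str(g.attrs.get("accel_units", "m/s^2")),
            gyro_units=str(g.attrs.get("gyro_units", "rad/s")),
        )
        accel = g["accel"][:]
        gyro = g["gyro"][:]
        accel, gyro, meta = _canonicalize(accel, gyro, meta)
        return ImuRecording(g["timestamps"][:], accel, gyro, meta)


def _write_hdf5(rec: ImuRecording, path) -> None:
    m = rec.meta
    with h5py.File(path, "a") as f:
        if m.foot_side in f:
            del f[m.foot_side]
        g = f.create_group(m.foot_side)
        g.create_dataset("timestamps", data=rec.timestamps)
        g.create_dataset("accel", data=rec.accel)
        g.create_dataset("gyro", data=rec.gyro)
        g.attrs["sample_rate_hz"] = m.sample_rate_hz
        g.attrs["foot_side"] = m.foot_side
        g.attrs["subject_id"] = m.subject_id
        g.attrs["accel_units"] = "m/s^2"
        g.attrs["gyro_units"] = "rad/s"


def resample_uniform(rec: ImuRecording, target_rate: float) -> ImuRecording:
    """Linearly interpolate a recording onto an exactly uniform time grid.

    The new grid starts at the first timestamp with spacing
    ``1/target_rate`` and covers the original span (last node within one
    sample period of the original end).
    """
    if not target_rate > 0:
        raise ValidationError(f"target_rate must be > 0, got {target_rate}")
    dt = 1.0 / target_rate
    t0, t1 = rec.timestamps[0], rec.timestamps[-1]
    n = int(np.floor((t1 - t0) / dt + 1e-9)) + 1
    t_new = t0 + dt * np.arange(n)
    accel = np.column_stack(
        [np.interp(t_new, rec.timestamps, rec.accel[:, k]) for k in range(3)]
    )
    gyro = np.column_stack(
        [np.interp(t_new, rec.timestamps, rec.gyro[:, k]) for k in range(3)]
    )
    meta = replace(rec.meta, sample_rate_hz=float(target_rate))
    return ImuRecording(t_new, accel, gyro, meta)
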