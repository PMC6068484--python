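"""Raw multichannel walking recordings.

A recording holds synchronously sampled shank-IMU channels (tri-axial
gyroscope in deg/s, tri-axial accelerometer in g) plus two force-sensitive
resistor (FSR) channels under heel and toe. The FSRs serve only as the
ground-truth contact reference for segmentation; they are never model input.

All channels share one fixed sampling period of 10 ms (100 Hz).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidSignalError

#: Sampling period in seconds; every recording is uniformly sampled at 100 Hz.
SAMPLE_PERIOD_S = 0.01

#: Gyroscope full-range scale, deg/s.
GYRO_RANGE = 2000.0
#: Accelerometer full-range scale, g.
ACCEL_RANGE = 16.0

CSV_COLUMNS = ["t", "gx", "gy", "gz", "ax", "ay", "az", "fsr_heel", "fsr_toe"]


@dataclass
class RawRecording:
    """A uniformly sampled multichannel gait recording.

    Parameters
    ----------
    gyro : (T, 3) array, deg/s
    accel : (T, 3) array, g
    fsr_heel, fsr_toe : (T,) arrays, contact force in arbitrary units >= 0
    subject_id : subject identifier
    speed : walking speed, m/s (metadata only)
    incline : surface incline, degrees (metadata only)
    """

    gyro: np.ndarray
    accel: np.ndarray
    fsr_heel: np.ndarray
    fsr_toe: np.ndarray
    subject_id: str = "S1"
    speed: float = 2.6
    incline: float = 0.0

    def __post_init__(self):
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.fsr_heel = np.asarray(self.fsr_heel, dtype=float)
        self.fsr_toe = np.asarray(self.fsr_toe, dtype=float)
        self.validate()

    def validate(self) -> None:
        T = len(self.fsr_heel)
        if self.gyro.shape != (T, 3) or self.accel.shape != (T, 3) or self.fsr_toe.shape != (T,):
            raise InvalidSignalError("all channels must have equal length (gyro/accel Tx3, FSRs T)")
        for name, arr in (("gyro", self.gyro), ("accel", self.accel),
                          ("fsr_heel", self.fsr_heel), ("fsr_toe", self.fsr_toe)):
            if not np.all(np.isfinite(arr)):
                raise InvalidSignalError(f"{name} contains non-finite values")
        if np.any(np.abs(self.gyro) > GYRO_RANGE):
            raise InvalidSignalError(f"gyro exceeds ±{GYRO_RANGE} deg/s full scale")
        if np.any(np.abs(self.accel) > ACCEL_RANGE):
            raise InvalidSignalError(f"accel exceeds ±{ACCEL_RANGE} g full scale")
        if np.any(self.fsr_heel < 0) or np.any(self.fsr_toe < 0):
            raise InvalidSignalError("FSR force must be >= 0")

    def __len__(self) -> int:
        return len(self.fsr_heel)

    @property
    def imu(self) -> np.ndarray:
        """(T, 6) matrix of the six IMU channels: gx gy gz ax ay az."""
        return np.hstack([self.gyro, self.accel])

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds on the fixed 10 ms grid."""
        return np.arange(len(self)) * SAMPLE_PERIOD_S

    # ---------------------------------------------------------------- I/O
    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        """Write `t,gx,gy,gz,ax,ay,az,fsr_heel,fsr_toe` rows, one per 10 ms sample.

        With ``sidecar=True`` a ``<stem>.meta.yaml`` file records subject id,
        speed and incline next to the CSV.
        """
        path = Path(path)
        df = pd.DataFrame(
            np.column_stack([self.time, self.gyro, self.accel, self.fsr_heel, self.fsr_toe]),
            columns=CSV_COLUMNS,
        )
        df.to_csv(path, index=False)
        if sidecar:
            meta = {"subject_id": self.subject_id, "speed": float(self.speed),
                    "incline": float(self.incline)}
            path.with_suffix(".meta.yaml").write_text(yaml.safe_dump(meta))

    @classmethod
    def from_csv(cls, path: str | Path) -> "RawRecording":
        path = Path(path)
        df = pd.read_csv(path)
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise InvalidSignalError(f"recording CSV missing columns: {missing}")
        meta: dict = {}
        sidecar = path.with_suffix(".meta.yaml")
        if sidecar.exists():
            meta = yaml.safe_load(sidecar.read_text()) or {}
        return cls(
            gyro=df[["gx", "gy", "gz"]].to_numpy(),
            accel=df[["ax", "ay", "az"]].to_numpy(),
            fsr_heel=df["fsr_heel"].to_numpy(),
            fsr_toe=df["fsr_toe"].to_numpy(),
            subject_id=str(meta.get("subject_id", path.stem)),
            speed=float(meta.get("speed", 2.6)),
            incline=float(meta.get("incline", 0.0)),
        )
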