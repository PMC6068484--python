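"""Heel-strike segmentation and continuous gait-percent labelling.

A gait cycle runs from the initial contact (IC) of one foot to the next IC of
the same foot. The heel FSR gives the contact reference: a rising threshold
crossing marks IC. Each cycle is then divided evenly so that sample *i* of a
cycle of ``n`` samples carries the percent label ``i / n`` in [0, 1) — a
sawtooth that resets to 0 at every heel strike.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateCycleError, InvalidSignalError
from .recording import SAMPLE_PERIOD_S, RawRecording

#: Cycles outside [0.5 s, 2.5 s] are discarded as outliers (missed or double strikes).
MIN_CYCLE_S = 0.5
MAX_CYCLE_S = 2.5

#: Table of classical gait phases: upper percent bound (exclusive) of each of the
#: eight phases IC, mid-stance (FF), terminal mid-stance (FF), push off,
#: pre-swing, initial swing, midswing, terminal swing.
PHASE_UPPER_PERCENT = np.array([8.0, 30.0, 40.0, 50.0, 60.0, 75.0, 85.0, 100.0])

PHASE_NAMES = [
    "Initial Contact",
    "Mid Mid-stance (FF)",
    "Terminal Mid-stance (FF)",
    "Push Off",
    "Pre-swing",
    "Initial swing",
    "Midswing",
    "Terminal Swing",
]


@dataclass(frozen=True)
class CycleSegment:
    """One gait cycle as a half-open sample interval [start_idx, end_idx)."""

    start_idx: int
    end_idx: int

    def __post_init__(self):
        if self.end_idx <= self.start_idx:
            raise ValueError("cycle must satisfy end_idx > start_idx")

    @property
    def duration(self) -> int:
        return self.end_idx - self.start_idx


@dataclass
class PercentLabeledDataset:
    """Per-sample IMU matrix with continuous gait-percent labels.

    ``X`` has one row per retained cycle sample and s·d = 6 columns (two
    sensors × three axes; FSRs are excluded — they are reference only).
    ``y`` holds the percent label in [0, 1). ``cycle_ids`` maps every row to
    the index of the cycle it belongs to, which downstream splitting uses to
    keep whole cycles together.
    """

    X: np.ndarray
    y: np.ndarray
    cycle_bounds: list[CycleSegment] = field(default_factory=list)
    cycle_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __len__(self) -> int:
        return len(self.y)

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_bounds)


def detect_heel_strikes(
    fsr_heel: np.ndarray,
    threshold: float | None = None,
    min_cycle_ms: float = 500.0,
) -> np.ndarray:
    """Find heel-strike (IC) sample indices as rising threshold crossings.

    A crossing at index *i* means ``fsr[i] >= threshold`` while the previous
    sample was below it (a series starting at/above threshold crosses at 0).
    Crossings closer than ``min_cycle_ms`` to the previously accepted one are
    rejected (refractory rule against contact chatter).

    Parameters
    ----------
    fsr_heel : heel contact force series, arbitrary units >= 0.
    threshold : force threshold; defaults to 50 % of the channel maximum.
    min_cycle_ms : refractory period in milliseconds.

    Returns
    -------
    Sorted array of accepted crossing indices (empty for an empty series or a
    series that never crosses).
    """
    fsr = np.asarray(fsr_heel, dtype=float)
    if fsr.size == 0:
        return np.empty(0, dtype=int)
    if not np.all(np.isfinite(fsr)):
        raise InvalidSignalError("FSR series contains non-finite values")
    if threshold is None:
        threshold = 0.5 * float(fsr.max())
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if min_cycle_ms <= 0:
        raise ValueError("min_cycle_ms must be > 0")

    above = fsr >= threshold
    rising = np.flatnonzero(above & ~np.concatenate([[False], above[:-1]]))

    min_gap = int(round(min_cycle_ms / 1000.0 / SAMPLE_PERIOD_S))
    accepted: list[int] = []
    for idx in rising:
        if not accepted or idx - accepted[-1] >= min_gap:
            accepted.append(int(idx))
    return np.array(accepted, dtype=int)


def segment_cycles(
    recording: RawRecording | int,
    events: np.ndarray,
    min_cycle_s: float = MIN_CYCLE_S,
    max_cycle_s: float = MAX_CYCLE_S,
) -> list[CycleSegment]:
    """Cut a recording into half-open cycles [e_i, e_{i+1}) between IC events.

    ``recording`` may be the recording itself or just its length in samples.
    Cycles shorter than ``min_cycle_s`` or longer than ``max_cycle_s`` are
    dropped as outliers. Fewer than two events yields an empty list.
    """
    n_samples = len(recording) if isinstance(recording, RawRecording) else int(recording)
    events = np.asarray(events, dtype=int)
    if events.size and (np.any(np.diff(events) <= 0)):
        raise ValueError("events must be sorted strictly ascending")
    if events.size and (events[0] < 0 or events[-1] > n_samples):
        raise ValueError("events out of recording range")
    lo = int(round(min_cycle_s / SAMPLE_PERIOD_S))
    hi = int(round(max_cycle_s / SAMPLE_PERIOD_S))
    segments = []
    for start, end in zip(events[:-1], events[1:]):
        if lo <= end - start <= hi:
            segments.append(CycleSegment(int(start), int(end)))
    return segments


def label_percent(cycle: CycleSegment, quantize: bool = False) -> np.ndarray:
    """Percent labels for one cycle: sample i of n gets i/n in [0, 1).

    With ``quantize`` the labels snap down to the 1 % grid
    (floor(100·i/n)/100), matching a hard 1 %-bin discretisation.
    """
    n = cycle.duration
    if n < 2:
        raise DegenerateCycleError(f"cycle of {n} samples cannot carry a percent ramp")
    y = np.arange(n, dtype=float) / n
    if quantize:
        y = np.floor(100.0 * y) / 100.0
    return y


def build_percent_matrix(
    recording: RawRecording,
    cycles: list[CycleSegment],
    quantize: bool = False,
    channels: list[int] | None = None,
) -> PercentLabeledDataset:
    """Stack the IMU channels of all retained cycle samples with their labels.

    FSR channels never enter ``X``. ``channels`` optionally selects a subset
    of the six IMU columns (gx gy gz ax ay az); default uses all six.
    """
    n_samples = len(recording)
    imu = recording.imu
    if channels is not None:
        imu = imu[:, channels]
    prev_end = -1
    for c in cycles:
        if c.start_idx < prev_end or c.end_idx > n_samples or c.start_idx < 0:
            raise ValueError("cycles must be non-overlapping and within the recording")
        prev_end = c.end_idx
    if not cycles:
        return PercentLabeledDataset(
            X=np.empty((0, imu.shape[1])), y=np.empty(0), cycle_bounds=[],
            cycle_ids=np.empty(0, dtype=int),
        )
    X = np.vstack([imu[c.start_idx:c.end_idx] for c in cycles])
    y = np.concatenate([label_percent(c, quantize=quantize) for c in cycles])
    ids = np.concatenate([np.full(c.duration, i, dtype=int) for i, c in enumerate(cycles)])
    return PercentLabeledDataset(X=X, y=y, cycle_bounds=list(cycles), cycle_ids=ids)


def percent_to_phase(percent: float | np.ndarray) -> int | np.ndarray:
    """Map continuous gait percent in [0, 1) to one of the 8 classical phases.

    Phase intervals are half-open [lo, hi) in percent-of-cycle units, so the
    preimages partition [0, 1) with no gaps or overlaps.
    """
    p = np.asarray(percent, dtype=float)
    if np.any(p < 0) or np.any(p >= 1):
        raise ValueError("percent must lie in [0, 1)")
    labels = np.searchsorted(PHASE_UPPER_PERCENT[:-1], 100.0 * p, side="right")
    if np.isscalar(percent) or p.ndim == 0:
        return int(labels)
    return labels
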