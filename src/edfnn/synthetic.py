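"""Synthetic multi-subject walking recordings.

Real shank-IMU walking data are periodic, phase-informative and
subject-varying; that is all the percent estimator relies on, so the
generator produces smooth harmonic waveforms per IMU channel (with a dominant
sagittal-gyroscope swing peak near 70 % of the cycle) rather than a
biomechanical simulation. Contact structure follows the classical 60/40
stance–swing division: the heel FSR is active for the first quarter of the
cycle (contact onset defines percent 0), the toe FSR from 10 % until toe-off
at 60 %, so some FSR is loaded for exactly the first 60 % of every cycle.

FSR channels are noiseless binary-style pulses — they are the ground-truth
reference — while IMU channels carry seeded Gaussian noise scaled to a
fraction of each channel's amplitude. Cycle durations jitter around the
subject's cadence, emulating speed variation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .recording import SAMPLE_PERIOD_S, RawRecording

#: Contact support regions in cycle-percent units.
HEEL_SUPPORT = (0.0, 0.25)
TOE_SUPPORT = (0.10, 0.60)
FSR_AMPLITUDE = 1.0

#: Walking speeds used across trials, m/s.
SPEEDS = (2.2, 2.6, 3.2, 3.8)

# (harmonic multiple, amplitude, phase shift) triples per channel; gyro in
# deg/s, accel in g. The dominant gz term -cos(2π(p-0.2)) peaks at p = 0.7
# (the mid-swing shank rotation peak).
_HARMONICS = {
    "gx": [(1, 40.0, 1.0), (2, 25.0, 2.2), (3, 10.0, 0.7)],
    "gy": [(1, 120.0, -2.83), (2, 60.0, 1.1), (3, 20.0, 2.5)],
    "gz": [(2, 20.0, 0.9), (3, 8.0, 1.8)],  # plus the dominant -cos bump below
    "ax": [(1, 0.25, 2.0), (2, 0.15, 0.3), (4, 0.05, 1.0)],
    "ay": [(1, 0.30, 0.8), (3, 0.12, 1.9)],
    "az": [(1, 0.35, -0.63), (2, 0.18, 2.7), (4, 0.06, 0.4)],
}
_GZ_SWING = (150.0, 0.25)  # amplitude, phase offset of the -cos swing bump
CHANNELS = ("gx", "gy", "gz", "ax", "ay", "az")


@dataclass
class SubjectProfile:
    """Per-subject gait characteristics.

    cadence_mean/std : cycle duration in seconds (mean and jitter).
    channel_gains : multiplicative amplitude scaling of the 6 IMU channels.
    noise_std : IMU noise as a fraction of each channel's peak amplitude.
    incline : surface incline in degrees (0 or 15), modelled as a mild
        gain/offset perturbation of the waveform template.
    speed : nominal walking speed, m/s (metadata).
    """

    cadence_mean: float = 1.0
    cadence_std: float = 0.05
    channel_gains: np.ndarray = field(default_factory=lambda: np.ones(6))
    noise_std: float = 0.02
    incline: float = 0.0
    speed: float = 2.6
    subject_id: str = "S1"

    def __post_init__(self):
        self.channel_gains = np.asarray(self.channel_gains, dtype=float)
        if self.cadence_mean <= 0:
            raise ValueError("cadence_mean must be > 0")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")
        if not min(SPEEDS) <= self.speed <= 4.0:
            raise ValueError(f"speed {self.speed} outside the studied range")


@dataclass
class GeneratorConfig:
    """Benchmark layout: how many subjects, how many cycles each, one seed."""

    n_subjects: int = 8
    cycles_per_subject: int = 250
    seed: int = 0
    profiles: list[SubjectProfile] | None = None

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.cycles_per_subject < 2:
            raise ValueError("cycles_per_subject must be >= 2")


@dataclass
class SyntheticTruth:
    """Generator-side ground truth: heel-strike onsets and per-sample phase."""

    onsets: np.ndarray
    phase: np.ndarray


def _in_support(phase: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (phase >= lo) & (phase < hi)


def cycle_template(phase, profile: SubjectProfile) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless waveform values at the given cycle phases in [0, 1).

    Returns ``(imu, fsr)`` with shapes (..., 6) and (..., 2). The template is
    1-periodic by construction (every term is a sinusoid of integer harmonic,
    and the contact pulses depend on phase only).
    """
    p = np.asarray(phase, dtype=float)
    if np.any(p < 0) or np.any(p >= 1):
        raise ValueError("phase must lie in [0, 1)")
    two_pi = 2.0 * np.pi
    cols = []
    for name in CHANNELS:
        v = np.zeros_like(p)
        for mult, amp, shift in _HARMONICS[name]:
            v = v + amp * np.sin(two_pi * mult * p + shift)
        if name == "gz":
            amp, off = _GZ_SWING
            v = v - amp * np.cos(two_pi * (p - off))
        cols.append(v)
    imu = np.stack(cols, axis=-1) * profile.channel_gains
    if profile.incline:
        scale = profile.incline / 15.0
        imu = imu * (1.0 + 0.15 * scale)
        imu[..., 3:] = imu[..., 3:] + 0.08 * scale  # gravity component shift on accel
    heel = np.where(_in_support(p, *HEEL_SUPPORT), FSR_AMPLITUDE, 0.0)
    toe = np.where(_in_support(p, *TOE_SUPPORT), FSR_AMPLITUDE, 0.0)
    return imu, np.stack([heel, toe], axis=-1)


def _channel_amplitudes(profile: SubjectProfile) -> np.ndarray:
    grid = np.linspace(0.0, 1.0, 1000, endpoint=False)
    imu, _ = cycle_template(grid, profile)
    return np.abs(imu).max(axis=0)


def generate_recording(
    profile: SubjectProfile, n_cycles: int, seed: int = 0
) -> tuple[RawRecording, SyntheticTruth]:
    """Generate ``n_cycles`` complete gait cycles plus their ground truth.

    Cycle durations are drawn from N(cadence_mean, cadence_std) (clipped to
    the plausible 0.55–2.45 s band) and sampled on the 10 ms grid. A one-
    sample stub of the next cycle's heel contact is appended so that the final
    cycle is bounded by a detectable heel strike; the truth therefore lists
    ``n_cycles + 1`` onsets. IMU noise is seeded Gaussian with standard
    deviation ``noise_std`` × channel amplitude; FSRs are noiseless.
    """
    if n_cycles < 2:
        raise ValueError("n_cycles must be >= 2")
    rng = np.random.default_rng(seed)
    durations_s = rng.normal(profile.cadence_mean, profile.cadence_std, n_cycles)
    durations_s = np.clip(durations_s, 0.55, 2.45)
    n_samples = np.rint(durations_s / SAMPLE_PERIOD_S).astype(int)

    phase = np.concatenate([np.arange(n) / n for n in n_samples] + [[0.0]])
    onsets = np.concatenate([[0], np.cumsum(n_samples)])

    imu, fsr = cycle_template(phase, profile)
    amps = _channel_amplitudes(profile)
    imu = imu + rng.normal(0.0, 1.0, imu.shape) * (profile.noise_std * amps)

    rec = RawRecording(
        gyro=imu[:, :3], accel=imu[:, 3:],
        fsr_heel=fsr[:, 0], fsr_toe=fsr[:, 1],
        subject_id=profile.subject_id, speed=profile.speed, incline=profile.incline,
    )
    return rec, SyntheticTruth(onsets=onsets, phase=phase)


def default_profiles(n_subjects: int, seed: int = 0) -> list[SubjectProfile]:
    """Distinct subject profiles: varying cadence, per-channel gains, incline.

    Cadences spread over 0.9–1.2 s with 5 % jitter, gains drawn in [0.7, 1.3],
    noise at 2 % of amplitude; the last two subjects walk the 15° incline,
    speeds cycle through the studied 2.2–3.8 m/s set.
    """
    rng = np.random.default_rng(seed)
    profiles = []
    cadences = np.linspace(0.9, 1.2, n_subjects)
    for i in range(n_subjects):
        profiles.append(SubjectProfile(
            cadence_mean=float(cadences[i]),
            cadence_std=0.05 * float(cadences[i]),
            channel_gains=rng.uniform(0.7, 1.3, 6),
            noise_std=0.02,
            incline=15.0 if n_subjects > 2 and i >= n_subjects - 2 else 0.0,
            speed=SPEEDS[i % len(SPEEDS)],
            subject_id=f"S{i + 1}",
        ))
    return profiles


def generate_benchmark(
    config: GeneratorConfig = GeneratorConfig(),
) -> dict[str, tuple[RawRecording, SyntheticTruth]]:
    """Per-subject recordings with distinct profiles, deterministic under seed."""
    profiles = config.profiles or default_profiles(config.n_subjects, seed=config.seed)
    if len(profiles) != config.n_subjects:
        raise ValueError("profiles length must match n_subjects")
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_subjects) % (2 ** 31)
    out = {}
    for profile, s in zip(profiles, seeds):
        out[profile.subject_id] = generate_recording(
            profile, config.cycles_per_subject, seed=int(s))
    return out
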