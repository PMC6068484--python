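"""Glue from raw recordings to embedded train-ready datasets."""
from __future__ import annotations

import numpy as np

from .embedding import DelayConfig, EmbeddedDataset, apply_exponential_window
from .recording import RawRecording
from .segmentation import (PercentLabeledDataset, build_percent_matrix,
                           detect_heel_strikes, segment_cycles)


def recording_to_labeled(
    recording: RawRecording,
    threshold: float | None = None,
    quantize: bool = False,
    channels: list[int] | None = None,
) -> PercentLabeledDataset:
    """Detect heel strikes, cut cycles and label every sample with its percent."""
    events = detect_heel_strikes(recording.fsr_heel, threshold=threshold)
    cycles = segment_cycles(recording, events)
    return build_percent_matrix(recording, cycles, quantize=quantize, channels=channels)


def recording_to_embedded(
    recording: RawRecording,
    cfg: DelayConfig = DelayConfig(),
    threshold: float | None = None,
    quantize: bool = False,
    channels: list[int] | None = None,
) -> EmbeddedDataset:
    """Full pipeline: segmentation, percent labelling, exponential-window embedding."""
    labeled = recording_to_labeled(recording, threshold=threshold,
                                   quantize=quantize, channels=channels)
    return apply_exponential_window(labeled, cfg)


def standard_single_subject(
    n_cycles: int = 250, seed: int = 0, cfg: DelayConfig = DelayConfig()
) -> EmbeddedDataset:
    """The reference single-subject benchmark: cadence 1.0 s ± 5 %, 2 % noise."""
    from .synthetic import SubjectProfile, generate_recording

    profile = SubjectProfile(cadence_mean=1.0, cadence_std=0.05, noise_std=0.02)
    rec, _ = generate_recording(profile, n_cycles, seed=seed)
    return recording_to_embedded(rec, cfg)


def standard_benchmark(
    n_subjects: int = 8, n_cycles: int = 250, seed: int = 0,
    cfg: DelayConfig = DelayConfig(),
) -> tuple[dict[str, EmbeddedDataset], EmbeddedDataset]:
    """The reference multi-subject benchmark and its joined dataset.

    Subjects carry distinct cadences, channel gains and inclines (see
    :func:`edfnn.synthetic.default_profiles`); returns (per-subject embedded
    datasets, joined dataset).
    """
    from .synthetic import GeneratorConfig, generate_benchmark

    bench = generate_benchmark(GeneratorConfig(n_subjects, n_cycles, seed))
    per = {sid: recording_to_embedded(rec, cfg) for sid, (rec, _) in bench.items()}
    return per, concat_embedded(list(per.values()))


def concat_embedded(datasets: list[EmbeddedDataset]) -> EmbeddedDataset:
    """Join per-subject embedded datasets; cycle ids are offset so they stay unique."""
    if not datasets:
        raise ValueError("need at least one dataset")
    first = datasets[0]
    ids, offset = [], 0
    for ds in datasets:
        if ds.k != first.k or ds.n_channels != first.n_channels:
            raise ValueError("datasets have incompatible layouts")
        if ds.cycle_ids is None:
            raise ValueError("joining requires cycle ids on every dataset")
        ids.append(ds.cycle_ids + offset)
        offset += int(ds.cycle_ids.max()) + 1
    return EmbeddedDataset(
        Xd=np.vstack([ds.Xd for ds in datasets]),
        Yd=np.vstack([ds.Yd for ds in datasets]),
        t_index=np.concatenate([ds.t_index for ds in datasets]),
        lags=first.lags,
        n_channels=first.n_channels,
        cycle_ids=np.concatenate(ids),
        config=first.config,
    )
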