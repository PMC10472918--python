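"""Orchestration helpers: synthetic cohort -> preprocessed segment datasets.

These drive the standard signal path for experiments: simulate each subject,
optionally perturb the continuous recording (channel time-shifts), bandpass
filter, optionally reject artifact components with ICA, select and normalize
segments, optionally shuffle time points, and stack everything into
:class:`~spaten.minispaten.SegmentDataset` objects.  Subjects are processed
one at a time so memory stays flat for large cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .minispaten import SegmentDataset
from .perturb import PerturbationSpec, shift_channels, shuffle_dataset_time
from .preprocess import (
    band_limits,
    bandpass_filter,
    detect_bad_channels,
    interpolate_bad_channels,
    normalize_segment,
    remove_artifact_components,
    select_segments,
)
from .synthetic_cohort import Recording, SimConfig, iter_cohort

__all__ = [
    "CohortSpec",
    "prepare_recording",
    "build_dataset",
    "build_split_datasets",
    "qrs_locked_relevance",
    "locked_ratio",
]


@dataclass(frozen=True)
class CohortSpec:
    """Sizes and preprocessing switches for one experimental cohort."""

    n_subjects: int = 60
    female_fraction: float = 0.5
    n_segments: int = 50
    seg_len_s: float = 4.0
    skip_s: float = 120.0
    band: str = "broadband"
    ica: bool = False
    signal: str = "eeg"  # "eeg" (21 channels) or "ecg" (the single reference)
    perturbation: PerturbationSpec = field(default_factory=PerturbationSpec)
    sim: SimConfig = field(default_factory=SimConfig)


def prepare_recording(
    recording: Recording, cohort: CohortSpec, subject_index: int = 0
) -> list:
    """Run one recording through the configured signal path; returns segments."""
    pert = cohort.perturbation
    if pert.kind == "shift_channels":
        recording = shift_channels(
            recording, pert.max_shift_s, seed=pert.seed + subject_index
        )
    recording = bandpass_filter(recording, band_limits(cohort.band))
    bad = detect_bad_channels(recording)
    if bad:
        recording = interpolate_bad_channels(recording, bad)
    if cohort.ica:
        recording, _ = remove_artifact_components(
            recording, seed=cohort.sim.seed + subject_index
        )
    segments = select_segments(
        recording,
        n_segments=cohort.n_segments,
        seg_len_s=cohort.seg_len_s,
        skip_s=cohort.skip_s,
        band=cohort.band,
    )
    if cohort.signal == "ecg":
        # same quality-selected windows, but the single ECG reference row
        from dataclasses import replace as _replace

        seg_len = segments[0].data.shape[1]
        segments = [
            _replace(
                s,
                data=recording.ecg[s.start_sample : s.start_sample + seg_len][None, :],
                channels=(recording.layout.ecg_label,),
            )
            for s in segments
        ]
    return [normalize_segment(s) for s in segments]


def build_dataset(cohort: CohortSpec) -> SegmentDataset:
    """Simulate and preprocess a whole cohort into one stacked dataset."""
    X, y, ids = [], [], []
    channels: tuple[str, ...] = ()
    for i, (subject, rec) in enumerate(
        iter_cohort(cohort.n_subjects, cohort.female_fraction, cohort.sim)
    ):
        segments = prepare_recording(rec, cohort, subject_index=i)
        channels = segments[0].channels
        for s in segments:
            X.append(s.data.astype(np.float32))
            y.append(subject.sex)
            ids.append(subject.subject_id)
    ds = SegmentDataset(
        X=np.stack(X), y=np.array(y), subject_ids=np.array(ids), channels=channels
    )
    if cohort.perturbation.kind == "shuffle_time":
        ds = shuffle_dataset_time(ds, seed=cohort.perturbation.seed)
    return ds


def build_split_datasets(
    train_cohort: CohortSpec, n_eval_subjects: int, eval_seed_offset: int = 10_000
) -> tuple[SegmentDataset, SegmentDataset]:
    """Train/eval datasets with disjoint subjects.

    The evaluation cohort shares all study conditions (including the
    cohort-level sex-typical structure, which is tied to ``sim.seed``) but
    uses distinct subject identifiers, so evaluation subjects are unseen
    individuals from the same population.
    """
    train_ds = build_dataset(train_cohort)
    eval_cohort = replace(train_cohort, n_subjects=n_eval_subjects)
    # the "e" id prefix drives distinct per-subject seeds: evaluation subjects
    # are independent draws from the same population, never seen in training
    X, y, ids = [], [], []
    channels: tuple[str, ...] = ()
    for i, (subject, rec) in enumerate(
        iter_cohort(n_eval_subjects, eval_cohort.female_fraction, eval_cohort.sim,
                    id_prefix="e")
    ):
        segments = prepare_recording(rec, eval_cohort, subject_index=eval_seed_offset + i)
        channels = segments[0].channels
        for s in segments:
            X.append(s.data.astype(np.float32))
            y.append(subject.sex)
            ids.append(subject.subject_id)
    eval_ds = SegmentDataset(
        X=np.stack(X), y=np.array(y), subject_ids=np.array(ids), channels=channels
    )
    if eval_cohort.perturbation.kind == "shuffle_time":
        eval_ds = shuffle_dataset_time(
            eval_ds, seed=eval_cohort.perturbation.seed + eval_seed_offset
        )
    return train_ds, eval_ds


def qrs_locked_relevance(
    model,
    cohort: CohortSpec,
    n_subjects: int,
    id_prefix: str = "r",
    window_s: float = 0.5,
):
    """QRS-locked average of the absolute relevance over a fresh cohort.

    For every subject the recording is preprocessed exactly as for training
    (same ``cohort`` switches), the total relevance of each selected segment
    is computed, summed over channels as |R|, and averaged in epochs of
    +-``window_s`` around every R peak that falls inside a segment.  The mean
    ECG waveform (uV, band-filtered) is collected alongside for reference.
    """
    from .relevance import event_locked_average, relevance_timecourse, total_relevance

    series, events, ecgs = [], [], []
    for i, (subject, rec) in enumerate(
        iter_cohort(n_subjects, cohort.female_fraction, cohort.sim, id_prefix)
    ):
        filtered = bandpass_filter(rec, band_limits(cohort.band))
        if cohort.ica:
            filtered, _ = remove_artifact_components(
                filtered, seed=cohort.sim.seed + 7000 + i
            )
        segments = select_segments(
            filtered, n_segments=cohort.n_segments,
            seg_len_s=cohort.seg_len_s, skip_s=cohort.skip_s, band=cohort.band,
        )
        for seg in segments:
            norm = normalize_segment(seg)
            R = total_relevance(norm.data, model)
            series.append(relevance_timecourse(R, absolute=True))
            n_t = norm.data.shape[1]
            local = filtered.qrs_times - seg.start_sample
            events.append(local[(local >= 0) & (local < n_t)])
            ecgs.append(
                filtered.ecg[seg.start_sample : seg.start_sample + n_t]
            )
    return event_locked_average(
        series, events, window_s=window_s, fs=cohort.sim.fs, ecg_series=ecgs
    )


def locked_ratio(avg, fs: float = 250.0, far_ms: float = 150.0) -> float:
    """Peak-to-baseline ratio of a QRS-locked |R| curve.

    Ratio of the mean |R| at lag 0 to the mean over lags beyond +-``far_ms``.
    """
    import numpy as _np

    lags_ms = avg.lags / fs * 1000.0
    center = avg.mean_abs_relevance[_np.argmin(_np.abs(lags_ms))]
    far = avg.mean_abs_relevance[_np.abs(lags_ms) > far_ms].mean()
    return float(center / far)
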