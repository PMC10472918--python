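"""Explorative data modifications that localize where the label information lives.

* ``shuffle_time_columns`` permutes sample columns jointly across channels:
  waveforms, spectra and cross-temporal structure are destroyed while every
  instantaneous topography survives.  Paired with single-sample (channels x 1)
  kernels this isolates purely topographic information.
* ``shift_channels`` delays/advances each EEG channel independently by up to
  ``max_shift_s`` on the continuous recording (before segmentation), keeping
  per-channel waveforms and spectra intact while destroying cross-channel
  alignment -- the complementary perturbation.
* ``restrict_channels`` projects a dataset onto a channel subset (e.g. the
  single ECG channel with 1 x 19 kernels).
* ``greedy_channel_selection`` ranks channels by forward selection on
  classification accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError, InvalidInputError
from .minispaten import ModelSpec, SegmentDataset
from .preprocess import Segment
from .synthetic_cohort import Recording

__all__ = [
    "PerturbationSpec",
    "shuffle_time_columns",
    "shuffle_dataset_time",
    "shift_channels",
    "restrict_channels",
    "greedy_channel_selection",
]

PERTURBATION_KINDS = ("shuffle_time", "shift_channels", "channel_subset", "none")


@dataclass(frozen=True)
class PerturbationSpec:
    kind: str = "none"
    max_shift_s: float = 0.2
    channels: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PERTURBATION_KINDS:
            raise ConfigurationError(
                f"kind must be one of {PERTURBATION_KINDS}, got {self.kind!r}"
            )
        if self.max_shift_s < 0:
            raise ConfigurationError("max_shift_s must be >= 0")
        if self.kind == "channel_subset" and not self.channels:
            raise ConfigurationError("channel_subset requires a nonempty channel list")


def shuffle_time_columns(segment: Segment | np.ndarray, seed: int = 0):
    """Apply one random permutation of the sample indices to all channels.

    Columns move as units, so the multiset of instantaneous topographies is
    preserved exactly.  Returns the same type as the input.
    """
    data = segment.data if isinstance(segment, Segment) else np.asarray(segment)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(data.shape[1])
    shuffled = data[:, perm]
    if isinstance(segment, Segment):
        return Segment(
            data=shuffled, start_sample=segment.start_sample,
            subject=segment.subject, band=segment.band,
            channels=segment.channels, normalized=segment.normalized,
        )
    return shuffled


def shuffle_dataset_time(dataset: SegmentDataset, seed: int = 0) -> SegmentDataset:
    """Independent column permutation per segment (vectorized over the stack)."""
    rng = np.random.default_rng(seed)
    X = dataset.X
    out = np.empty_like(X)
    for i in range(len(X)):
        out[i] = X[i][:, rng.permutation(X.shape[2])]
    return SegmentDataset(
        X=out, y=dataset.y, subject_ids=dataset.subject_ids, channels=dataset.channels
    )


def shift_channels(
    recording: Recording, max_shift_s: float = 0.2, seed: int = 0
) -> Recording:
    """Shift each EEG channel by an independent uniform integer offset.

    Offsets are drawn from [-fs*max_shift_s, +fs*max_shift_s] and applied to
    the continuous recording; both edges are trimmed by the maximum shift so
    no padding values can enter later segments.  The ECG channel is not
    shifted; QRS annotations are re-indexed onto the trimmed support.
    """
    if max_shift_s < 0:
        raise ConfigurationError("max_shift_s must be >= 0")
    m = int(round(max_shift_s * recording.fs))
    if m == 0:
        return recording
    n = recording.n_samples
    if n <= 2 * m:
        raise ConfigurationError("recording shorter than twice the maximum shift")
    rng = np.random.default_rng(seed)
    n_eeg = recording.layout.n_eeg
    shifts = rng.integers(-m, m + 1, size=n_eeg)
    out = np.empty((n_eeg + 1, n - 2 * m), dtype=recording.signal.dtype)
    for c in range(n_eeg):
        s = int(shifts[c])
        # shift by s: sample at trimmed position t comes from original t + m - s
        out[c] = recording.signal[c, m - s : n - m - s]
    out[n_eeg] = recording.signal[n_eeg, m : n - m]
    qrs = recording.qrs_times - m
    qrs = qrs[(qrs >= 0) & (qrs < n - 2 * m)]
    return Recording(
        signal=out, layout=recording.layout, fs=recording.fs,
        qrs_times=qrs, subject=recording.subject,
    )


def restrict_channels(
    dataset: SegmentDataset,
    channels,
    spec: ModelSpec | None = None,
) -> tuple[SegmentDataset, ModelSpec]:
    """Project a dataset onto a channel subset and adapt the model spec.

    Returns (restricted dataset, spec with ``n_channels = len(channels)``),
    e.g. 1 x 19 kernels when restricting to the single ECG channel.
    """
    channels = tuple(channels)
    if not channels:
        raise InvalidInputError("channel subset must be nonempty")
    labels = dataset.channels
    unknown = [c for c in channels if c not in labels]
    if unknown:
        raise InvalidInputError(f"unknown channel labels: {unknown}")
    rows = [labels.index(c) for c in channels]
    sub = SegmentDataset(
        X=dataset.X[:, rows, :], y=dataset.y,
        subject_ids=dataset.subject_ids, channels=channels,
    )
    base = spec or ModelSpec(input_len=dataset.X.shape[2])
    new_spec = replace(base, n_channels=len(channels))
    return sub, new_spec


def greedy_channel_selection(
    channel_labels,
    evaluate_fn,
    max_channels: int,
    n_repeats: int = 5,
    seed: int = 0,
) -> list[dict]:
    """Forward selection: repeatedly add the channel giving the largest gain.

    ``evaluate_fn(channels: tuple[str, ...], seed: int) -> accuracy`` trains
    and evaluates a classifier on the given channel subset (it must be
    deterministic given its seed).  Accuracies are averaged over ``n_repeats``
    seeds; candidate ties resolve to the alphabetically first label.

    Returns one dict per step: ``{"channel", "channels", "mean_accuracy", "sd"}``.
    """
    channel_labels = list(channel_labels)
    if max_channels < 1:
        raise InvalidInputError("max_channels must be >= 1")
    if max_channels > len(channel_labels):
        raise InvalidInputError("max_channels exceeds the number of channels")
    selected: list[str] = []
    steps: list[dict] = []
    for step in range(max_channels):
        best = None  # (mean, sd, label)
        for cand in sorted(set(channel_labels) - set(selected)):
            subset = tuple(selected + [cand])
            accs = [
                float(evaluate_fn(subset, seed + 1000 * step + r))
                for r in range(n_repeats)
            ]
            mean, sd = float(np.mean(accs)), float(np.std(accs))
            if best is None or mean > best[0]:
                best = (mean, sd, cand)
        mean, sd, label = best
        selected.append(label)
        steps.append(
            {
                "channel": label,
                "channels": tuple(selected),
                "mean_accuracy": mean,
                "sd": sd,
            }
        )
    return steps
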