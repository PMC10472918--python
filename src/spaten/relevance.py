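"""Closed-form relevance attribution for the shallow CNN.

For each pooling window i and kernel k, only the lag with the maximum
(rectified) correlation contributes to the prediction.  The relevance of the
data points under that best-matching placement is

    R'_{i,k} = X_[argmax C_{i,k}] (Hadamard) K_k * max C_{i,k}
    R_{i,k}  = R'_{i,k} * w_k

i.e. the kernel-shaped submatrix of the segment at the argmax lag,
element-wise multiplied by the kernel, scaled by the window's maximum
correlation and by the kernel's dense-layer weight.  Contributions of
overlapping windows accumulate additively; windows whose rectified maximum is
zero contribute nothing.  Summing R over kernels gives the total relevance
map; negative values pull the prediction toward female, positive toward male.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError
from .minispaten import ModelSpec, TrainedModel
from .preprocess import Segment

__all__ = [
    "RelevanceMatrix",
    "EventLockedAverage",
    "window_argmax",
    "kernel_relevance",
    "total_relevance",
    "relevance_timecourse",
    "event_locked_average",
]


@dataclass
class RelevanceMatrix:
    """Signed per-channel, per-sample attribution aligned with its segment."""

    values: np.ndarray
    segment_ref: Segment | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("relevance values must be finite")


@dataclass(frozen=True)
class EventLockedAverage:
    lags: np.ndarray                # sample offsets, symmetric around 0
    mean_abs_relevance: np.ndarray  # per-lag average of |R| channel sums
    mean_ecg: np.ndarray | None     # per-lag average ECG amplitude (uV)
    n_events: int
    n_skipped: int = 0


def _spec_for(segment_data: np.ndarray, kernel: np.ndarray,
              pool_window: int, pool_stride: int) -> ModelSpec:
    n_ch, n_t = segment_data.shape
    return ModelSpec(
        n_channels=n_ch, input_len=n_t, n_kernels=1, kernel_len=kernel.shape[1],
        pool_window=pool_window, pool_stride=pool_stride,
    )


def _as_data(segment: Segment | np.ndarray) -> np.ndarray:
    data = segment.data if isinstance(segment, Segment) else np.asarray(segment)
    return data.astype(np.float64)


def window_argmax(
    segment: Segment | np.ndarray,
    kernel: np.ndarray,
    pool_window: int = 75,
    pool_stride: int = 25,
) -> list[tuple[int, float]]:
    """Per-window (argmax lag, rectified max correlation) pairs for one kernel.

    Lags are restricted to positions where the kernel span lies fully inside
    the segment (all valid lags of the correlation curve).  Ties resolve to
    the earliest lag; a window whose rectified maximum is zero reports the
    earliest lag of the window with value 0.
    """
    data = _as_data(segment)
    kernel = np.asarray(kernel, dtype=np.float64)
    if kernel.ndim != 2 or kernel.shape[0] != data.shape[0]:
        raise InvalidInputError(
            f"kernel channel count {kernel.shape} does not match segment "
            f"{data.shape}"
        )
    spec = _spec_for(data, kernel, pool_window, pool_stride)
    L = kernel.shape[1]
    win = np.lib.stride_tricks.sliding_window_view(data, L, axis=1)  # (C,curve,L)
    curve = np.tensordot(win, kernel, axes=([0, 2], [0, 1]))
    rect = np.maximum(curve, 0.0)
    out = []
    for a, b in spec.window_bounds():
        seg = rect[a:b]
        lag = int(np.argmax(seg)) + a  # np.argmax: earliest index on ties
        out.append((lag, float(rect[lag])))
    return out


def kernel_relevance(
    segment: Segment | np.ndarray,
    kernel: np.ndarray,
    weight: float,
    pool_window: int = 75,
    pool_stride: int = 25,
) -> RelevanceMatrix:
    """Relevance matrix of one kernel, accumulated over all pooling windows."""
    data = _as_data(segment)
    kernel = np.asarray(kernel, dtype=np.float64)
    L = kernel.shape[1]
    R = np.zeros_like(data)
    for lag, cmax in window_argmax(segment, kernel, pool_window, pool_stride):
        if cmax <= 0.0:
            continue
        R[:, lag : lag + L] += data[:, lag : lag + L] * kernel * cmax * weight
    return RelevanceMatrix(
        values=R, segment_ref=segment if isinstance(segment, Segment) else None
    )


def total_relevance(
    segment: Segment | np.ndarray, model: TrainedModel
) -> RelevanceMatrix:
    """Sum of the kernel-specific relevance matrices over all kernels."""
    data = _as_data(segment)
    spec = model.spec
    if data.shape != (spec.n_channels, spec.input_len):
        raise InvalidInputError(
            f"segment shape {data.shape} does not match model spec"
        )
    total = np.zeros_like(data)
    for k in range(spec.n_kernels):
        total += kernel_relevance(
            data, model.kernels[k], float(model.dense_weights[k]),
            spec.pool_window, spec.pool_stride,
        ).values
    return RelevanceMatrix(
        values=total, segment_ref=segment if isinstance(segment, Segment) else None
    )


def relevance_timecourse(R: RelevanceMatrix, absolute: bool = False) -> np.ndarray:
    """Per-sample sum over channels; ``absolute`` sums |R| entries."""
    v = np.abs(R.values) if absolute else R.values
    return v.sum(axis=0)


def event_locked_average(
    timecourses,
    qrs_times,
    window_s: float = 0.5,
    fs: float = 250.0,
    ecg_series=None,
) -> EventLockedAverage:
    """Average |R| time courses (and optionally ECG) around QRS events.

    ``timecourses`` is one series or a list of per-subject series;
    ``qrs_times`` the matching event sample indices (per series).  Events
    whose +-window epoch exceeds the series bounds are skipped and counted.
    Epochs are first averaged within each series, then across series, so every
    subject contributes equally.
    """
    if isinstance(timecourses, np.ndarray) and timecourses.ndim == 1:
        timecourses = [timecourses]
        qrs_times = [qrs_times]
        if ecg_series is not None:
            ecg_series = [ecg_series]
    half = int(round(window_s * fs))
    lags = np.arange(-half, half + 1)
    rel_means, ecg_means = [], []
    n_events = 0
    n_skipped = 0
    for i, (series, events) in enumerate(zip(timecourses, qrs_times)):
        series = np.asarray(series, dtype=np.float64)
        epochs, ecg_epochs = [], []
        for e in np.asarray(events, dtype=np.int64):
            if e - half < 0 or e + half + 1 > len(series):
                n_skipped += 1
                continue
            epochs.append(series[e - half : e + half + 1])
            if ecg_series is not None:
                ecg_epochs.append(
                    np.asarray(ecg_series[i])[e - half : e + half + 1]
                )
        if epochs:
            n_events += len(epochs)
            rel_means.append(np.mean(epochs, axis=0))
            if ecg_epochs:
                ecg_means.append(np.mean(ecg_epochs, axis=0))
    if not rel_means:
        raise InvalidInputError("no usable events inside the series bounds")
    return EventLockedAverage(
        lags=lags,
        mean_abs_relevance=np.mean(rel_means, axis=0),
        mean_ecg=np.mean(ecg_means, axis=0) if ecg_means else None,
        n_events=n_events,
        n_skipped=n_skipped,
    )
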