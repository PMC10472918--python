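"""Signal path from raw recording to normalized analysis segments.

Order of operations for the standard pipeline:

1. zero-phase Butterworth bandpass (default broadband 1-40 Hz),
2. interpolation of bad channels (flat or extreme-amplitude),
3. ICA-based rejection of components correlated with the ECG reference
   (and optionally other artifact references such as a blink channel),
4. quality-ranked selection of 50 non-overlapping 4-s segments, skipping the
   first 120 s of the recording,
5. per-segment normalization: common average reference, per-channel
   de-meaning, division by the segment's global standard deviation.

The quality scorer is deliberately simple (peak-to-peak amplitude based); a
different scorer can be passed to :func:`select_segments` for real data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sp_signal
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .errors import (
    ConfigurationError,
    DegenerateInputError,
    InsufficientDataError,
    InvalidInputError,
)
from .synthetic_cohort import Recording, SubjectRecord

__all__ = [
    "BandDefinition",
    "Segment",
    "BAND_EDGES_HZ",
    "band_limits",
    "bandpass_filter",
    "select_segments",
    "detect_bad_channels",
    "interpolate_bad_channels",
    "remove_artifact_components",
    "normalize_segment",
]

#: Traditional EEG frequency bands (Hz); broadband is the 1-40 Hz analysis range.
BAND_EDGES_HZ = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 14.0),
    "beta": (14.0, 30.0),
    "gamma": (30.0, 40.0),
    "broadband": (1.0, 40.0),
}

#: Peak-to-peak amplitude (uV, pre-normalization) above which a channel counts
#: as bad within a candidate window.
DEFAULT_P2P_BAD_UV = 150.0


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ConfigurationError("band edges must satisfy 0 < low < high")


@dataclass
class Segment:
    """One analysis window (channels x samples) cut from a recording.

    ``data`` is in uV before :func:`normalize_segment` and unitless after.
    """

    data: np.ndarray
    start_sample: int
    subject: SubjectRecord
    band: str = "broadband"
    channels: tuple[str, ...] = ()
    normalized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise InvalidInputError("segment data must be 2D (channels x samples)")


def band_limits(name: str) -> BandDefinition:
    """Fixed band edges: delta 1-4, theta 4-8, alpha 8-14, beta 14-30,
    gamma 30-40, broadband 1-40 Hz."""
    try:
        low, high = BAND_EDGES_HZ[name]
    except KeyError:
        raise InvalidInputError(
            f"unknown band {name!r}; known: {sorted(BAND_EDGES_HZ)}"
        ) from None
    return BandDefinition(name=name, low=low, high=high)


def bandpass_filter(recording: Recording, band: BandDefinition | str) -> Recording:
    """Zero-phase order-4 Butterworth bandpass applied to all channels."""
    if isinstance(band, str):
        band = band_limits(band)
    if band.high >= recording.fs / 2:
        raise ConfigurationError(
            f"band high edge {band.high} Hz >= Nyquist ({recording.fs / 2} Hz)"
        )
    sos = sp_signal.butter(
        4, [band.low, band.high], btype="bandpass", fs=recording.fs, output="sos"
    )
    filtered = sp_signal.sosfiltfilt(sos, recording.signal, axis=1)
    return Recording(
        signal=filtered,
        layout=recording.layout,
        fs=recording.fs,
        qrs_times=recording.qrs_times,
        subject=recording.subject,
    )


def _window_quality(
    eeg: np.ndarray, p2p_bad_uv: float
) -> tuple[int, float]:
    """(number of bad channels, total peak-to-peak amplitude) for one window."""
    p2p = eeg.max(axis=1) - eeg.min(axis=1)
    return int(np.sum(p2p > p2p_bad_uv)), float(p2p.sum())


def select_segments(
    recording: Recording,
    n_segments: int = 50,
    seg_len_s: float = 4.0,
    skip_s: float = 120.0,
    band: str = "broadband",
    p2p_bad_uv: float = DEFAULT_P2P_BAD_UV,
    quality_fn=None,
) -> list[Segment]:
    """Select the best-quality non-overlapping EEG segments, best first.

    Candidate windows lie on a non-overlapping grid starting at
    ``fs * skip_s``.  Each window is scored (fewest bad channels, then lowest
    total peak-to-peak amplitude) and the ``n_segments`` best are returned in
    quality order.  ``quality_fn(window_eeg) -> sortable score`` may replace
    the default scorer (extension hook for Autoreject-style algorithms).
    """
    fs = recording.fs
    seg_len = int(round(seg_len_s * fs))
    skip = int(round(skip_s * fs))
    n_total = recording.n_samples
    if n_total <= skip:
        raise InsufficientDataError(
            f"recording ({n_total / fs:.0f} s) is not longer than the "
            f"{skip_s:.0f} s lead-in skip"
        )
    starts = np.arange(skip, n_total - seg_len + 1, seg_len)
    if len(starts) < n_segments:
        raise InsufficientDataError(
            f"only {len(starts)} candidate segments available, need {n_segments}"
        )
    eeg = recording.eeg
    if quality_fn is None:
        scores = [_window_quality(eeg[:, s : s + seg_len], p2p_bad_uv) for s in starts]
    else:
        scores = [quality_fn(eeg[:, s : s + seg_len]) for s in starts]
    order = sorted(range(len(starts)), key=lambda i: (scores[i], starts[i]))
    chosen = order[:n_segments]
    return [
        Segment(
            data=eeg[:, starts[i] : starts[i] + seg_len].copy(),
            start_sample=int(starts[i]),
            subject=recording.subject,
            band=band,
            channels=recording.layout.eeg_labels,
        )
        for i in chosen
    ]


def detect_bad_channels(
    recording: Recording,
    flat_p2p_uv: float = 0.1,
    extreme_p2p_uv: float = 500.0,
) -> set[str]:
    """Channels that are flat or extreme over the whole recording."""
    eeg = recording.eeg
    p2p = eeg.max(axis=1) - eeg.min(axis=1)
    labels = recording.layout.eeg_labels
    return {
        labels[c]
        for c in range(len(labels))
        if p2p[c] < flat_p2p_uv or p2p[c] > extreme_p2p_uv
    }


def interpolate_bad_channels(recording: Recording, bad: set[str]) -> Recording:
    """Replace each bad channel by the mean of its (good) spatial neighbors."""
    layout = recording.layout
    unknown = bad - set(layout.eeg_labels)
    if unknown:
        raise InvalidInputError(f"unknown channels: {sorted(unknown)}")
    if len(bad) >= layout.n_eeg:
        raise InvalidInputError("cannot interpolate: all channels are bad")
    if not bad:
        return recording
    signal = recording.signal.copy()
    for label in sorted(bad):
        neighbors = [l for l in layout.neighbors(label, k=4) if l not in bad]
        if not neighbors:  # widen until a good neighbor is found
            neighbors = [
                l for l in layout.neighbors(label, k=layout.n_eeg - 1) if l not in bad
            ][:4]
        rows = [layout.index(l) for l in neighbors]
        signal[layout.index(label)] = signal[rows].mean(axis=0)
    return Recording(
        signal=signal,
        layout=layout,
        fs=recording.fs,
        qrs_times=recording.qrs_times,
        subject=recording.subject,
    )


@dataclass(frozen=True)
class ComponentReport:
    """Which ICA components were rejected and why."""

    n_components: int
    rejected: tuple[int, ...]
    correlations: dict[int, float]  # component index -> max |r| over references


def remove_artifact_components(
    recording: Recording,
    max_components: int = 20,
    corr_threshold: float = 0.3,
    extra_references: dict[str, np.ndarray] | None = None,
    seed: int = 0,
    fit_samples: int = 30_000,
) -> tuple[Recording, ComponentReport]:
    """ICA-based artifact rejection against the ECG reference channel.

    An ICA unmixing with at most ``max_components`` components is estimated on
    the EEG channels.  Components whose time course correlates with the ECG
    reference (or any extra reference series, e.g. a blink template) with
    ``|r| > corr_threshold`` are zeroed before remixing.  The unmixing is fit
    on an evenly strided subsample of at most ``fit_samples`` time points and
    then applied to the full recording.
    """
    eeg = recording.eeg
    n_comp = min(max_components, eeg.shape[0])
    references = {"ecg": recording.ecg}
    if extra_references:
        references.update(extra_references)

    ica = FastICA(
        n_components=n_comp,
        whiten="unit-variance",
        max_iter=500,
        tol=1e-4,
        random_state=seed,
    )
    stride = max(eeg.shape[1] // fit_samples, 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        ica.fit(eeg[:, ::stride].T)
    sources = ica.transform(eeg.T)  # (samples, components)

    correlations: dict[int, float] = {}
    rejected: list[int] = []
    for k in range(n_comp):
        s = sources[:, k]
        r = max(
            abs(float(np.corrcoef(s, ref)[0, 1])) for ref in references.values()
        )
        correlations[k] = r
        if r > corr_threshold:
            rejected.append(k)

    # subtract only the rejected component subspace; untouched directions
    # (including variance outside the n_comp PCA subspace) pass through exactly
    if rejected:
        artifact = sources[:, rejected] @ ica.mixing_[:, rejected].T
        cleaned = eeg - artifact.T
    else:
        cleaned = eeg.copy()

    out = Recording(
        signal=np.vstack([cleaned, recording.ecg[None, :]]),
        layout=recording.layout,
        fs=recording.fs,
        qrs_times=recording.qrs_times,
        subject=recording.subject,
    )
    report = ComponentReport(
        n_components=n_comp, rejected=tuple(rejected), correlations=correlations
    )
    return out, report


def normalize_segment(segment: Segment) -> Segment:
    """Common average reference, per-channel de-mean, global unit SD.

    After this the channel sum is ~0 at every sample and the global standard
    deviation of the whole segment is 1.  The single global SD (rather than
    per-channel) preserves relative channel amplitudes, which carry the
    topographic signal.
    """
    x = segment.data.astype(np.float64)
    if x.shape[0] > 1:  # CAR is a no-op trap for single-channel (ECG-only) data
        x = x - x.mean(axis=0, keepdims=True)  # common average reference
    x = x - x.mean(axis=1, keepdims=True)  # de-mean each channel
    sd = x.std()
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateInputError("segment has zero variance after referencing")
    return Segment(
        data=x / sd,
        start_sample=segment.start_sample,
        subject=segment.subject,
        band=segment.band,
        channels=segment.channels,
        normalized=True,
    )
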