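"""Synthetic multichannel EEG cohorts with controllable sex-dependent structure.

The generator produces 21-channel 10-20 EEG at 250 Hz plus one ECG reference
channel.  A recording is a linear mixture of band-limited Gaussian neural
sources, per-channel 1/f background noise, and (optionally) a scalp-projected
cardiac QRS artifact train whose R-peak times are annotated.  The sex label
can be wired into one of three loci:

``topographic``
    Males and females mix the sources through different scalp patterns.  The
    pattern matrices are column-normalized so the marginal variance of every
    channel is the same for both sexes -- only the instantaneous cross-channel
    covariance (the topography) differs.
``spectral``
    Same patterns for both sexes, but one sex receives a gain of
    ``1 + effect_size`` in the alpha band (8-14 Hz) of the mixed signal, so the
    per-channel spectral shape differs while spatial correlation is preserved.
``cardiac``
    The QRS artifact leaks onto the scalp with amplitude
    ``artifact_gain * (1 + effect_size * sex)``.

With ``effect_mode='none'`` the label is independent of the signal and any
classifier should perform at chance.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .errors import ConfigurationError
from .layout import ChannelLayout, standard_1020

__all__ = [
    "SimConfig",
    "SubjectRecord",
    "Recording",
    "make_sex_topography",
    "qrs_template",
    "simulate_recording",
    "simulate_cohort",
    "iter_cohort",
    "make_subjects",
    "cohort_manifest",
]

EFFECT_MODES = ("topographic", "spectral", "cardiac", "none")

# Background amplitudes (uV).  The mixed neural signal has unit per-channel
# variance by construction and is scaled to SIGNAL_RMS_UV.
SIGNAL_RMS_UV = 20.0
PINK_NOISE_RMS_UV = 10.0
WHITE_NOISE_RMS_UV = 2.0
ECG_PEAK_UV = 300.0
ECG_NOISE_RMS_UV = 5.0

_SOURCE_BAND_HZ = (2.0, 30.0)
_ALPHA_BAND_HZ = (8.0, 14.0)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a synthetic cohort.

    duration must be at least 320 s so that, after the 120 s lead-in skip used
    by segment selection, 50 non-overlapping 4-s analysis windows fit.
    """

    fs: float = 250.0
    duration: float = 330.0  # headroom above the 320 s minimum (edge trimming)
    n_sources: int = 8
    effect_mode: str = "none"
    effect_size: float = 1.0
    heart_rate: float = 70.0        # mean beats per minute
    rr_jitter: float = 0.05         # fractional SD of the RR interval
    artifact_gain: float = 0.0      # scalp QRS leak amplitude (uV); cardiac mode
                                    # falls back to 15 uV when left at 0
    blink_rate_per_min: float = 0.0
    noise_exponent: float = 1.0     # spectral slope of the 1/f background
    subject_variability: float = 0.3  # per-subject scalp-pattern jitter
    seed: int = 0
    layout: ChannelLayout = field(default_factory=standard_1020)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        if self.duration < 320.0:
            raise ConfigurationError(
                "duration must be >= 320 s (120 s skip + 50 x 4 s segments)"
            )
        if self.effect_mode not in EFFECT_MODES:
            raise ConfigurationError(
                f"effect_mode must be one of {EFFECT_MODES}, got {self.effect_mode!r}"
            )
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be >= 0")
        if self.n_sources < 1:
            raise ConfigurationError("n_sources must be >= 1")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    sex: int  # 0 = female, 1 = male
    age: float

    def __post_init__(self) -> None:
        if self.sex not in (0, 1):
            raise ConfigurationError("sex must be 0 (female) or 1 (male)")


@dataclass
class Recording:
    """(21 EEG + 1 ECG) x samples signal matrix in microvolts."""

    signal: np.ndarray
    layout: ChannelLayout
    fs: float
    qrs_times: np.ndarray  # ascending R-peak sample indices
    subject: SubjectRecord

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.qrs_times = np.asarray(self.qrs_times, dtype=np.int64)
        if self.signal.shape[0] != self.layout.n_eeg + 1:
            raise ConfigurationError(
                f"signal must have {self.layout.n_eeg + 1} rows, "
                f"got {self.signal.shape[0]}"
            )
        if self.qrs_times.size and (
            np.any(np.diff(self.qrs_times) <= 0)
            or self.qrs_times[0] < 0
            or self.qrs_times[-1] >= self.n_samples
        ):
            raise ConfigurationError("qrs_times must be strictly increasing and in range")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def eeg(self) -> np.ndarray:
        """View of the 21 EEG rows."""
        return self.signal[: self.layout.n_eeg]

    @property
    def ecg(self) -> np.ndarray:
        """View of the ECG reference row."""
        return self.signal[self.layout.n_eeg]


# ---------------------------------------------------------------------------
# seeding

def _cohort_rng(config: SimConfig, stream: int) -> np.random.Generator:
    """RNG for cohort-level structure shared by all subjects (patterns etc.)."""
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, 0xC0, stream])


def subject_seed_key(subject_id: str, seed: int) -> list[int]:
    """Counter-based per-subject seed key: master seed + CRC32 of the id.

    Any subject is reproducible in isolation from (subject_id, master seed).
    """
    return [int(seed) & 0x7FFFFFFF, 0x5B, zlib.crc32(subject_id.encode("utf-8"))]


# ---------------------------------------------------------------------------
# building blocks

def make_sex_topography(
    sex: int,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    subject_rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Scalp mixing patterns for one sex: ``n_sources x 21`` with unit-norm columns.

    Both sexes share the same base patterns; in ``topographic`` mode a fixed
    differential pattern scaled by ``effect_size`` is added for males before
    column normalization.  Unit-norm columns make the per-channel marginal
    variance of the mixed signal identical for both sexes (for unit-variance
    sources), so only the cross-channel covariance carries the label.

    When ``subject_rng`` is given, an idiosyncratic pattern perturbation of
    scale ``config.subject_variability`` is added before normalization, so
    subjects are heterogeneous within each sex (as real cohorts are).
    """
    if config.effect_size < 0:  # defensive; SimConfig already validates
        raise ConfigurationError("effect_size must be >= 0")
    if sex not in (0, 1):
        raise ConfigurationError("sex must be 0 or 1")
    if rng is None:
        rng = _cohort_rng(config, stream=1)
    n_ch = config.layout.n_eeg
    base = rng.standard_normal((config.n_sources, n_ch))
    diff = rng.standard_normal((config.n_sources, n_ch))
    patterns = base.copy()
    if config.effect_mode == "topographic" and sex == 1:
        patterns = base + config.effect_size * diff
    if subject_rng is not None and config.subject_variability > 0:
        patterns = patterns + config.subject_variability * subject_rng.standard_normal(
            (config.n_sources, n_ch)
        )
    norms = np.linalg.norm(patterns, axis=0, keepdims=True)
    return patterns / norms


def qrs_template(fs: float, include_t_wave: bool = True) -> tuple[np.ndarray, int]:
    """Biphasic ~100 ms Q-R-S triangle (R peak normalized to 1), optional T bump.

    Returns (waveform, r_peak_index within the waveform).
    """
    def tri(dur_s: float, amp: float) -> np.ndarray:
        n = max(int(round(dur_s * fs)), 2)
        return amp * sp_signal.windows.triang(n)

    q = tri(0.025, -0.15)
    r = tri(0.045, 1.0)
    s = tri(0.030, -0.25)
    wave = np.concatenate([q, r, s])
    r_peak = len(q) + int(np.argmax(r))
    if include_t_wave:
        gap = np.zeros(int(round(0.18 * fs)))
        t_n = int(round(0.16 * fs))
        t = 0.18 * np.hanning(t_n)
        wave = np.concatenate([wave, gap, t])
    return wave, r_peak


def _qrs_train(
    config: SimConfig, n_samples: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Template train (unit R amplitude) and its R-peak sample indices."""
    wave, r_peak = qrs_template(config.fs)
    rr_mean = 60.0 / config.heart_rate * config.fs
    train = np.zeros(n_samples)
    peaks = []
    t = 0.5 * config.fs  # first beat at ~0.5 s
    while True:
        peak = int(round(t))
        start = peak - r_peak
        if start + len(wave) >= n_samples:
            break
        if start >= 0:
            train[start : start + len(wave)] += wave
            peaks.append(peak)
        jitter = rng.normal(0.0, config.rr_jitter) if config.rr_jitter > 0 else 0.0
        t += rr_mean * max(1.0 + jitter, 0.3)
    return train, np.asarray(peaks, dtype=np.int64)


def _pink_noise(
    shape: tuple[int, int], exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """1/f^exponent amplitude-shaped Gaussian noise, unit RMS per row."""
    n_ch, n = shape
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    out = np.fft.irfft(spec * scale, n=n, axis=1)
    rms = out.std(axis=1, keepdims=True)
    return out / rms


def _bandpass_sos(low: float, high: float, fs: float, order: int = 4):
    return sp_signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def _blink_train(
    config: SimConfig, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """Sparse train of ~300 ms smooth blink bumps (unit peak amplitude)."""
    out = np.zeros(n_samples)
    n_blinks = rng.poisson(config.blink_rate_per_min * config.duration / 60.0)
    width = int(round(0.3 * config.fs))
    bump = np.hanning(width)
    starts = rng.integers(0, max(n_samples - width, 1), size=n_blinks)
    for s in starts:
        out[s : s + width] += bump
    return out


# ---------------------------------------------------------------------------
# recordings and cohorts

def simulate_recording(subject: SubjectRecord, config: SimConfig) -> Recording:
    """Simulate one recording; deterministic given (subject_id, config.seed)."""
    layout = config.layout
    n = config.n_samples
    rng = np.random.default_rng(subject_seed_key(subject.subject_id, config.seed))

    # band-limited unit-variance neural sources mixed through sex patterns
    patterns = make_sex_topography(subject.sex, config, subject_rng=rng)
    sources = rng.standard_normal((config.n_sources, n))
    sos = _bandpass_sos(*_SOURCE_BAND_HZ, config.fs)
    sources = sp_signal.sosfiltfilt(sos, sources, axis=1)
    sources /= sources.std(axis=1, keepdims=True)
    eeg = SIGNAL_RMS_UV * (patterns.T @ sources)  # (21, n)

    if config.effect_mode == "spectral" and subject.sex == 1:
        sos_a = _bandpass_sos(*_ALPHA_BAND_HZ, config.fs)
        eeg = eeg + config.effect_size * sp_signal.sosfiltfilt(sos_a, eeg, axis=1)

    eeg += PINK_NOISE_RMS_UV * _pink_noise(
        (layout.n_eeg, n), config.noise_exponent, rng
    )
    eeg += WHITE_NOISE_RMS_UV * rng.standard_normal((layout.n_eeg, n))

    # cardiac artifact train; the ECG reference always carries the heartbeat
    train, peaks = _qrs_train(config, n, rng)
    inject = config.effect_mode == "cardiac" or config.artifact_gain > 0
    if inject:
        gain = config.artifact_gain if config.artifact_gain > 0 else 15.0
        if config.effect_mode == "cardiac":
            gain = gain * (1.0 + config.effect_size * subject.sex)
        leak_pattern = _cohort_rng(config, stream=2).standard_normal(layout.n_eeg)
        leak_pattern /= np.linalg.norm(leak_pattern)
        eeg += gain * np.sqrt(layout.n_eeg) * np.outer(leak_pattern, train)

    if config.blink_rate_per_min > 0:
        blink = _blink_train(config, n, rng)
        frontal = np.zeros(layout.n_eeg)
        for lbl, w in (("Fp1", 1.0), ("Fp2", 1.0), ("F7", 0.4), ("F8", 0.4),
                       ("F3", 0.3), ("F4", 0.3), ("Fz", 0.2)):
            frontal[layout.index(lbl)] = w
        eeg += 80.0 * np.outer(frontal, blink)

    ecg = ECG_PEAK_UV * train + ECG_NOISE_RMS_UV * rng.standard_normal(n)

    return Recording(
        signal=np.vstack([eeg, ecg[None, :]]),
        layout=layout,
        fs=config.fs,
        qrs_times=peaks,
        subject=subject,
    )


def make_subjects(
    n_subjects: int, female_fraction: float, config: SimConfig, id_prefix: str = ""
) -> list[SubjectRecord]:
    """Subject roster with exactly round(n * female_fraction) females.

    ``id_prefix`` distinguishes cohorts (e.g. train vs eval) drawn from the
    same study conditions: per-subject seeds derive from the subject id, so a
    different prefix yields statistically independent recordings.
    """
    if n_subjects <= 0:
        raise ConfigurationError("n_subjects must be positive")
    if not 0.0 <= female_fraction <= 1.0:
        raise ConfigurationError("female_fraction must be in [0, 1]")
    n_female = int(round(n_subjects * female_fraction))
    rng = _cohort_rng(config, stream=3)
    ages = rng.uniform(18.0, 88.0, size=n_subjects)
    subjects = []
    for i in range(n_subjects):
        sex = 0 if i < n_female else 1
        subjects.append(
            SubjectRecord(
                subject_id=f"{id_prefix}s{i:04d}", sex=sex, age=float(round(ages[i], 1))
            )
        )
    return subjects


def cohort_manifest(subjects: list[SubjectRecord], paths: list[str] | None = None) -> pd.DataFrame:
    """Manifest table (subject_id, sex, age, path), one row per subject."""
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "sex": [s.sex for s in subjects],
            "age": [s.age for s in subjects],
            "path": paths if paths is not None else [""] * len(subjects),
        }
    )


def iter_cohort(
    n_subjects: int, female_fraction: float, config: SimConfig, id_prefix: str = ""
):
    """Yield (SubjectRecord, Recording) lazily; memory-friendly for large cohorts."""
    for subject in make_subjects(n_subjects, female_fraction, config, id_prefix):
        yield subject, simulate_recording(subject, config)


def simulate_cohort(
    n_subjects: int, female_fraction: float, config: SimConfig
) -> tuple[list[Recording], pd.DataFrame]:
    """Simulate a labeled cohort.

    Exactly ``round(n_subjects * female_fraction)`` subjects get sex = 0.
    Per-subject seeds derive from the master seed so any subject can be
    regenerated in isolation.  Returns (recordings, manifest).
    """
    subjects = make_subjects(n_subjects, female_fraction, config)
    recordings = [simulate_recording(s, config) for s in subjects]
    return recordings, cohort_manifest(subjects)
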