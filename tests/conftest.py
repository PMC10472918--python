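"""Shared fixtures and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from spaten.layout import standard_1020
from spaten.minispaten import ModelSpec, TrainedModel
from spaten.synthetic_cohort import Recording, SubjectRecord


@pytest.fixture(scope="session")
def layout():
    return standard_1020()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_recording(signal_uv: np.ndarray, fs: float = 250.0, qrs=None,
                   sex: int = 0, subject_id: str = "t000") -> Recording:
    """Wrap a plain (22, n) array into a Recording for unit tests."""
    return Recording(
        signal=signal_uv,
        layout=standard_1020(),
        fs=fs,
        qrs_times=np.asarray(qrs if qrs is not None else [], dtype=np.int64),
        subject=SubjectRecord(subject_id=subject_id, sex=sex, age=40.0),
    )


def random_model(spec: ModelSpec, seed: int = 0) -> TrainedModel:
    """Model with standard-normal weights, for oracle comparisons."""
    r = np.random.default_rng(seed)
    return TrainedModel(
        kernels=r.standard_normal((spec.n_kernels, spec.n_channels, spec.kernel_len)),
        dense_weights=r.standard_normal(spec.n_kernels),
        dense_bias=float(r.standard_normal()),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# brute-force oracles (independent of the package's vectorized paths)

def brute_curve(X: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Lag-by-lag cross-correlation of one kernel with one segment."""
    C, T = X.shape
    L = K.shape[1]
    return np.array([float(np.sum(X[:, t:t + L] * K)) for t in range(T - L + 1)])


def brute_forward(model: TrainedModel, X: np.ndarray) -> float:
    """All-loops forward pass: curves -> ReLU -> window maxima -> mean -> sigmoid."""
    spec = model.spec
    pooled = []
    for k in range(spec.n_kernels):
        rect = np.maximum(brute_curve(X, model.kernels[k]), 0.0)
        maxima = [rect[a:b].max() for a, b in spec.window_bounds()]
        pooled.append(np.mean(maxima))
    z = float(np.dot(pooled, model.dense_weights)) + model.dense_bias
    return 1.0 / (1.0 + np.exp(-z))


def brute_total_relevance(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """All-loops relevance: per kernel, per window, earliest-lag argmax."""
    spec = model.spec
    R = np.zeros_like(X)
    L = spec.kernel_len
    for k in range(spec.n_kernels):
        rect = np.maximum(brute_curve(X, model.kernels[k]), 0.0)
        for a, b in spec.window_bounds():
            lag = a + int(np.argmax(rect[a:b]))
            cmax = rect[lag]
            if cmax <= 0.0:
                continue
            R[:, lag:lag + L] += (
                X[:, lag:lag + L] * model.kernels[k] * cmax
                * model.dense_weights[k]
            )
    return R
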