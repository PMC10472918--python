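"""Minimalistic spatio-temporal CNN (Mini-SpaTeN) for sex detection from EEG.

Architecture (two trainable layers):

1. cross-correlation of the input segment (channels x samples) with
   ``n_kernels`` spatio-temporal kernels spanning all channels and sliding
   only along time, followed by an unbiased ReLU;
2. temporal max pooling (window 75 samples, stride 25, end-padded so a
   982-sample correlation curve yields 40 windows);
3. global average over the pooled window maxima;
4. single sigmoid unit (logistic regression over the per-kernel averages).

For the default spec (21 channels, 1000 samples, 16 kernels of length 19) the
correlation curves have 982 samples, pooling gives 40 windows, and the model
carries 16*21*19 + 16 = 6400 weights (the convolution is bias-free; only the
sigmoid unit has a bias, reported separately).

The network is small enough that the forward and backward passes are
implemented directly in NumPy; training uses Adam on the class-weighted
binary cross-entropy with the label encoding 0 = female, 1 = male.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ConfigurationError, InvalidInputError
from .preprocess import Segment

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "TrainedModel",
    "SegmentDataset",
    "SexPrediction",
    "build_model",
    "count_parameters",
    "forward",
    "forward_batch",
    "train",
    "predict_subject",
    "ensemble_predict",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture constants.  Defaults give the 6400-weight configuration."""

    n_channels: int = 21
    input_len: int = 1000
    n_kernels: int = 16
    kernel_len: int = 19
    pool_window: int = 75
    pool_stride: int = 25
    conv_bias: bool = False
    dense_bias: bool = True

    def __post_init__(self) -> None:
        if self.kernel_len > self.input_len:
            raise ConfigurationError("kernel_len must not exceed input_len")
        if min(self.n_channels, self.n_kernels, self.kernel_len,
               self.pool_window, self.pool_stride) < 1:
            raise ConfigurationError("all spec counts must be >= 1")

    @property
    def curve_len(self) -> int:
        """Length of each cross-correlation curve (valid lags)."""
        return self.input_len - self.kernel_len + 1

    @property
    def n_windows(self) -> int:
        """Pooled window count; end-padding lets tail windows truncate."""
        return -(-self.curve_len // self.pool_stride)  # ceil division

    def window_bounds(self) -> list[tuple[int, int]]:
        """[start, stop) lag ranges of the pooling windows."""
        return [
            (j * self.pool_stride,
             min(j * self.pool_stride + self.pool_window, self.curve_len))
            for j in range(self.n_windows)
        ]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 20
    holdout_fraction: float = 0.2
    class_weighting: bool = True
    learning_rate: float = 1e-3
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ConfigurationError("holdout_fraction must be in (0, 1)")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")


@dataclass
class TrainedModel:
    """Learned kernels K (n_kernels x n_channels x kernel_len), dense weights w
    (sign encodes the kernel's sex: negative pulls female, positive male) and
    the dense bias."""

    kernels: np.ndarray
    dense_weights: np.ndarray
    dense_bias: float
    spec: ModelSpec
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.kernels = np.asarray(self.kernels, dtype=np.float64)
        self.dense_weights = np.asarray(self.dense_weights, dtype=np.float64)
        s = self.spec
        if self.kernels.shape != (s.n_kernels, s.n_channels, s.kernel_len):
            raise ConfigurationError(
                f"kernel tensor shape {self.kernels.shape} does not match spec"
            )
        if self.dense_weights.shape != (s.n_kernels,):
            raise ConfigurationError("dense_weights length must equal n_kernels")
        if not (np.all(np.isfinite(self.kernels))
                and np.all(np.isfinite(self.dense_weights))
                and np.isfinite(self.dense_bias)):
            raise ConfigurationError("model weights must be finite")


@dataclass(frozen=True)
class SexPrediction:
    label: int
    vote_fraction: float   # fraction of votes for male (label 1)
    mean_probability: float


@dataclass
class SegmentDataset:
    """Stacked normalized segments with labels and subject provenance.

    ``X`` has shape (n_segments, n_channels, n_samples); float32 is used for
    training throughput.
    """

    X: np.ndarray
    y: np.ndarray
    subject_ids: np.ndarray
    channels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.X = np.ascontiguousarray(self.X, dtype=np.float32)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.subject_ids = np.asarray(self.subject_ids)
        if not (len(self.X) == len(self.y) == len(self.subject_ids)):
            raise InvalidInputError("X, y and subject_ids must have equal length")

    @classmethod
    def from_segments(cls, segments: list[Segment]) -> "SegmentDataset":
        if not segments:
            raise InvalidInputError("no segments given")
        X = np.stack([s.data for s in segments])
        y = np.array([s.subject.sex for s in segments])
        ids = np.array([s.subject.subject_id for s in segments])
        return cls(X=X, y=y, subject_ids=ids, channels=segments[0].channels)

    def __len__(self) -> int:
        return len(self.X)

    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.subject_ids:
            seen.setdefault(str(s), None)
        return list(seen)

    def subject_label(self, subject_id: str) -> int:
        mask = self.subject_ids == subject_id
        return int(self.y[mask][0])

    def select(self, mask: np.ndarray) -> "SegmentDataset":
        return SegmentDataset(
            X=self.X[mask], y=self.y[mask], subject_ids=self.subject_ids[mask],
            channels=self.channels,
        )


# ---------------------------------------------------------------------------
# construction / bookkeeping

def build_model(spec: ModelSpec, seed: int = 0) -> TrainedModel:
    """Randomly initialized model (Glorot-scaled kernels, zero dense layer)."""
    rng = np.random.default_rng(seed)
    fan_in = spec.n_channels * spec.kernel_len
    kernels = rng.normal(
        0.0, np.sqrt(2.0 / fan_in), size=(spec.n_kernels, spec.n_channels, spec.kernel_len)
    )
    dense = rng.normal(0.0, np.sqrt(1.0 / spec.n_kernels), size=spec.n_kernels)
    return TrainedModel(
        kernels=kernels, dense_weights=dense, dense_bias=0.0, spec=spec,
        training_meta={"seed": int(seed), "epochs_run": 0},
    )


def count_parameters(spec: ModelSpec) -> tuple[int, int]:
    """(weight count excluding biases, total including enabled biases)."""
    weights = spec.n_kernels * spec.n_channels * spec.kernel_len + spec.n_kernels
    total = weights
    if spec.conv_bias:
        total += spec.n_kernels
    if spec.dense_bias:
        total += 1
    return weights, total


# ---------------------------------------------------------------------------
# forward pass

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _conv_curves(X: np.ndarray, kernels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cross-correlation curves for a batch.

    X: (B, C, T); kernels: (K, C, L).  Returns (curves (B, curve_len, K),
    im2col matrix (B, curve_len, C*L)) -- the latter is reused by backprop.
    """
    B, C, T = X.shape
    K, _, L = kernels.shape
    curve = T - L + 1
    win = np.lib.stride_tricks.sliding_window_view(X, L, axis=2)  # (B,C,curve,L)
    Xc = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(B, curve, C * L)
    Kf = kernels.reshape(K, C * L)
    return Xc @ Kf.T.astype(Xc.dtype), Xc


def forward_batch(
    model: TrainedModel, X: np.ndarray
) -> tuple[np.ndarray, dict]:
    """Probabilities and intermediates for a batch of segments.

    Intermediates: ``curves`` (pre-ReLU correlation curves, (B, curve, K)),
    ``relu`` (rectified curves), ``window_max`` (B, n_windows, K),
    ``window_argmax`` (lag of each window maximum), ``pooled_mean`` (B, K).
    """
    spec = model.spec
    X = np.asarray(X)
    if X.ndim == 2:
        X = X[None]
    if X.shape[1:] != (spec.n_channels, spec.input_len):
        raise InvalidInputError(
            f"input shape {X.shape[1:]} does not match spec "
            f"({spec.n_channels}, {spec.input_len})"
        )
    curves, _ = _conv_curves(X, model.kernels.astype(X.dtype))
    relu = np.maximum(curves, 0.0)
    bounds = spec.window_bounds()
    B = X.shape[0]
    W = spec.n_windows
    wmax = np.empty((B, W, spec.n_kernels), dtype=relu.dtype)
    wargmax = np.empty((B, W, spec.n_kernels), dtype=np.int64)
    for j, (a, b) in enumerate(bounds):
        seg = relu[:, a:b, :]
        wmax[:, j] = seg.max(axis=1)
        wargmax[:, j] = seg.argmax(axis=1) + a
    pooled = wmax.mean(axis=1)  # (B, K)
    z = pooled @ model.dense_weights + model.dense_bias
    p = _sigmoid(z)
    return p, {
        "curves": curves,
        "relu": relu,
        "window_max": wmax,
        "window_argmax": wargmax,
        "pooled_mean": pooled,
    }


def forward(model: TrainedModel, segment: Segment | np.ndarray) -> tuple[float, dict]:
    """Probability of male for one segment, with exposed intermediates."""
    data = segment.data if isinstance(segment, Segment) else np.asarray(segment)
    p, inter = forward_batch(model, data.astype(np.float64))
    return float(p[0]), {k: v[0] for k, v in inter.items()}


# ---------------------------------------------------------------------------
# training

def _subject_stratified_split(
    dataset: SegmentDataset, holdout_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks (train, holdout); no subject appears in both folds."""
    holdout_subjects: list[str] = []
    subjects = np.array(dataset.subjects())
    labels = np.array([dataset.subject_label(s) for s in subjects])
    for cls in (0, 1):
        cls_subjects = subjects[labels == cls]
        perm = rng.permutation(len(cls_subjects))
        n_hold = max(1, int(round(holdout_fraction * len(cls_subjects))))
        if n_hold >= len(cls_subjects):
            n_hold = max(len(cls_subjects) - 1, 1)
        holdout_subjects.extend(cls_subjects[perm[:n_hold]])
    hold_mask = np.isin(dataset.subject_ids, np.array(holdout_subjects))
    return ~hold_mask, hold_mask


def _segment_balanced_accuracy(y_true: np.ndarray, p: np.ndarray) -> float:
    pred = (p > 0.5).astype(int)
    accs = []
    for cls in (0, 1):
        mask = y_true == cls
        if mask.any():
            accs.append(float(np.mean(pred[mask] == cls)))
    return float(np.mean(accs)) if accs else 0.5


class _Adam:
    def __init__(self, shapes, lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [np.zeros(s, dtype=np.float64) for s in shapes]
        self.v = [np.zeros(s, dtype=np.float64) for s in shapes]

    def step(self, params, grads):
        self.t += 1
        out = []
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            out.append(p - self.lr * mh / (np.sqrt(vh) + self.eps))
        return out


def train(
    dataset: SegmentDataset,
    spec: ModelSpec | None = None,
    config: TrainConfig | None = None,
) -> TrainedModel:
    """Train on class-weighted binary cross-entropy with Adam.

    A subject-stratified 20% holdout is split off; after every epoch the
    segment-level balanced accuracy on the holdout is evaluated and the best
    epoch's weights are returned.  Deterministic given ``config.seed``.
    """
    config = config or TrainConfig()
    if spec is None:
        spec = ModelSpec(
            n_channels=dataset.X.shape[1], input_len=dataset.X.shape[2]
        )
    classes = np.unique(dataset.y)
    if len(classes) < 2:
        raise InvalidInputError("training requires both classes present")
    if dataset.X.shape[1:] != (spec.n_channels, spec.input_len):
        raise InvalidInputError("dataset shape does not match model spec")

    rng = np.random.default_rng(config.seed)
    train_mask, hold_mask = _subject_stratified_split(
        dataset, config.holdout_fraction, rng
    )
    Xtr, ytr = dataset.X[train_mask], dataset.y[train_mask]
    Xho, yho = dataset.X[hold_mask], dataset.y[hold_mask]
    n = len(ytr)

    if config.class_weighting:
        # inversely proportional to class frequency, mean weight 1
        n0, n1 = int(np.sum(ytr == 0)), int(np.sum(ytr == 1))
        cw = {0: n / (2.0 * n0), 1: n / (2.0 * n1)}
    else:
        cw = {0: 1.0, 1: 1.0}
    sample_w = np.where(ytr == 1, cw[1], cw[0]).astype(np.float64)

    model = build_model(spec, seed=int(rng.integers(2**31 - 1)))
    K = model.kernels.copy()
    w = model.dense_weights.copy()
    b = float(model.dense_bias)
    adam = _Adam([K.shape, w.shape, ()], lr=config.learning_rate)
    bounds = spec.window_bounds()
    W = spec.n_windows
    bidx = None

    best = (-np.inf, K.copy(), w.copy(), b, 0)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            Xb = Xtr[idx]
            yb = ytr[idx].astype(np.float64)
            wb = sample_w[idx]
            B = len(idx)

            curves, Xc = _conv_curves(Xb, K.astype(np.float32))
            relu = np.maximum(curves, 0.0)
            wmax = np.empty((B, W, spec.n_kernels), dtype=relu.dtype)
            wamax = np.empty((B, W, spec.n_kernels), dtype=np.int64)
            for j, (a0, b0) in enumerate(bounds):
                seg = relu[:, a0:b0, :]
                wmax[:, j] = seg.max(axis=1)
                wamax[:, j] = seg.argmax(axis=1) + a0
            pooled = wmax.mean(axis=1).astype(np.float64)
            z = pooled @ w + b
            p = _sigmoid(z)

            dz = wb * (p - yb) / B                         # dL/dz
            gw = pooled.T @ dz
            gb = float(dz.sum())
            dpool = np.outer(dz, w) / W                    # (B, K) per-window share
            dA = np.zeros_like(relu)
            if bidx is None or bidx.shape[0] != B:
                bidx = np.arange(B)[:, None]
            kidx = np.arange(spec.n_kernels)[None, :]
            for j in range(W):
                np.add.at(dA, (bidx, wamax[:, j], kidx), dpool.astype(relu.dtype))
            dC = dA * (curves > 0)
            gK = (
                dC.reshape(B * curves.shape[1], spec.n_kernels).T.astype(np.float64)
                @ Xc.reshape(B * curves.shape[1], -1).astype(np.float64)
            ).reshape(K.shape)

            K, w, b_arr = adam.step([K, w, np.float64(b)], [gK, gw, np.float64(gb)])
            b = float(b_arr)

        snapshot = TrainedModel(
            kernels=K, dense_weights=w, dense_bias=b, spec=spec
        )
        p_ho, _ = forward_batch(snapshot, Xho)
        score = _segment_balanced_accuracy(yho, p_ho)
        if score > best[0]:
            best = (score, K.copy(), w.copy(), b, epoch + 1)

    score, Kb, wb_, bb, ep = best
    return TrainedModel(
        kernels=Kb, dense_weights=wb_, dense_bias=bb, spec=spec,
        training_meta={
            "seed": int(config.seed),
            "epochs_run": int(config.epochs),
            "best_epoch": int(ep),
            "holdout_balanced_accuracy": float(score),
            "n_train_segments": int(n),
            "n_holdout_segments": int(len(yho)),
        },
    )


# ---------------------------------------------------------------------------
# prediction

def _segment_probs(model: TrainedModel, segments) -> np.ndarray:
    if isinstance(segments, SegmentDataset):
        X = segments.X
    elif isinstance(segments, np.ndarray):
        X = segments
    else:
        X = np.stack([s.data for s in segments]).astype(np.float32)
    p, _ = forward_batch(model, X)
    return p


def predict_subject(model: TrainedModel, segments) -> SexPrediction:
    """Majority vote over per-segment thresholded predictions.

    Ties are broken by the mean predicted probability (>= 0.5 -> male).
    """
    p = _segment_probs(model, segments)
    if len(p) == 0:
        raise InvalidInputError("need at least one segment")
    votes_male = int(np.sum(p > 0.5))
    n = len(p)
    mean_p = float(p.mean())
    if votes_male * 2 > n:
        label = 1
    elif votes_male * 2 < n:
        label = 0
    else:
        label = 1 if mean_p >= 0.5 else 0
    return SexPrediction(label=label, vote_fraction=votes_male / n, mean_probability=mean_p)


def ensemble_predict(models: list[TrainedModel], segments) -> SexPrediction:
    """Majority vote over the per-subject predictions of several networks."""
    if not models:
        raise InvalidInputError("need at least one model")
    preds = [predict_subject(m, segments) for m in models]
    votes_male = sum(pr.label for pr in preds)
    n = len(preds)
    grand_mean = float(np.mean([pr.mean_probability for pr in preds]))
    if votes_male * 2 > n:
        label = 1
    elif votes_male * 2 < n:
        label = 0
    else:
        label = 1 if grand_mean >= 0.5 else 0
    return SexPrediction(
        label=label, vote_fraction=votes_male / n, mean_probability=grand_mean
    )


# ---------------------------------------------------------------------------
# serialization

_FORMAT_VERSION = 1


def save_model(model: TrainedModel, path) -> None:
    """Single-file container: NPZ with spec/meta as JSON plus weight arrays."""
    header = json.dumps(
        {
            "format_version": _FORMAT_VERSION,
            "spec": asdict(model.spec),
            "training_meta": model.training_meta,
        }
    )
    np.savez(
        path,
        header=np.frombuffer(header.encode("utf-8"), dtype=np.uint8),
        kernels=model.kernels,
        dense_weights=model.dense_weights,
        dense_bias=np.float64(model.dense_bias),
    )


def load_model(path) -> TrainedModel:
    with np.load(path) as data:
        header = json.loads(bytes(data["header"]).decode("utf-8"))
        if header.get("format_version") != _FORMAT_VERSION:
            raise InvalidInputError("unsupported model file version")
        spec = ModelSpec(**header["spec"])
        return TrainedModel(
            kernels=data["kernels"],
            dense_weights=data["dense_weights"],
            dense_bias=float(data["dense_bias"]),
            spec=spec,
            training_meta=header.get("training_meta", {}),
        )
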