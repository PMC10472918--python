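"""Perturbations: what each one preserves and destroys, plus channel selection."""

import numpy as np
import pytest

from spaten.errors import ConfigurationError, InvalidInputError
from spaten.minispaten import ModelSpec, SegmentDataset, TrainConfig, train
from spaten.perturb import (
    PerturbationSpec,
    greedy_channel_selection,
    restrict_channels,
    shift_channels,
    shuffle_time_columns,
)
from spaten.synthetic_cohort import SimConfig, SubjectRecord, simulate_recording

from conftest import make_recording, random_model


class TestShuffleTime:
    def test_columns_move_as_units(self):
        X = np.array([[1.0, 2, 3], [4, 5, 6]])
        out = shuffle_time_columns(X, seed=0)
        # the multiset of column vectors is preserved exactly
        cols_in = sorted(map(tuple, X.T))
        cols_out = sorted(map(tuple, out.T))
        assert cols_in == cols_out

    def test_moments_preserved(self, rng):
        X = rng.standard_normal((5, 400))
        out = shuffle_time_columns(X, seed=3)
        np.testing.assert_allclose(out.mean(axis=1), X.mean(axis=1), atol=1e-12)
        np.testing.assert_allclose(out.var(axis=1), X.var(axis=1), atol=1e-12)

    def test_deterministic_given_seed(self, rng):
        X = rng.standard_normal((3, 100))
        np.testing.assert_array_equal(
            shuffle_time_columns(X, seed=9), shuffle_time_columns(X, seed=9)
        )

    def test_sinusoid_autocorrelation_destroyed(self):
        t = np.arange(1000) / 250.0
        X = np.tile(np.sin(2 * np.pi * 10 * t), (2, 1))

        def lag1_autocorr(x):
            return np.corrcoef(x[:-1], x[1:])[0, 1]

        assert lag1_autocorr(X[0]) > 0.9
        r1 = [lag1_autocorr(shuffle_time_columns(X, seed=s)[0]) for s in range(30)]
        assert abs(np.mean(r1)) < 0.05

    def test_single_window_topography_model_invariant(self, rng):
        # kernel_len = 1 and one global pooling window: the max over all lags
        # of a column-permuted segment is identical -> outputs exactly equal
        from spaten.minispaten import forward

        spec = ModelSpec(n_channels=4, input_len=200, n_kernels=3, kernel_len=1,
                         pool_window=200, pool_stride=200)
        model = random_model(spec, seed=4)
        X = rng.standard_normal((4, 200))
        p0, _ = forward(model, X)
        p1, _ = forward(model, shuffle_time_columns(X, seed=1))
        assert p1 == pytest.approx(p0, abs=1e-12)


class TestShiftChannels:
    def test_zero_shift_is_identity(self):
        rec = make_recording(np.random.default_rng(0).standard_normal((22, 2000)))
        out = shift_channels(rec, max_shift_s=0.0, seed=0)
        np.testing.assert_array_equal(out.signal, rec.signal)

    def test_waveforms_preserved_per_channel(self):
        cfg = SimConfig(seed=5)
        rec = simulate_recording(SubjectRecord("s0000", 0, 30.0), cfg)
        out = shift_channels(rec, max_shift_s=0.2, seed=2)
        m = 50
        n = rec.n_samples
        # each output channel must be an exact slice of its input channel
        for c in range(21):
            found = any(
                np.array_equal(out.signal[c], rec.signal[c, m - s:n - m - s])
                for s in range(-m, m + 1)
            )
            assert found
        # magnitude spectra agree closely on the trimmed support
        a = np.abs(np.fft.rfft(rec.signal[0, m:n - m]))
        b = np.abs(np.fft.rfft(out.signal[0]))
        assert np.corrcoef(a, b)[0, 1] > 0.99

    def test_zero_lag_correlation_attenuated(self, rng):
        # two perfectly correlated broadband channels decorrelate on average
        from scipy.signal import butter, sosfiltfilt

        sos = butter(4, [1, 40], btype="bandpass", fs=250.0, output="sos")
        base = sosfiltfilt(sos, rng.standard_normal(20_000))
        sig = np.tile(base, (22, 1))
        rs = []
        for seed in range(20):
            out = shift_channels(make_recording(sig), max_shift_s=0.2, seed=seed)
            rs.append(abs(np.corrcoef(out.signal[0], out.signal[1])[0, 1]))
        assert np.mean(rs) < 0.5

    def test_qrs_times_reindexed(self):
        cfg = SimConfig(effect_mode="cardiac", seed=5)
        rec = simulate_recording(SubjectRecord("s0001", 1, 30.0), cfg)
        out = shift_channels(rec, max_shift_s=0.2, seed=3)
        m = 50
        np.testing.assert_array_equal(
            out.signal[21], rec.signal[21, m:rec.n_samples - m]
        )
        expected = rec.qrs_times - m
        expected = expected[(expected >= 0) & (expected < rec.n_samples - 2 * m)]
        np.testing.assert_array_equal(out.qrs_times, expected)

    def test_negative_shift_rejected(self):
        rec = make_recording(np.zeros((22, 1000)))
        with pytest.raises(ConfigurationError):
            shift_channels(rec, max_shift_s=-1.0, seed=0)


class TestRestrictChannels:
    def _dataset(self, rng):
        labels = ("Fp1", "F4", "P3", "ECG")
        X = rng.standard_normal((6, 4, 100)).astype(np.float32)
        return SegmentDataset(X=X, y=np.array([0, 1] * 3),
                              subject_ids=np.array(list("abcdef")),
                              channels=labels)

    def test_ecg_only_gives_1x19_kernels(self, rng):
        ds = self._dataset(rng)
        sub, spec = restrict_channels(ds, ("ECG",), ModelSpec(input_len=100))
        assert spec.n_channels == 1
        assert spec.kernel_len == 19
        np.testing.assert_array_equal(sub.X[:, 0, :], ds.X[:, 3, :])

    def test_full_subset_is_identity(self, rng):
        ds = self._dataset(rng)
        sub, spec = restrict_channels(ds, ds.channels, ModelSpec(input_len=100))
        np.testing.assert_array_equal(sub.X, ds.X)
        assert spec.n_channels == 4

    def test_single_channel_projection(self, rng):
        ds = self._dataset(rng)
        sub, _ = restrict_channels(ds, ("F4",))
        np.testing.assert_array_equal(sub.X[:, 0, :], ds.X[:, 1, :])

    def test_unknown_label_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            restrict_channels(self._dataset(rng), ("Oz",))


class TestGreedySelection:
    def test_informative_channel_found_first(self):
        # oracle: exhaustive single-channel accuracies favor P3 only
        def eval_fn(channels, seed):
            score = 0.5
            if "P3" in channels or "P4" in channels:
                score += 0.3  # P4 is an exact copy of P3: no additional gain
            if "Cz" in channels:
                score += 0.1
            return score

        labels = ["Cz", "F3", "P3", "P4", "O1"]
        steps = greedy_channel_selection(labels, eval_fn, max_channels=2,
                                         n_repeats=1)
        assert steps[0]["channel"] == "P3"  # alphabetical tie-break P3 < P4
        assert steps[1]["channel"] == "Cz"  # the redundant copy is not added
        assert steps[1]["mean_accuracy"] == pytest.approx(0.9)

    def test_max_channels_one(self):
        steps = greedy_channel_selection(
            ["A", "B"], lambda ch, s: 0.9 if "B" in ch else 0.1, 1, n_repeats=2
        )
        assert len(steps) == 1
        assert steps[0]["channel"] == "B"

    def test_invalid_max_channels(self):
        with pytest.raises(InvalidInputError):
            greedy_channel_selection(["A"], lambda ch, s: 0.5, 0)

    def test_trained_selector_finds_informative_channel(self, rng):
        # end-to-end check with real trainings on a tiny amplitude-coded set
        labels = ("C3", "C4", "P3", "P4")
        X, y, ids = [], [], []
        for s in range(12):
            sex = s % 2
            for _ in range(6):
                seg = rng.standard_normal((4, 100))
                seg[2] *= 1.0 + 2.0 * sex  # P3 carries the label
                X.append(seg)
                y.append(sex)
                ids.append(f"s{s:02d}")
        ds = SegmentDataset(X=np.stack(X), y=np.array(y),
                            subject_ids=np.array(ids), channels=labels)

        def eval_fn(channels, seed):
            sub, spec = restrict_channels(
                ds, channels,
                ModelSpec(input_len=100, n_kernels=2, kernel_len=5,
                          pool_window=25, pool_stride=15),
            )
            model = train(sub, spec, TrainConfig(epochs=20, batch_size=8,
                                                 learning_rate=1e-2, seed=seed))
            return model.training_meta["holdout_balanced_accuracy"]

        steps = greedy_channel_selection(labels, eval_fn, max_channels=1,
                                         n_repeats=2, seed=0)
        assert steps[0]["channel"] == "P3"


class TestPerturbationSpec:
    def test_invalid_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            PerturbationSpec(kind="fourier_phase")

    def test_channel_subset_requires_channels(self):
        with pytest.raises(ConfigurationError):
            PerturbationSpec(kind="channel_subset")
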