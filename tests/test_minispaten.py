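"""Architecture arithmetic, forward-pass equivalence, training contracts,
majority voting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spaten.errors import ConfigurationError, InvalidInputError
from spaten.minispaten import (
    ModelSpec,
    SegmentDataset,
    TrainConfig,
    TrainedModel,
    build_model,
    count_parameters,
    ensemble_predict,
    forward,
    forward_batch,
    load_model,
    predict_subject,
    save_model,
    train,
)

from conftest import brute_curve, brute_forward, random_model


class TestSpecArithmetic:
    def test_default_spec_shapes(self):
        spec = ModelSpec()
        assert spec.curve_len == 982
        assert spec.n_windows == 40

    def test_kernel_equal_to_input_gives_single_lag(self):
        spec = ModelSpec(input_len=1000, kernel_len=1000)
        assert spec.curve_len == 1

    @given(
        input_len=st.integers(5, 60),
        kernel_len=st.integers(1, 60),
        stride=st.integers(1, 10),
        window=st.integers(1, 20),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_shape_law_matches_brute_force(self, input_len, kernel_len, stride, window):
        if kernel_len > input_len:
            kernel_len = input_len
        spec = ModelSpec(
            n_channels=2, input_len=input_len, n_kernels=1, kernel_len=kernel_len,
            pool_window=window, pool_stride=stride,
        )
        r = np.random.default_rng(0)
        X = r.standard_normal((2, input_len))
        K = r.standard_normal((1, 2, kernel_len))
        assert spec.curve_len == len(brute_curve(X, K[0]))
        bounds = spec.window_bounds()
        assert bounds[0][0] == 0
        assert all(a < b <= spec.curve_len for a, b in bounds)
        assert bounds[-1][0] < spec.curve_len
        if window >= stride:  # overlapping pooling covers every lag
            assert bounds[-1][1] == spec.curve_len

    @pytest.mark.parametrize(
        "spec,expected_weights",
        [
            (ModelSpec(), 6400),
            (ModelSpec(kernel_len=1), 16 * 21 + 16),
            (ModelSpec(n_channels=1), 16 * 19 + 16),
        ],
    )
    def test_count_parameters(self, spec, expected_weights):
        weights, total = count_parameters(spec)
        assert weights == expected_weights
        assert total == expected_weights + 1  # dense bias only

    def test_invalid_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelSpec(kernel_len=2000)


class TestForward:
    def test_zero_kernels_give_sigmoid_of_bias(self, rng):
        spec = ModelSpec(n_channels=3, input_len=50, n_kernels=2, kernel_len=5,
                         pool_window=10, pool_stride=5)
        model = TrainedModel(
            kernels=np.zeros((2, 3, 5)), dense_weights=np.zeros(2),
            dense_bias=0.7, spec=spec,
        )
        p, inter = forward(model, rng.standard_normal((3, 50)))
        assert p == pytest.approx(1 / (1 + np.exp(-0.7)))
        assert np.all(inter["curves"] == 0)

    def test_zero_segment_gives_sigmoid_of_bias(self):
        spec = ModelSpec(n_channels=3, input_len=50, n_kernels=2, kernel_len=5,
                         pool_window=10, pool_stride=5)
        model = random_model(spec, seed=3)
        p, inter = forward(model, np.zeros((3, 50)))
        assert p == pytest.approx(1 / (1 + np.exp(-model.dense_bias)))

    def test_two_channel_hand_case(self):
        # X = [[1,0,2,0,0,0],[0,1,0,0,0,0]], K = [[1,0],[0,1]]:
        # correlation curve (2,0,2,0,0); single end-padded window max 2
        spec = ModelSpec(n_channels=2, input_len=6, n_kernels=1, kernel_len=2,
                         pool_window=5, pool_stride=5)
        X = np.array([[1.0, 0, 2, 0, 0, 0], [0, 1, 0, 0, 0, 0]])
        model = TrainedModel(
            kernels=np.array([[[1.0, 0], [0, 1.0]]]),
            dense_weights=np.array([1.0]), dense_bias=0.0, spec=spec,
        )
        p, inter = forward(model, X)
        np.testing.assert_allclose(inter["curves"][:, 0], [2, 0, 2, 0, 0])
        assert inter["window_max"][0, 0] == 2.0
        assert p == pytest.approx(1 / (1 + np.exp(-2.0)))

    def test_layered_forward_equals_brute_force(self, rng):
        for seed in range(3):
            spec = ModelSpec(n_channels=5, input_len=120, n_kernels=4,
                             kernel_len=9, pool_window=25, pool_stride=10)
            model = random_model(spec, seed=seed)
            X = rng.standard_normal((5, 120))
            p, _ = forward(model, X)
            assert p == pytest.approx(brute_forward(model, X), rel=1e-5)
        # and once at the full default geometry
        model = random_model(ModelSpec(), seed=11)
        X = rng.standard_normal((21, 1000))
        p, _ = forward(model, X)
        assert p == pytest.approx(brute_forward(model, X), rel=1e-5)

    def test_shape_mismatch_rejected(self):
        model = random_model(ModelSpec(), seed=0)
        with pytest.raises(InvalidInputError):
            forward(model, np.zeros((5, 100)))

    def test_dense_weight_sign_sets_pull_direction(self, rng):
        spec = ModelSpec(n_channels=4, input_len=80, n_kernels=3, kernel_len=7,
                         pool_window=20, pool_stride=10)
        model = random_model(spec, seed=5)
        X = rng.standard_normal((4, 80))
        p0, inter = forward(model, X)
        pooled = inter["pooled_mean"]
        k = int(np.argmax(pooled))  # kernel with a strictly positive average
        assert pooled[k] > 0
        up = TrainedModel(
            kernels=model.kernels,
            dense_weights=model.dense_weights + np.eye(3)[k] * 0.5,
            dense_bias=model.dense_bias, spec=spec,
        )
        p1, _ = forward(up, X)
        assert p1 > p0


def _toy_dataset(rng, n_subjects=8, segs_per_subject=6, informative=True,
                 n_channels=4, n_samples=120):
    """Tiny dataset; channel 1 amplitude carries the label when informative."""
    X, y, ids = [], [], []
    for s in range(n_subjects):
        sex = s % 2
        for _ in range(segs_per_subject):
            seg = rng.standard_normal((n_channels, n_samples))
            if informative:
                seg[1] *= 1.0 + 1.5 * sex
            X.append(seg)
            y.append(sex)
            ids.append(f"s{s:03d}")
    return SegmentDataset(X=np.stack(X), y=np.array(y),
                          subject_ids=np.array(ids),
                          channels=tuple(f"ch{i}" for i in range(n_channels)))


SMALL_SPEC = ModelSpec(n_channels=4, input_len=120, n_kernels=4, kernel_len=7,
                       pool_window=25, pool_stride=10)


class TestTrain:
    def test_learns_informative_amplitude(self, rng):
        ds = _toy_dataset(rng, n_subjects=16, segs_per_subject=10)
        model = train(ds, SMALL_SPEC, TrainConfig(epochs=30, batch_size=16, seed=0))
        assert model.training_meta["holdout_balanced_accuracy"] > 0.8

    def test_permuted_labels_stay_at_chance(self, rng):
        ds = _toy_dataset(rng, n_subjects=16, segs_per_subject=10)
        perm = {f"s{s:03d}": lab for s, lab in
                enumerate(np.random.default_rng(3).permutation([0, 1] * 8))}
        y_perm = np.array([perm[sid] for sid in ds.subject_ids])
        ds_perm = SegmentDataset(X=ds.X, y=y_perm, subject_ids=ds.subject_ids,
                                 channels=ds.channels)
        model = train(ds_perm, SMALL_SPEC, TrainConfig(epochs=6, seed=0))
        assert model.training_meta["holdout_balanced_accuracy"] < 0.75

    def test_deterministic_given_seed(self, rng):
        ds = _toy_dataset(rng, n_subjects=8, segs_per_subject=4)
        cfg = TrainConfig(epochs=3, seed=42)
        a = train(ds, SMALL_SPEC, cfg)
        b = train(ds, SMALL_SPEC, cfg)
        np.testing.assert_array_equal(a.kernels, b.kernels)
        np.testing.assert_array_equal(a.dense_weights, b.dense_weights)
        assert a.dense_bias == b.dense_bias

    def test_single_class_rejected(self, rng):
        ds = _toy_dataset(rng, n_subjects=4)
        ds0 = ds.select(ds.y == 0)
        with pytest.raises(InvalidInputError):
            train(ds0, SMALL_SPEC, TrainConfig(epochs=1, seed=0))

    def test_holdout_is_subject_disjoint(self, rng):
        from spaten.minispaten import _subject_stratified_split

        ds = _toy_dataset(rng, n_subjects=10)
        tr_mask, ho_mask = _subject_stratified_split(
            ds, 0.2, np.random.default_rng(0)
        )
        assert not set(ds.subject_ids[tr_mask]) & set(ds.subject_ids[ho_mask])
        assert ho_mask.any() and tr_mask.any()

    def test_class_weights_unity_on_balanced_data(self, rng):
        # on a balanced cohort class weighting must be a no-op
        ds = _toy_dataset(rng, n_subjects=8, segs_per_subject=4)
        a = train(ds, SMALL_SPEC, TrainConfig(epochs=2, seed=1, class_weighting=True))
        b = train(ds, SMALL_SPEC, TrainConfig(epochs=2, seed=1, class_weighting=False))
        np.testing.assert_allclose(a.kernels, b.kernels, atol=1e-12)


def _const_prob_model(prob: float) -> TrainedModel:
    """1-channel model whose output is constant for any input."""
    spec = ModelSpec(n_channels=1, input_len=4, n_kernels=1, kernel_len=1,
                     pool_window=4, pool_stride=4)
    z = np.log(prob / (1 - prob))
    return TrainedModel(kernels=np.zeros((1, 1, 1)),
                        dense_weights=np.zeros(1), dense_bias=z, spec=spec)


class TestVoting:
    def test_majority_vote(self):
        m = _const_prob_model(0.9)
        segs = np.zeros((50, 1, 4), dtype=np.float32)
        pred = predict_subject(m, segs)
        assert pred.label == 1
        assert pred.vote_fraction == 1.0

    def test_tie_broken_by_mean_probability(self):
        # two models voting oppositely on the same segments -> ensemble tie
        m_hi = _const_prob_model(0.9)
        m_lo = _const_prob_model(0.2)
        segs = np.zeros((10, 1, 4), dtype=np.float32)
        pred = ensemble_predict([m_hi, m_lo], segs)
        assert pred.vote_fraction == 0.5
        assert pred.label == 1  # grand mean prob (0.9+0.2)/2 = 0.55 >= 0.5
        pred2 = ensemble_predict([_const_prob_model(0.6), _const_prob_model(0.1)], segs)
        assert pred2.label == 0  # grand mean 0.35 < 0.5

    def test_single_low_probability_segment_votes_female(self):
        pred = predict_subject(_const_prob_model(0.4), np.zeros((1, 1, 4), np.float32))
        assert pred.label == 0

    def test_identical_models_match_single_model(self):
        m = _const_prob_model(0.8)
        segs = np.zeros((7, 1, 4), dtype=np.float32)
        single = predict_subject(m, segs)
        ens = ensemble_predict([m] * 30, segs)
        assert ens.label == single.label

    def test_empty_inputs_rejected(self):
        m = _const_prob_model(0.8)
        with pytest.raises(InvalidInputError):
            predict_subject(m, np.zeros((0, 1, 4), np.float32))
        with pytest.raises(InvalidInputError):
            ensemble_predict([], np.zeros((1, 1, 4), np.float32))


class TestSerialization:
    def test_roundtrip(self, tmp_path, rng):
        model = random_model(ModelSpec(n_channels=3, input_len=30, n_kernels=2,
                                       kernel_len=4, pool_window=10,
                                       pool_stride=5), seed=8)
        model.training_meta = {"seed": 8, "best_epoch": 2}
        path = tmp_path / "model.msn.npz"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_array_equal(back.kernels, model.kernels)
        np.testing.assert_array_equal(back.dense_weights, model.dense_weights)
        assert back.dense_bias == model.dense_bias
        assert back.spec == model.spec
        assert back.training_meta["best_epoch"] == 2

    def test_build_model_reproducible(self):
        a = build_model(ModelSpec(), seed=5)
        b = build_model(ModelSpec(), seed=5)
        np.testing.assert_array_equal(a.kernels, b.kernels)
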