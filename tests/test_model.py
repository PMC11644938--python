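import numpy as np
import pandas as pd
import pytest

from bsdr import (
    BSDR,
    BSDRConfig,
    BandSelectionState,
    SyntheticSpec,
    count_parameters,
    denormalize_index,
    extract_bands,
    generate,
    init_band_params,
    make_split_plan,
    train,
)
from bsdr.exceptions import ConfigurationError, DataValidationError
from bsdr.model import (
    InferenceParams,
    _loss_and_grad,
    compute_loss,
    forward,
    init_inference_params,
)


class TestInitialization:
    def test_single_index_starts_at_midpoint(self):
        np.testing.assert_allclose(init_band_params(1, 10).normalized, [0.5])

    def test_three_indices_evenly_spaced(self):
        np.testing.assert_allclose(
            init_band_params(3, 100).normalized, [0.25, 0.5, 0.75]
        )

    def test_initial_integer_preview(self):
        state = init_band_params(4, 131)
        preview = [denormalize_index(q, 131) for q in state.normalized]
        assert preview == [27, 53, 79, 105]

    def test_initial_indices_strictly_increasing_and_interior(self):
        r = init_band_params(8, 50).normalized
        assert (np.diff(r) > 0).all() and (r > 0).all() and (r < 1).all()

    def test_target_size_guard(self):
        with pytest.raises(ConfigurationError):
            init_band_params(10, 10)
        with pytest.raises(ConfigurationError):
            init_band_params(0, 10)


class TestParameterAccounting:
    @pytest.mark.parametrize(
        "t, K, expected",
        [(5, 5, 9354), (5, 16, 10069), (5, 1, 9094)],
    )
    def test_closed_form_counts(self, t, K, expected):
        assert count_parameters(t, K) == expected

    @pytest.mark.parametrize("t, K", [(1, 1), (5, 5), (5, 16), (12, 3)])
    def test_instantiated_model_matches_closed_form(self, t, K):
        state = init_band_params(t, 200)
        params = init_inference_params(t, K, seed=0)
        assert state.raw_params.size + params.n_parameters == count_parameters(t, K)

    def test_each_extra_target_adds_129_parameters(self):
        for t in range(1, 6):
            assert count_parameters(t + 1, 4) - count_parameters(t, 4) == 129


class TestForwardAndLoss:
    def test_zero_weights_give_zero_outputs(self, rng):
        X = rng.random((6, 20))
        state = init_band_params(3, 20)
        zeros = InferenceParams(
            W1=np.zeros((3, 128)), b1=np.zeros(128),
            W2=np.zeros((128, 64)), b2=np.zeros(64),
            W3=np.zeros((64, 4)), b3=np.zeros(4),
        )
        np.testing.assert_array_equal(forward(X, state, zeros), np.zeros((6, 4)))

    def test_single_row_equals_batched_row(self, rng):
        X = rng.random((5, 15))
        state = init_band_params(2, 15)
        params = init_inference_params(2, 3, seed=1)
        full = forward(X, state, params)
        np.testing.assert_allclose(forward(X[2:3], state, params), full[2:3])

    def test_forward_deterministic(self, rng):
        X = rng.random((4, 10))
        state = init_band_params(2, 10)
        params = init_inference_params(2, 1, seed=5)
        np.testing.assert_array_equal(
            forward(X, state, params), forward(X, state, params)
        )

    def test_regression_loss_values(self):
        assert compute_loss(np.array([[1.0], [2.0]]), np.array([1.0, 2.0]), "regression") == 0.0
        assert compute_loss(np.array([[1.0], [1.0]]), np.array([0.0, 2.0]), "regression") == 1.0

    def test_uniform_classification_scores_give_log_k(self):
        for K in (2, 5, 16):
            scores = np.zeros((7, K))
            y = np.arange(7) % K
            assert compute_loss(scores, y, "classification") == pytest.approx(np.log(K))

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(DataValidationError):
            compute_loss(np.zeros((3, 2)), np.array([0, 1, 2]), "classification")

    @pytest.mark.parametrize("task, K", [("regression", 1), ("classification", 3)])
    def test_full_gradient_matches_finite_differences(self, task, K, rng):
        """End-to-end check of the hand-derived backward pass."""
        from bsdr.model import _backward, _forward_cached

        X = rng.random((12, 25))
        y = (rng.integers(0, K, 12) if task == "classification"
             else rng.standard_normal(12))
        c = init_band_params(3, 25).raw_params + rng.normal(0, 0.1, 3)
        params = init_inference_params(3, K, seed=3)
        out, cache = _forward_cached(X, c, params, 0.01)
        loss, dout = _loss_and_grad(out, y, task)
        grads = _backward(X, c, params, 0.01, cache, dout)
        arrays = [c] + params.arrays()
        rng2 = np.random.default_rng(0)
        for arr, grad in zip(arrays, grads):
            flat = arr.reshape(-1)
            for idx in rng2.choice(flat.size, size=min(5, flat.size), replace=False):
                h = 1e-6
                orig = flat[idx]
                flat[idx] = orig + h
                lp = compute_loss(_forward_cached(X, c, params, 0.01)[0], y, task)
                flat[idx] = orig - h
                lm = compute_loss(_forward_cached(X, c, params, 0.01)[0], y, task)
                flat[idx] = orig
                fd = (lp - lm) / (2 * h)
                assert fd == pytest.approx(grad.reshape(-1)[idx], rel=1e-4, abs=1e-8)


class TestExtraction:
    def test_known_rounding(self):
        got = extract_bands(np.array([0.0, 0.5, 1.0]), 131)
        assert got.bands.tolist() == [1, 66, 131]

    def test_duplicate_indices_collapse(self):
        # two normalized indices rounding to the same integer band
        r = np.array([0.2, 0.6915, 0.6923])  # both map to band 91 at L=131
        got = extract_bands(r, 131)
        assert got.t_prime == 2
        assert 91 in got.bands
        assert (np.diff(got.bands) > 0).all()

    def test_all_distinct_keeps_target_size(self):
        got = extract_bands(np.array([0.1, 0.4, 0.9]), 50)
        assert got.t_prime == 3

    def test_extraction_idempotent(self, rng):
        r = rng.random(6)
        L = 80
        first = extract_bands(r, L)
        re_embedded = (first.bands - 1) / (L - 1)
        second = extract_bands(re_embedded, L)
        np.testing.assert_array_equal(first.bands, second.bands)


class TestTraining:
    def test_constant_target_is_learnable(self, rng):
        X = rng.random((120, 12))
        y = np.full(120, 0.7)
        res = BSDR(X, y, task="regression").fit(target_size=2, epochs=200, seed=0)
        assert res.final_train_loss <= 1e-3  # variance of a constant target is 0

    def test_planted_band_recovery_single_index(self):
        """A single relaxed index migrates to a planted band at position 0.6L."""
        spec = SyntheticSpec(
            n_samples=500, n_bands=100, informative_bands=[60],
            task="regression", smoothness=5, noise_sd=0.05, seed=1,
        )
        ds, truth = generate(spec)
        res = BSDR(ds).fit(target_size=1, epochs=500, seed=0)
        assert res.selected_bands.t_prime == 1
        assert abs(res.bands[0] - 60) <= 2  # within 2% of L

    def test_training_is_reproducible(self, tiny_regression):
        ds, _ = tiny_regression
        plan = make_split_plan(ds.n_samples, 1, 3)
        config = BSDRConfig(target_size=2, task="regression", epochs=60, seed=9)
        s1, p1, t1 = train(ds, plan, config)
        s2, p2, t2 = train(ds, plan, config)
        np.testing.assert_array_equal(s1.raw_params, s2.raw_params)
        np.testing.assert_array_equal(p1.W1, p2.W1)
        pd.testing.assert_frame_equal(t1, t2)

    def test_trace_shape_and_band_range(self, tiny_regression):
        ds, _ = tiny_regression
        plan = make_split_plan(ds.n_samples, 2, 3)
        config = BSDRConfig(target_size=3, task="regression", epochs=40, seed=0)
        _, _, trace = train(ds, plan, config)
        assert len(trace) == 40
        band_cols = [c for c in trace.columns if c.startswith("band_")]
        assert len(band_cols) == 3
        assert trace[band_cols].min().min() >= 1
        assert trace[band_cols].max().max() <= ds.n_bands
        assert {"train_loss", "val_r2", "val_rmse"} <= set(trace.columns)

    def test_normalized_indices_stay_interior(self, tiny_classification):
        ds, _ = tiny_classification
        plan = make_split_plan(ds.n_samples, 1, 5, labels=ds.targets)
        config = BSDRConfig(target_size=2, task="classification", epochs=50, seed=2)
        state, _, trace = train(ds, plan, config)
        assert (state.normalized > 0).all() and (state.normalized < 1).all()
        assert {"val_oa", "val_kappa"} <= set(trace.columns)

    def test_task_mismatch_rejected(self, tiny_regression):
        ds, _ = tiny_regression
        plan = make_split_plan(ds.n_samples, 1, 3)
        config = BSDRConfig(target_size=2, task="classification", epochs=5)
        with pytest.raises(ConfigurationError):
            train(ds, plan, config)

    def test_target_size_must_be_below_band_count(self, tiny_regression):
        ds, _ = tiny_regression
        with pytest.raises(ConfigurationError):
            BSDR(ds).fit(target_size=ds.n_bands, epochs=5)


class TestResultsObject:
    def test_summary_and_predict(self, tiny_regression):
        ds, _ = tiny_regression
        res = BSDR(ds).fit(target_size=2, epochs=80, seed=4)
        text = res.summary()
        assert "Selected bands" in text and str(ds.n_bands) in text
        pred = res.predict(ds.reflectance[:10])
        assert pred.shape == (10,)
        assert res.n_parameters == count_parameters(2, 1)

    def test_from_dataframe_classification(self, tiny_classification):
        ds, _ = tiny_classification
        df = ds.to_dataframe("crop")
        model = BSDR.from_dataframe(df, "crop", "classification")
        assert model.dataset.n_classes == 3
        assert model.dataset.n_bands == ds.n_bands
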