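"""Network forward pass, backprop gradients, training and metrics."""

import numpy as np
import pytest

import crocinopt as co
from crocinopt.ann import (
    EnsembleModel,
    forward,
    mse_and_gradient,
    new_model,
    predict,
    train,
)


def _identity_scaled_model(n_hidden, activation, n_in=25):
    """Model whose range scaling is the identity on inputs and output."""
    X = np.vstack([np.zeros(n_in), np.ones(n_in)])
    y = np.array([0.0, 1.0])
    return new_model(n_hidden, activation, X, y)


def test_zero_weight_network_outputs_zero():
    model = _identity_scaled_model(4, "tanh")
    X = np.random.default_rng(0).random((6, 25))
    np.testing.assert_allclose(forward(model, X), 0.0, atol=1e-15)


def test_hand_evaluated_single_hidden_unit():
    model = _identity_scaled_model(1, "tanh")
    model.W_h[0, 0] = 1.0
    model.w_out[0] = 2.0
    model.b_out = 0.5
    x = np.zeros(25)
    x[0] = 0.3
    assert forward(model, x)[0] == pytest.approx(2.0 * np.tanh(0.3) + 0.5)


def test_logistic_and_tanh_members_differ():
    x = np.full(25, 0.4)
    outputs = []
    for act in ("logistic", "tanh"):
        model = _identity_scaled_model(3, act)
        model.W_h[:] = 0.5
        model.w_out[:] = 1.0
        outputs.append(forward(model, x)[0])
    assert outputs[0] != pytest.approx(outputs[1])


def test_dimension_mismatch_rejected():
    model = _identity_scaled_model(2, "tanh")
    with pytest.raises(ValueError, match="expected 25 inputs"):
        forward(model, np.zeros(7))


@pytest.mark.parametrize("activation", ["logistic", "tanh"])
@pytest.mark.parametrize("n_hidden", [1, 3, 6])
def test_backprop_gradient_matches_central_differences(activation, n_hidden):
    rng = np.random.default_rng(42)
    n, n_in = 15, 5
    Z = rng.random((n, n_in))
    ys = rng.random(n)
    X_cal = np.vstack([np.zeros(n_in), np.ones(n_in)])
    model = new_model(n_hidden, activation, X_cal, np.array([0.0, 1.0]))
    w = rng.normal(scale=0.7, size=n_hidden * (n_in + 2) + 1)

    _, grad = mse_and_gradient(model, w, Z, ys)
    h = 1e-6
    for k in range(len(w)):
        wp, wm = w.copy(), w.copy()
        wp[k] += h
        wm[k] -= h
        fd = (mse_and_gradient(model, wp, Z, ys)[0]
              - mse_and_gradient(model, wm, Z, ys)[0]) / (2 * h)
        assert grad[k] == pytest.approx(fd, rel=1e-6, abs=1e-9)


def _linear_problem(seed=0, n=120, n_in=6):
    rng = np.random.default_rng(seed)
    X = rng.random((n, n_in))
    y = X[:, 0].copy()
    return X[: n // 2], y[: n // 2], X[n // 2 :], y[n // 2 :]


def test_linear_target_learned_to_high_r2():
    X_tr, y_tr, X_vl, y_vl = _linear_problem()
    model = new_model(4, "tanh", np.vstack([X_tr, X_vl]),
                      np.concatenate([y_tr, y_vl]))
    config = co.TrainConfig(max_epochs=200, patience=30, seed=1)
    train(model, X_tr, y_tr, X_vl, y_vl, config, seed=1)
    r2, _ = co.metrics(forward(model, X_tr), y_tr)
    assert r2 >= 0.999


def test_training_is_deterministic_and_reports_validation_minimum():
    X_tr, y_tr, X_vl, y_vl = _linear_problem(seed=3)
    X_cal = np.vstack([X_tr, X_vl])
    y_cal = np.concatenate([y_tr, y_vl])
    config = co.TrainConfig(max_epochs=60, patience=10, seed=7)

    results = []
    weights = []
    for _ in range(2):
        model = new_model(3, "logistic", X_cal, y_cal)
        results.append(train(model, X_tr, y_tr, X_vl, y_vl, config, seed=7))
        weights.append(model.get_weights())
    np.testing.assert_array_equal(weights[0], weights[1])

    result = results[0]
    assert result.best_epoch == int(np.argmin(result.val_trace))
    # early stopping never reports a worse error than the final epoch
    assert result.val_trace[result.best_epoch] <= result.val_trace[-1]


def test_empty_sets_rejected():
    model = _identity_scaled_model(2, "tanh", n_in=3)
    with pytest.raises(ValueError, match="nonempty"):
        train(model, np.empty((0, 3)), np.empty(0), np.ones((2, 3)),
              np.ones(2), co.TrainConfig())


def test_singleton_grid_selected():
    X_tr, y_tr, X_vl, y_vl = _linear_problem(seed=5)
    config = co.TrainConfig(max_epochs=40, patience=10, seed=0,
                            hidden_grid=(8,), activations=("tanh",))
    H, act, table = co.select_architecture(X_tr, y_tr, X_vl, y_vl, config)
    assert (H, act) == (8, "tanh")
    assert len(table) == 1


def test_grid_scan_is_exhaustive():
    X_tr, y_tr, X_vl, y_vl = _linear_problem(seed=5)
    config = co.TrainConfig(max_epochs=15, patience=5, seed=0,
                            hidden_grid=(2, 4), activations=("logistic", "tanh"))
    _, _, table = co.select_architecture(X_tr, y_tr, X_vl, y_vl, config)
    assert len(table) == 4


def test_single_restart_ensemble_equals_member():
    X_tr, y_tr, X_vl, y_vl = _linear_problem(seed=2)
    config = co.TrainConfig(max_epochs=40, patience=10, restarts=1, seed=0)
    ensemble = co.train_ensemble(3, "tanh", X_tr, y_tr, X_vl, y_vl, config)
    np.testing.assert_array_equal(
        predict(ensemble, X_vl), forward(ensemble.members[0], X_vl)
    )


def test_ensemble_mean_is_bounded_by_members():
    X_tr, y_tr, X_vl, y_vl = _linear_problem(seed=2)
    config = co.TrainConfig(max_epochs=30, patience=10, restarts=3, seed=0)
    ensemble = co.train_ensemble(3, "tanh", X_tr, y_tr, X_vl, y_vl, config)
    members = np.stack([forward(m, X_vl) for m in ensemble.members])
    mean = predict(ensemble, X_vl)
    assert np.all(mean <= members.max(axis=0) + 1e-12)
    assert np.all(mean >= members.min(axis=0) - 1e-12)


def test_mixed_architectures_rejected():
    a = _identity_scaled_model(2, "tanh")
    b = _identity_scaled_model(3, "tanh")
    with pytest.raises(ValueError, match="share one architecture"):
        EnsembleModel(members=[a, b])


def test_ensemble_json_roundtrip(tmp_path):
    X_tr, y_tr, X_vl, y_vl = _linear_problem(seed=9)
    config = co.TrainConfig(max_epochs=20, patience=5, restarts=2, seed=0)
    ensemble = co.train_ensemble(2, "logistic", X_tr, y_tr, X_vl, y_vl, config)
    path = tmp_path / "model.json"
    ensemble.to_json(path)
    loaded = EnsembleModel.from_json(path)
    np.testing.assert_allclose(predict(loaded, X_vl), predict(ensemble, X_vl))


def test_forward_matches_sklearn_mlp_with_same_weights():
    """Independent forward-pass check against scikit-learn's MLP."""
    from sklearn.neural_network import MLPRegressor

    rng = np.random.default_rng(0)
    model = _identity_scaled_model(5, "tanh", n_in=7)
    model.set_weights(rng.normal(scale=0.5, size=5 * 9 + 1))

    X = rng.random((20, 7))
    mlp = MLPRegressor(hidden_layer_sizes=(5,), activation="tanh", max_iter=5)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # un-converged throwaway fit
        mlp.fit(X, rng.random(20))
    mlp.coefs_ = [model.W_h.T.copy(), model.w_out[:, None].copy()]
    mlp.intercepts_ = [model.b_h.copy(), np.array([model.b_out])]
    np.testing.assert_allclose(mlp.predict(X), forward(model, X), rtol=1e-10)


def test_metrics_hand_examples():
    assert co.metrics(np.array([1.0, 2.0]), np.array([1.0, 2.0])) == (1.0, 0.0)
    targets = np.array([0.0, 1.0, 2.0])
    r2, se = co.metrics(np.full(3, 1.0), targets)
    assert r2 == pytest.approx(0.0)
    r2, se = co.metrics(np.array([0.0, 1.0, 1.0]), targets)
    assert r2 == pytest.approx(0.5)
    assert se == pytest.approx(np.sqrt(1.0 / 3.0))


def test_metrics_zero_variance_targets_rejected():
    with pytest.raises(ValueError, match="zero-variance"):
        co.metrics(np.array([1.0, 2.0]), np.array([3.0, 3.0]))


def test_ensemble_r2_on_default_noisy_campaign(factors, design):
    """Validation fit on the default-noise seed-0 campaign is strong."""
    config = co.SimulationConfig(seed=0)
    params = co.sample_analyte_params(config)
    chroms = co.simulate_campaign(params, design, config)
    calibration, _ = co.assemble(chroms)
    split = co.split_dataset(calibration)
    X, y = co.samples_to_arrays(calibration)
    tr, vl = list(split.training), list(split.validation)
    tc = co.TrainConfig(restarts=3, seed=0)
    ensemble = co.train_ensemble(8, "tanh", X[tr], y[tr], X[vl], y[vl], tc)
    r2, _ = co.metrics(predict(ensemble, X[vl]), y[vl])
    assert r2 >= 0.85
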