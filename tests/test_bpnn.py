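import json
import math

import numpy as np
import pytest

from imurehab.bpnn import (
    NetworkModel,
    TrainingConfig,
    _mse_and_grads,
    evaluate_mse,
    forward,
    logsig,
    stratified_split,
    train,
)


def tiny_model(sizes=(2, 2, 2), fill=0.0, **overrides):
    n, l, m = sizes
    fields = dict(
        sizes=sizes,
        w_hidden=np.full((l, n), fill),
        b_hidden=np.full(l, fill),
        w_out=np.full((m, l), fill),
        b_out=np.full(m, fill),
        stop_reason="pg_reached",
    )
    fields.update(overrides)
    return NetworkModel(**fields)


# ---------------------------------------------------------------- logsig


def test_logsig_at_zero():
    assert logsig(0.0) == pytest.approx(0.5)


def test_logsig_limits_and_stability():
    assert logsig(40.0) == pytest.approx(1.0)
    assert logsig(-40.0) == pytest.approx(0.0, abs=1e-15)
    with np.errstate(over="raise"):  # must not overflow for huge |t|
        assert logsig(1e4) == 1.0
        assert logsig(-1e4) == 0.0


def test_logsig_derivative_matches_finite_differences():
    h = 1e-6
    for t in np.linspace(-6, 6, 25):
        analytic = logsig(t) * (1 - logsig(t))
        numeric = (logsig(t + h) - logsig(t - h)) / (2 * h)
        assert analytic == pytest.approx(numeric, abs=1e-6)


# ---------------------------------------------------------------- forward


def test_zero_network_outputs_zero():
    model = tiny_model((4, 3, 2))
    out = forward(model, np.array([1.0, -2.0, 3.0, 0.5]))
    assert np.allclose(out, 0.0)


def test_forward_matches_pencil_and_paper():
    # 2-2-2 network evaluated by independent scalar arithmetic
    model = tiny_model(
        (2, 2, 2),
        w_hidden=np.array([[0.5, -0.25], [1.0, 0.5]]),
        b_hidden=np.array([0.1, -0.2]),
        w_out=np.array([[1.0, 2.0], [-1.0, 0.5]]),
        b_out=np.array([0.0, 0.3]),
    )
    x = (1.0, -1.0)
    h0 = 1 / (1 + math.exp(-(0.5 * 1.0 + -0.25 * -1.0 + 0.1)))
    h1 = 1 / (1 + math.exp(-(1.0 * 1.0 + 0.5 * -1.0 + -0.2)))
    expected = (h0 + 2 * h1, -h0 + 0.5 * h1 + 0.3)
    assert forward(model, np.array(x)) == pytest.approx(expected)


def test_forward_wrong_length_raises():
    with pytest.raises(ValueError, match="length"):
        forward(tiny_model((4, 3, 2)), np.zeros(5))


def test_forward_finite_on_unit_inputs():
    rng = np.random.default_rng(0)
    model = tiny_model(
        (10, 5, 6),
        w_hidden=rng.normal(size=(5, 10)),
        b_hidden=rng.normal(size=5),
        w_out=rng.normal(size=(6, 5)),
        b_out=rng.normal(size=6),
    )
    X = rng.uniform(-1, 1, size=(10, 30))
    assert np.isfinite(forward(model, X)).all()


# ---------------------------------------------------------------- evaluate_mse


def test_mse_zero_when_outputs_equal_targets():
    model = tiny_model((3, 2, 2), b_out=np.array([0.7, -0.2]))
    X = np.zeros((3, 5))
    T = np.tile([[0.7], [-0.2]], (1, 5))
    assert evaluate_mse(model, X, T) == pytest.approx(0.0)


def test_mse_zero_output_vs_one_hot_is_one_sixth():
    # each column contributes 1^2 over 6 outputs
    model = tiny_model((8, 3, 6))
    X = np.zeros((8, 12))
    T = np.zeros((6, 12))
    T[np.arange(12) % 6, np.arange(12)] = 1.0
    assert evaluate_mse(model, X, T) == pytest.approx(1.0 / 6.0)


def test_mse_invariant_to_joint_column_permutation():
    rng = np.random.default_rng(5)
    model = tiny_model(
        (4, 3, 2),
        w_hidden=rng.normal(size=(3, 4)),
        b_hidden=rng.normal(size=3),
        w_out=rng.normal(size=(2, 3)),
        b_out=rng.normal(size=2),
    )
    X = rng.normal(size=(4, 9))
    T = rng.normal(size=(2, 9))
    perm = rng.permutation(9)
    assert evaluate_mse(model, X, T) == pytest.approx(evaluate_mse(model, X[:, perm], T[:, perm]))


# ---------------------------------------------------------------- gradients (core oracle)


@pytest.mark.parametrize("seed", range(5))
def test_backprop_matches_central_finite_differences(seed):
    rng = np.random.default_rng(seed)
    n, l, m, N = 7, 4, 3, 6
    model = tiny_model(
        (n, l, m),
        w_hidden=rng.normal(size=(l, n)) * 0.7,
        b_hidden=rng.normal(size=l) * 0.7,
        w_out=rng.normal(size=(m, l)) * 0.7,
        b_out=rng.normal(size=m) * 0.7,
    )
    X = rng.normal(size=(n, N))
    T = rng.normal(size=(m, N))
    _, grads = _mse_and_grads(model, X, T)

    h = 1e-6
    params = (model.w_hidden, model.b_hidden, model.w_out, model.b_out)
    for p, g in zip(params, grads):
        it = np.nditer(p, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = p[idx]
            p[idx] = orig + h
            up = evaluate_mse(model, X, T)
            p[idx] = orig - h
            down = evaluate_mse(model, X, T)
            p[idx] = orig
            numeric = (up - down) / (2 * h)
            denom = max(abs(numeric), abs(g[idx]), 1e-8)
            assert abs(g[idx] - numeric) / denom < 1e-5


# ---------------------------------------------------------------- training


def blob_data(seed=0, n_classes=2, dim=4, per_class=20, spread=0.15):
    rng = np.random.default_rng(seed)
    centers = rng.uniform(-1, 1, size=(n_classes, dim)) * 2
    X, T = [], []
    for k in range(n_classes):
        pts = centers[k][:, None] + rng.normal(0, spread, size=(dim, per_class))
        X.append(pts)
        t = np.zeros((n_classes, per_class))
        t[k] = 1.0
        T.append(t)
    return np.concatenate(X, axis=1), np.concatenate(T, axis=1)


def test_train_separable_toy_reaches_pg():
    X, T = blob_data(seed=1)
    cfg = TrainingConfig(pg=1e-3, seed=1, max_epochs=2000)
    model = train(X, T, cfg, sizes=(4, 3, 2), scale=False)
    assert model.pg_reached and model.train_mse[-1] <= 1e-3
    tr = np.asarray(model.split_indices["train"])
    out = forward(model, X[:, tr])
    assert np.array_equal(out.argmax(axis=0), T[:, tr].argmax(axis=0))  # 100% train accuracy


def test_train_monotone_under_small_fixed_rate():
    # with adaptation off and a tiny rate, batch descent must not increase MSE
    X, T = blob_data(seed=2)
    cfg = TrainingConfig(
        pg=1e-12,
        seed=2,
        learning_rate=1e-3,
        momentum=0.0,
        lr_increase=1.0,
        lr_decrease=1.0,
        max_error_increase=1e9,
        max_epochs=300,
        patience=300,
        restarts=0,
    )
    model = train(X, T, cfg, sizes=(4, 3, 2), scale=False)
    assert (np.diff(model.train_mse) <= 1e-12).all()


def test_train_deterministic():
    X, T = blob_data(seed=3)
    cfg = TrainingConfig(pg=1e-4, seed=7, max_epochs=500)
    m1 = train(X, T, cfg, sizes=(4, 3, 2), scale=False)
    m2 = train(X, T, cfg, sizes=(4, 3, 2), scale=False)
    assert np.array_equal(m1.w_hidden, m2.w_hidden) and np.array_equal(m1.w_out, m2.w_out)
    assert m1.train_mse == m2.train_mse and m1.val_mse == m2.val_mse


def test_unreachable_pg_flagged_not_raised():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(4, 40))
    T = rng.normal(size=(2, 40))  # noise targets: PG hopeless
    cfg = TrainingConfig(pg=1e-12, seed=0, max_epochs=30, patience=30, restarts=1)
    model = train(X, T, cfg, sizes=(4, 3, 2), scale=False)
    assert not model.pg_reached
    assert model.stop_reason in ("max_epochs", "validation_rise")


def test_early_stop_restores_best_validation_weights():
    rng = np.random.default_rng(9)
    X, T = blob_data(seed=9, spread=0.8)
    T = T + rng.normal(0, 0.3, size=T.shape)  # noisy targets invite overfitting
    cfg = TrainingConfig(pg=1e-10, seed=9, max_epochs=800, patience=3, restarts=0)
    model = train(X, T, cfg, sizes=(4, 4, 2), scale=False)
    va = np.asarray(model.split_indices["val"])
    final_val = evaluate_mse(model, X[:, va], T[:, va])
    assert final_val <= min(model.val_mse) + 1e-9


def test_split_is_partition():
    labels = np.repeat(np.arange(1, 7), 12)
    rng = np.random.default_rng(11)
    tr, va, te = stratified_split(labels, (0.7, 0.15, 0.15), rng)
    merged = np.concatenate([tr, va, te])
    assert len(np.unique(merged)) == len(labels) == len(merged)
    # stratification: every class appears in every partition
    for part in (tr, va, te):
        assert set(labels[part]) == set(range(1, 7))
    tr2, va2, te2 = stratified_split(labels, (0.7, 0.15, 0.15), np.random.default_rng(11))
    assert np.array_equal(tr, tr2) and np.array_equal(va, va2) and np.array_equal(te, te2)


def test_config_validation():
    with pytest.raises(ValueError):
        TrainingConfig(pg=0.0)
    with pytest.raises(ValueError):
        TrainingConfig(split=(0.5, 0.5, 0.2))
    with pytest.raises(ValueError):
        TrainingConfig(patience=0)


# ---------------------------------------------------------------- persistence


def test_model_json_round_trip(tmp_path):
    X, T = blob_data(seed=6)
    cfg = TrainingConfig(pg=1e-3, seed=6, max_epochs=500)
    model = train(X, T, cfg, sizes=(4, 3, 2), scale=False)
    path = tmp_path / "model.json"
    model.save(path)
    json.loads(path.read_text())  # must be plain JSON
    back = NetworkModel.load(path)
    probe = np.random.default_rng(0).normal(size=(4, 7))
    assert np.allclose(forward(model, probe), forward(back, probe))
    assert back.config == model.config and back.stop_reason == model.stop_reason
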