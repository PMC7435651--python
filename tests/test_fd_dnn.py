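"""FD-DNN tests: the framework-free shape/parameter audits, softmax and
cross-entropy closed forms, finite-difference gradient checks of the
NumPy layers, and the training harness contract."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fallsense import (LayerSpec, ModelSpec, TrainConfig, audit_params,
                       audit_shapes, cross_entropy, default_model_spec,
                       one_hot, predict, softmax, train)
from fallsense.fd_dnn import (TrainingError, _backward, _forward,
                              build_network, format_audit_table)


# ------------------------------------------------------------------ audits

def test_parameter_audit_reproduces_printed_counts():
    params = audit_params(default_model_spec(4))
    assert params["C1"] == 608                 # 32 x (3 x 6) + 32
    assert params["L1"] == params["L2"] == 320_800  # 4x200x(200+200+1)
    assert params["Fc"] == 1_608               # 200 x 8 + 8
    assert params["S1"] == params["S4"] == params["reshape"] == 0


def test_shape_audit_timestep_sequence():
    shapes = audit_shapes(default_model_spec(4))
    assert [t for _, t, _ in shapes] == [
        200, 200, 100, 100, 50, 50, 25, 25, 13, 13, None, None, None]
    by_name = {name: (t, f) for name, t, f in shapes}
    assert by_name["C1"] == (200, 32)
    assert by_name["S4"] == (13, 200)
    assert by_name["Fc"] == (None, 8)


def test_even_length_pool_halves_exactly():
    spec = ModelSpec(layers=(
        LayerSpec(kind="maxpool1d", name="S", pool_size=2, stride=2),),
        input_length=64, in_channels=4)
    assert audit_shapes(spec)[-1][1] == 32


@pytest.mark.parametrize("conv_layers,reshape_shape", [
    (1, (100, 32)), (2, (50, 64)), (4, (13, 200))])
def test_truncated_specs(conv_layers, reshape_shape):
    shapes = dict((name, (t, f))
                  for name, t, f in audit_shapes(default_model_spec(conv_layers)))
    assert shapes["reshape"] == reshape_shape


def test_extension_replicates_last_conv_block():
    spec = default_model_spec(5)
    convs = [l for l in spec.layers if l.kind == "conv1d"]
    assert convs[4].filters == convs[3].filters == 200
    assert convs[4].kernel == convs[3].kernel == 9
    # the extra block's parameter cost is reported by the auditor
    delta = audit_params(spec)["total"] - audit_params(default_model_spec(4))["total"]
    assert delta > 0
    with pytest.raises(ValueError):
        default_model_spec(0)
    with pytest.raises(ValueError):
        default_model_spec(7)


def test_audit_table_mentions_headline_counts():
    table = format_audit_table(default_model_spec(4))
    assert "608" in table and "320,800" in table


def test_model_spec_yaml_round_trip(tmp_path):
    spec = default_model_spec(3, lstm_units=16)
    path = tmp_path / "spec.yaml"
    spec.to_yaml(path)
    assert ModelSpec.from_yaml(path) == spec


# ---------------------------------------------------- elementary functions

def test_softmax_closed_forms():
    np.testing.assert_allclose(softmax(np.zeros(8)), np.full(8, 0.125))
    np.testing.assert_allclose(softmax(np.array([0.0, np.log(2)])),
                               [1 / 3, 2 / 3])
    rng = np.random.default_rng(0)
    x = rng.normal(0, 100, (5, 8))
    np.testing.assert_allclose(softmax(x).sum(axis=1), 1.0, atol=1e-12)


@given(st.lists(st.floats(-50, 50), min_size=2, max_size=8),
       st.floats(-100, 100))
@settings(deadline=None, max_examples=50, derandomize=True)
def test_softmax_shift_invariance(logits, c):
    x = np.array(logits)
    np.testing.assert_allclose(softmax(x + c), softmax(x), atol=1e-12)


def test_cross_entropy_closed_forms():
    y = one_hot([0, 3, 7], 8)
    assert cross_entropy(y, y) == pytest.approx(0.0)
    uniform = np.full((3, 8), 0.125)
    assert cross_entropy(y, uniform) == pytest.approx(np.log(8))
    rng = np.random.default_rng(1)
    p = softmax(rng.normal(size=(10, 8)))
    assert cross_entropy(one_hot(rng.integers(0, 8, 10), 8), p) >= 0.0
    with pytest.raises(ValueError, match="shape"):
        cross_entropy(y, uniform[:, :4])


def test_one_hot_contract():
    np.testing.assert_array_equal(one_hot([0], 2), [[1.0, 0.0]])
    np.testing.assert_array_equal(one_hot([7], 8)[0],
                                  np.eye(8)[7])
    v = np.array([3, 1, 4, 1, 5])
    assert np.array_equal(one_hot(v, 8).argmax(axis=1), v)
    with pytest.raises(ValueError):
        one_hot([8], 8)


# ------------------------------------------------------- gradient checking

def _tiny_spec() -> ModelSpec:
    return ModelSpec(layers=(
        LayerSpec(kind="conv1d", name="C1", filters=3, kernel=3,
                  activation="relu"),
        LayerSpec(kind="maxpool1d", name="S1", pool_size=2, stride=2),
        LayerSpec(kind="conv1d", name="C2", filters=4, kernel=4,
                  activation="relu"),
        LayerSpec(kind="maxpool1d", name="S2", pool_size=2, stride=2),
        LayerSpec(kind="reshape_split", name="reshape"),
        LayerSpec(kind="lstm", name="L1", units=5, dropout=0.0),
        LayerSpec(kind="lstm", name="L2", units=5, dropout=0.0),
        LayerSpec(kind="dense", name="Fc", units=3, activation="softmax"),
    ), input_length=9, in_channels=2, n_classes=3)


def test_backpropagation_matches_finite_differences():
    """Analytic gradients of every layer (conv with even and odd
    kernels, pooling over odd lengths, stacked LSTMs, dense) agree with
    central finite differences."""
    rng = np.random.default_rng(0)
    layers = build_network(_tiny_spec(), rng)
    x = rng.normal(size=(3, 9, 2))
    y = one_hot(np.array([0, 1, 2]), 3)

    def loss():
        return cross_entropy(y, softmax(_forward(layers, x, False, rng)))

    probs = softmax(_forward(layers, x, False, rng))
    _backward(layers, (probs - y) / len(x))
    eps = 1e-6
    for layer in layers:
        for p, g in zip(getattr(layer, "params", []),
                        getattr(layer, "grads", [])):
            flat, gflat = p.ravel(), g.ravel()
            for idx in rng.choice(flat.size, size=min(8, flat.size),
                                  replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = loss()
                flat[idx] = orig - eps
                lm = loss()
                flat[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                assert gflat[idx] == pytest.approx(numeric, rel=1e-4,
                                                   abs=1e-7)


def test_shape_audit_agrees_with_network_forward():
    """The auditor's arithmetic matches the actual tensor shapes the
    NumPy network produces, layer by layer."""
    spec = default_model_spec(4, lstm_units=8)
    rng = np.random.default_rng(0)
    layers = build_network(spec, rng)
    x = rng.normal(size=(2, 200, 6))
    audited = audit_shapes(spec)[1:]  # skip the input row
    li = 0
    for layer, (name, t, f) in zip(layers, audited):
        x = layer.forward(x, False, rng)
        if t is not None:
            assert x.shape[1:] == (t, f), name
        li += 1
        if name == "Fc":
            assert x.shape[1:] == (f,)


# --------------------------------------------------------- training harness

def _toy_data(n_per=24, length=9, channels=2, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(length)
    x0 = 0.8 * np.sin(2 * np.pi * t / 4)[None, :, None] + \
        rng.normal(0, 0.1, (n_per, length, channels))
    x1 = 0.6 + rng.normal(0, 0.1, (n_per, length, channels))
    x2 = -0.6 + 0.1 * t[None, :, None] + \
        rng.normal(0, 0.1, (n_per, length, channels))
    x = np.concatenate([x0, x1, x2])
    y = np.repeat([0, 1, 2], n_per)
    return x, y


def test_training_is_deterministic_for_fixed_seed():
    x, y = _toy_data()
    spec = _tiny_spec()
    cfg = TrainConfig(batch_size=16, max_epochs=2, seed=11)
    m1 = train(spec, x, y, config=cfg)
    m2 = train(spec, x, y, config=cfg)
    h1 = [r["loss"] for r in m1.history]
    h2 = [r["loss"] for r in m2.history]
    assert h1 == h2
    p1, _ = predict(m1, x)
    p2, _ = predict(m2, x)
    assert np.array_equal(p1, p2)


def test_separable_toy_problem_reaches_full_training_accuracy():
    x, y = _toy_data()
    spec = _tiny_spec()
    cfg = TrainConfig(batch_size=16, max_epochs=50, seed=3, patience=100)
    model = train(spec, x, y, x, y, config=cfg)
    _, pred = predict(model, x)
    assert np.mean(pred == y) == 1.0


def test_history_cadence_and_checkpoints(tmp_path):
    x, y = _toy_data()
    spec = _tiny_spec()
    # 72 samples / batch 16 -> 5 iterations per epoch; 12 epochs -> 60
    cfg = TrainConfig(batch_size=16, max_epochs=12, seed=0, patience=100,
                      checkpoint_every_epochs=10)
    model = train(spec, x, y, x, y, config=cfg,
                  checkpoint_dir=tmp_path / "ckpt")
    iters = 12 * 5
    train_rows = [r for r in model.history if r["split"] == "train"]
    val_rows = [r for r in model.history if r["split"] == "val"]
    assert len(train_rows) == iters // cfg.train_metric_every
    assert len(val_rows) == iters // cfg.val_every
    assert sorted(p.name for p in (tmp_path / "ckpt").glob("*.npz")) == [
        "epoch_0010.npz"]
    model.export_history_csv(tmp_path / "history.csv")
    header = (tmp_path / "history.csv").read_text().splitlines()[0]
    assert header == "iteration,epoch,split,loss,accuracy"


def test_checkpoint_round_trip_preserves_predictions(tmp_path):
    x, y = _toy_data()
    spec = _tiny_spec()
    cfg = TrainConfig(batch_size=16, max_epochs=3, seed=5)
    model = train(spec, x, y, config=cfg)
    probs, _ = predict(model, x)
    model.save_checkpoint(tmp_path / "m.npz")
    other = train(spec, x, y, config=TrainConfig(batch_size=16, max_epochs=1,
                                                 seed=99))
    other.load_checkpoint(tmp_path / "m.npz")
    probs2, _ = predict(other, x)
    np.testing.assert_allclose(probs, probs2)


def test_prediction_is_deterministic_despite_dropout():
    x, y = _toy_data()
    spec = ModelSpec(layers=tuple(
        LayerSpec(**{**l.__dict__, "dropout": 0.5}) if l.kind == "lstm" else l
        for l in _tiny_spec().layers), input_length=9, in_channels=2,
        n_classes=3)
    model = train(spec, x, y, config=TrainConfig(batch_size=16, max_epochs=2,
                                                 seed=1))
    p1, l1 = predict(model, x)
    p2, l2 = predict(model, x)
    assert np.array_equal(p1, p2) and np.array_equal(l1, l2)
    np.testing.assert_allclose(p1.sum(axis=1), 1.0, atol=1e-12)


def test_training_input_contract():
    spec = _tiny_spec()
    with pytest.raises(TrainingError, match="empty"):
        train(spec, np.empty((0, 9, 2)), np.empty(0, dtype=int))
    with pytest.raises(ValueError, match="window shape"):
        train(spec, np.zeros((4, 7, 2)), np.zeros(4, dtype=int))
    x, y = _toy_data()
    with pytest.raises(TrainingError, match="non-finite"):
        bad = x.copy()
        bad[0] = np.nan
        train(spec, bad, y, config=TrainConfig(batch_size=72, max_epochs=1))
    model = train(spec, x, y, config=TrainConfig(batch_size=16, max_epochs=1))
    with pytest.raises(ValueError, match="window shape"):
        predict(model, np.zeros((2, 5, 2)))
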