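"""Analog classifier simulation: quantization, charge-sharing MACs,
amplifier transfer curves, forward passes and error-aware training."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from sepsisfuse.analog import (
    AnalogANN,
    TrainConfig,
    characterize_activation,
    dac_quantize,
    mac,
    train_error_aware,
)


# ------------------------------------------------------------- quantization

def test_dac_endpoint_codes():
    assert dac_quantize(0.0, 4) == 0.0
    assert dac_quantize(1.0, 4) == 1.0


def test_dac_half_up_at_midpoint():
    # nearest 4-bit level to 0.5 is code 8 -> 8/15
    assert dac_quantize(0.5, 4) == pytest.approx(8 / 15, abs=1e-15)


def test_dac_error_bounded_by_half_lsb_and_monotone_in_bits():
    g = np.linspace(0.0, 1.0, 10_000)
    errors = {b: np.abs(g - dac_quantize(g, b)).max() for b in (2, 4, 8)}
    assert errors[4] <= 1 / 30 + 1e-12
    assert errors[8] <= errors[4] <= errors[2]


def test_dac_out_of_range_clipped_and_logged():
    log = {}
    out = dac_quantize(np.array([-0.2, 0.5, 1.7]), 4, saturation_log=log)
    assert out[0] == 0.0 and out[2] == 1.0
    assert log["clipped"] == 2


# --------------------------------------------------------------------- MAC

def test_mac_single_weight_passthrough():
    assert mac(np.array([1.0]), np.array([0.5])) == pytest.approx(0.5)


def test_mac_bounded_for_any_inputs(rng):
    for _ in range(100):
        n = rng.integers(1, 10)
        w = rng.normal(size=n)
        x = rng.uniform(-1, 1, size=n)
        b = float(rng.normal())
        assert abs(mac(w, x, b)) <= 1.0 + 1e-12


def test_mac_matches_brute_force(rng):
    for _ in range(200):
        n = int(rng.integers(1, 9))
        w = rng.normal(size=n)
        x = rng.uniform(-1, 1, size=n)
        want = sum(wi * xi for wi, xi in zip(w, x)) / sum(abs(wi) for wi in w)
        assert mac(w, x) == pytest.approx(want, abs=1e-12)


def test_mac_all_zero_weights_error():
    with pytest.raises(ValueError):
        mac(np.zeros(3), np.ones(3))


# -------------------------------------------------------------- activations

def test_activation_odd_symmetry_at_defaults():
    act = characterize_activation("tanh", gain=1.0)
    assert act(np.array([0.0]))[0] == pytest.approx(0.0, abs=1e-12)


def test_activation_monotone_over_grid():
    for kind in ("tanh", "sigmoid"):
        act = characterize_activation(kind, gain=3.0, offset=0.05, sat_lo=-0.9 if kind == "tanh" else 0.05, sat_hi=0.95)
        assert np.all(np.diff(act.table) >= 0)


def test_lookup_matches_closed_form_tanh():
    act = characterize_activation("tanh", gain=2.0)
    x = np.linspace(-1, 1, 4001)
    assert np.abs(act(x) - np.tanh(2 * x)).max() < 1e-4


def test_sigmoid_kind_output_within_unit_interval():
    act = characterize_activation("sigmoid", gain=4.0)
    x = np.linspace(-1, 1, 1001)
    out = act(x)
    assert out.min() >= 0.0 and out.max() <= 1.0


def test_non_monotone_table_rejected():
    from sepsisfuse.analog import ActivationModel

    with pytest.raises(ValueError):
        ActivationModel("tanh", np.linspace(-1, 1, 5), np.array([0, 1, 0.5, 1, 1]))


def test_mismatch_zero_is_repeatable(rng):
    act = characterize_activation("tanh", gain=2.0, mismatch_sd=0.0)
    inst = act.instance(rng)
    assert inst is act


# ----------------------------------------------------------------- forward

def _reference_dense_forward(weights, biases, X):
    """Independent plain-numpy dense network (tanh hidden, sigmoid out)."""
    A = X
    for i, (W, b) in enumerate(zip(weights, biases)):
        Z = A @ W.T + b
        A = 1 / (1 + np.exp(-Z)) if i == len(weights) - 1 else np.tanh(Z)
    return A[:, 0]


def test_ideal_forward_matches_reference_oracle(rng):
    ann = AnalogANN(mode="ideal").init_weights(3)
    for _ in range(100):
        X = rng.normal(size=(5, 14))
        want = _reference_dense_forward(ann.weights, ann.biases, X)
        got = ann.forward(X)
        assert np.abs(got - want).max() < 1e-9


def test_constant_network_outputs_sigmoid_of_bias():
    ann = AnalogANN(layer_sizes=(14, 1), mode="ideal")
    ann.weights = [np.zeros((1, 14))]
    ann.biases = [np.array([0.7])]
    out = ann.forward(np.random.default_rng(0).normal(size=(3, 14)))
    assert np.allclose(out, 1 / (1 + np.exp(-0.7)))


def test_analog_preactivations_bounded(rng):
    ann = AnalogANN(mode="analog").init_weights(5)
    from sepsisfuse.analog import FeatureScaler

    X = rng.uniform(0, 1, size=(50, 14))
    ann.scaler = FeatureScaler.fit(X)
    _, cache = ann.forward(X, return_hidden=True)
    for layer in cache:
        assert np.all(np.abs(layer["Z"]) <= 1.0 + 1e-12)


def test_single_layer_analog_preserves_score_ordering(rng):
    """Charge-sharing normalization plus the lookup sigmoid is a monotone
    transform of the ideal affine score: on identical (quantized) inputs
    the two modes rank 100 random inputs identically."""
    from sepsisfuse.analog import FeatureScaler

    X = rng.uniform(0, 1, size=(100, 14))
    ann_a = AnalogANN(layer_sizes=(14, 1), dac_bits=16, mode="analog")
    ann_a.init_weights(7)
    ann_a.scaler = FeatureScaler.fit(X)
    ann_i = AnalogANN(layer_sizes=(14, 1), mode="ideal")
    ann_i.weights = [w.copy() for w in ann_a.weights]
    ann_i.biases = [b.copy() for b in ann_a.biases]
    X_seen = dac_quantize(ann_a.scaler.transform(X), 16)  # what the chip sees
    rho = spearmanr(ann_a.forward(X), ann_i.forward(X_seen)).statistic
    assert rho == pytest.approx(1.0, abs=1e-12)


def test_dimension_mismatch_names_layer(rng):
    ann = AnalogANN(mode="ideal").init_weights(0)
    with pytest.raises(ValueError, match="14"):
        ann.forward(rng.normal(size=(3, 9)))


def test_checkpoint_round_trip(rng):
    ann = AnalogANN(mode="ideal").init_weights(2)
    clone = AnalogANN.from_json(ann.to_json())
    X = rng.normal(size=(4, 14))
    assert np.allclose(ann.forward(X), clone.forward(X), atol=1e-12)


# ---------------------------------------------------------------- training

def _two_gaussians(rng, n=400, gap=2.5):
    X = np.vstack([
        rng.normal(0, 1, (n // 2, 14)),
        rng.normal(gap, 1, (n // 2, 14)),
    ])
    y = np.r_[np.zeros(n // 2), np.ones(n // 2)]
    return X, y


def test_training_separates_well_separated_gaussians(rng):
    X, y = _two_gaussians(rng)
    ann, report = train_error_aware(X, y, cfg=TrainConfig(epochs=200, seed=1))
    assert report["train_accuracy"].iloc[-1] >= 0.95


def test_training_is_seed_deterministic(rng):
    X, y = _two_gaussians(rng)
    ann1, _ = train_error_aware(X, y, cfg=TrainConfig(epochs=30, seed=9))
    ann2, _ = train_error_aware(X, y, cfg=TrainConfig(epochs=30, seed=9))
    for w1, w2 in zip(ann1.weights, ann2.weights):
        assert np.array_equal(w1, w2)
    for b1, b2 in zip(ann1.biases, ann2.biases):
        assert np.array_equal(b1, b2)


def test_single_class_dataset_rejected(rng):
    X = rng.normal(size=(50, 14))
    with pytest.raises(ValueError):
        train_error_aware(X, np.ones(50))


def test_ideal_training_matches_reference_backprop(rng):
    """In ideal-forward/ideal-gradient mode the trainer reproduces an
    independently coded full-batch backprop loss trajectory to 1e-6."""
    X, y = _two_gaussians(rng, n=64, gap=1.5)

    cfg = TrainConfig(epochs=5, learning_rate=0.1, batch_size=64, seed=4,
                      surrogate="ideal-gradient", split=0.99)
    ann = AnalogANN(layer_sizes=(14, 5, 1), mode="ideal").init_weights(cfg.seed)
    w0 = [w.copy() for w in ann.weights]
    b0 = [b.copy() for b in ann.biases]
    ids = np.arange(len(y)).astype(str)
    # figure out which rows the trainer will use so the reference sees
    # exactly the same batches
    from sepsisfuse.analog import patient_split

    train_mask, _ = patient_split(ids, cfg.split, cfg.seed)
    Xt, yt = X[train_mask], y[train_mask]

    # ----- independent reference implementation (full-batch SGD, BCE) ----
    def ref_losses():
        Ws = [w.copy() for w in w0]
        bs = [b.copy() for b in b0]
        losses = []
        order_rng = np.random.default_rng(cfg.seed + 1)
        for _ in range(cfg.epochs):
            idx = order_rng.permutation(len(yt))  # single full batch
            Xb, yb = Xt[idx], yt[idx]
            # forward
            As = [Xb]
            for i, (W, b) in enumerate(zip(Ws, bs)):
                Z = As[-1] @ W.T + b
                As.append(np.tanh(Z) if i < len(Ws) - 1 else 1 / (1 + np.exp(-Z)))
            s = np.clip(As[-1][:, 0], 1e-12, 1 - 1e-12)
            m = len(yb)
            delta = ((s - yb) / m)[:, None]  # dL/dZ_out for BCE + sigmoid
            for i in reversed(range(len(Ws))):
                gW = delta.T @ As[i]
                gb = delta.sum(axis=0)
                if i > 0:
                    delta = (delta @ Ws[i]) * (1 - As[i] ** 2)
                Ws[i] -= cfg.learning_rate * gW
                bs[i] -= cfg.learning_rate * gb
            # epoch-end loss on the training rows
            A = Xt
            for i, (W, b) in enumerate(zip(Ws, bs)):
                Z = A @ W.T + b
                A = np.tanh(Z) if i < len(Ws) - 1 else 1 / (1 + np.exp(-Z))
            sc = np.clip(A[:, 0], 1e-12, 1 - 1e-12)
            losses.append(-np.mean(yt * np.log(sc) + (1 - yt) * np.log(1 - sc)))
        return losses

    _, report = train_error_aware(X, y, ids, ann=ann, cfg=cfg)
    want = ref_losses()
    got = report["train_loss"].tolist()
    assert np.abs(np.asarray(got) - np.asarray(want)).max() < 1e-6


def test_error_aware_analog_close_to_ideal_on_fixed_task(rng):
    """The point of co-design: the 4-bit analog network trained through
    its own non-idealities stays within 0.05 of the ideal network's test
    accuracy on the same task and split."""
    X, y = _two_gaussians(rng, n=500, gap=2.0)
    ids = np.arange(len(y)).astype(str)
    cfg = TrainConfig(epochs=150, seed=2)
    ideal = AnalogANN(mode="ideal")
    _, rep_i = train_error_aware(X, y, ids, ann=ideal, cfg=cfg)
    analog = AnalogANN(mode="analog", dac_bits=4)
    _, rep_a = train_error_aware(X, y, ids, ann=analog, cfg=cfg)
    assert rep_a["test_accuracy"].iloc[-1] >= rep_i["test_accuracy"].iloc[-1] - 0.05
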