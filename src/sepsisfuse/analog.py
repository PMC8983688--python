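"""Simulator of the on-sensor analog classifier and its error-aware training.

The hardware being modelled computes a small dense network
(14 → 20 → 6 → 1) entirely in the analog domain: features enter through
4-bit switched-capacitor DACs, each neuron performs its weighted sum by
passive charge sharing on capacitors (which physically computes a
capacitance-weighted average, so every pre-activation is bounded to
[−1, 1]), and activation functions are realized by 5-transistor amplifier
stages whose transfer curves only approximate ideal tanh/sigmoid.

The simulator exposes two modes:

* ``analog`` — quantized inputs, charge-sharing-normalized MACs, and
  lookup-table activations built from a parametric amplifier transfer
  family; this is the path deployed inference takes.
* ``ideal`` — exact affine pre-activations with exact tanh/sigmoid; used
  as the mathematical reference.

Error-aware training runs gradient descent *through* the analog forward
path (straight-through quantization, piecewise-linear lookup derivatives),
so the trained weights compensate for the hardware's non-idealities
instead of being surprised by them at deployment.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ecg import FEATURE_NAMES

__all__ = [
    "ActivationModel",
    "AnalogANN",
    "TrainConfig",
    "dac_quantize",
    "mac",
    "characterize_activation",
    "train_error_aware",
    "sweep_table",
]

_GRID_POINTS = 257


def dac_quantize(
    x: np.ndarray | float, bits: int = 4, saturation_log: dict | None = None
) -> np.ndarray:
    """Quantize values in [0, 1] to the nearest of ``2^bits`` uniform levels.

    Levels are ``k/(2^bits − 1)``; rounding is deterministic half-up.
    Out-of-range inputs are clipped and counted in ``saturation_log``.
    """
    x = np.asarray(x, dtype=np.float64)
    n_sat = int(np.count_nonzero((x < 0) | (x > 1)))
    if saturation_log is not None:
        saturation_log["clipped"] = saturation_log.get("clipped", 0) + n_sat
    x = np.clip(x, 0.0, 1.0)
    levels = (1 << bits) - 1
    return np.floor(x * levels + 0.5) / levels


def mac(weights: np.ndarray, inputs: np.ndarray, bias: float | None = None) -> float:
    """Charge-sharing multiply-accumulate for one neuron.

    Passive charge redistribution over the weight capacitors computes the
    capacitance-normalized sum ``Σ w·x / (Σ|w| + |b|)`` (the bias acts as
    an extra input tied to 1), which is bounded to [−1, 1] for inputs in
    [−1, 1] by the triangle inequality.
    """
    w = np.asarray(weights, dtype=np.float64)
    x = np.asarray(inputs, dtype=np.float64)
    total = float(np.abs(w).sum()) + (abs(bias) if bias is not None else 0.0)
    if total == 0.0:
        raise ValueError("all-zero weights: charge-sharing MAC undefined")
    num = float(w @ x) + (bias if bias is not None else 0.0)
    return num / total


@dataclass
class ActivationModel:
    """Monotone lookup-table activation with linear interpolation.

    ``grid``/``table`` sample the amplifier's transfer curve on a uniform
    grid over [−1, 1].  ``mismatch_sd`` models per-instance input-referred
    offset spread; 0 gives perfectly repeatable instances.
    """

    kind: str  # "tanh" | "sigmoid"
    grid: np.ndarray
    table: np.ndarray
    params: dict = field(default_factory=dict)
    mismatch_sd: float = 0.0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        self.table = np.asarray(self.table, dtype=np.float64)
        if self.kind not in ("tanh", "sigmoid"):
            raise ValueError(f"unknown activation kind {self.kind!r}")
        if np.any(np.diff(self.table) < -1e-12):
            raise ValueError("activation transfer table must be non-decreasing")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.interp(x, self.grid, self.table)

    def derivative(self, x: np.ndarray) -> np.ndarray:
        """Piecewise-linear surrogate derivative from the lookup table."""
        x = np.asarray(x, dtype=np.float64)
        slopes = np.diff(self.table) / np.diff(self.grid)
        idx = np.clip(np.searchsorted(self.grid, x, side="right") - 1, 0, slopes.size - 1)
        return slopes[idx]

    def instance(self, rng: np.random.Generator) -> "ActivationModel":
        """A per-neuron instance with a random input-referred offset."""
        if self.mismatch_sd == 0:
            return self
        off = float(rng.normal(0.0, self.mismatch_sd))
        return ActivationModel(
            kind=self.kind,
            grid=self.grid,
            table=np.interp(self.grid + off, self.grid, self.table),
            params={**self.params, "instance_offset": off},
            mismatch_sd=0.0,
        )


def characterize_activation(
    kind: str,
    gain: float = 2.0,
    offset: float = 0.0,
    sat_lo: float | None = None,
    sat_hi: float | None = None,
    mismatch_sd: float = 0.0,
    grid_points: int = _GRID_POINTS,
) -> ActivationModel:
    """Build an :class:`ActivationModel` from the parametric amplifier family.

    For tanh-kind: ``f(x) = sat_lo + (sat_hi − sat_lo)·(tanh(gain·(x+offset))+1)/2``
    with saturation defaults ±1 (reducing to ``tanh(gain·x)`` at defaults);
    the sigmoid-kind analogue uses the logistic function with saturation
    defaults 0/1.  This parametric characterization stands in for a
    circuit-level (SPICE) characterization of the amplifier.
    """
    if gain <= 0:
        raise ValueError("gain must be > 0")
    if sat_lo is None:
        sat_lo = -1.0 if kind == "tanh" else 0.0
    if sat_hi is None:
        sat_hi = 1.0
    if sat_lo >= sat_hi:
        raise ValueError("sat_lo must be < sat_hi")
    grid = np.linspace(-1.0, 1.0, grid_points)
    if kind == "tanh":
        core = (np.tanh(gain * (grid + offset)) + 1.0) / 2.0
    elif kind == "sigmoid":
        core = 1.0 / (1.0 + np.exp(-gain * (grid + offset)))
    else:
        raise ValueError(f"unknown activation kind {kind!r}")
    table = sat_lo + (sat_hi - sat_lo) * core
    return ActivationModel(
        kind=kind,
        grid=grid,
        table=table,
        params={"gain": gain, "offset": offset, "sat_lo": sat_lo, "sat_hi": sat_hi},
        mismatch_sd=mismatch_sd,
    )


@dataclass
class FeatureScaler:
    """Min-max scaler fitted on training rows; the DAC input range is
    fixed hardware, so test-time values are clipped to [0, 1]."""

    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "FeatureScaler":
        lo = X.min(axis=0)
        hi = X.max(axis=0)
        hi = np.where(hi == lo, lo + 1.0, hi)  # constant column guard
        return cls(lo=lo, hi=hi)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.clip((X - self.lo) / (self.hi - self.lo), 0.0, 1.0)


@dataclass
class AnalogANN:
    """The simulated on-chip classifier."""

    layer_sizes: tuple[int, ...] = (14, 20, 6, 1)
    weights: list[np.ndarray] = field(default_factory=list)
    biases: list[np.ndarray] = field(default_factory=list)
    hidden_activation: ActivationModel = field(
        default_factory=lambda: characterize_activation("tanh")
    )
    output_activation: ActivationModel = field(
        default_factory=lambda: characterize_activation("sigmoid")
    )
    dac_bits: int = 4
    mode: str = "analog"  # "analog" | "ideal"
    use_bias: bool = True
    scaler: FeatureScaler | None = None
    saturation_log: dict = field(default_factory=dict)

    def init_weights(self, seed: int = 0) -> "AnalogANN":
        rng = np.random.default_rng(seed)
        self.weights = []
        self.biases = []
        for n_in, n_out in zip(self.layer_sizes[:-1], self.layer_sizes[1:]):
            bound = math.sqrt(6.0 / (n_in + n_out))
            self.weights.append(rng.uniform(-bound, bound, size=(n_out, n_in)))
            self.biases.append(rng.uniform(-0.1, 0.1, size=n_out))
        return self

    # --- forward passes ------------------------------------------------

    def _activation_for_layer(self, layer: int) -> ActivationModel:
        last = len(self.weights) - 1
        return self.output_activation if layer == last else self.hidden_activation

    def _mac_layer(self, A: np.ndarray, layer: int) -> np.ndarray:
        """Vectorized charge-sharing MAC for one layer; rows are samples."""
        W, b = self.weights[layer], self.biases[layer]
        denom = np.abs(W).sum(axis=1)
        if self.use_bias:
            denom = denom + np.abs(b)
        if np.any(denom == 0):
            raise ValueError(f"layer {layer}: neuron with all-zero weights")
        num = A @ W.T + (b if self.use_bias else 0.0)
        return num / denom

    def forward(self, X: np.ndarray, return_hidden: bool = False):
        """Scores in [0, 1] for a batch of raw feature rows.

        Analog mode scales features to [0, 1], quantizes them through the
        DACs, and runs normalized MACs with lookup activations (asserting
        every pre-activation stays in [−1, 1]); ideal mode computes exact
        affine pre-activations with exact tanh/sigmoid.
        """
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.layer_sizes[0]:
            raise ValueError(
                f"input layer expects {self.layer_sizes[0]} features, got {X.shape[1]}"
            )
        if not self.weights:
            raise ValueError("network weights not initialized")
        cache: list[dict] = []
        A = self.scaler.transform(X) if self.scaler is not None else X
        if self.mode == "analog":
            A = dac_quantize(A, self.dac_bits, self.saturation_log)
        for layer in range(len(self.weights)):
            act = self._activation_for_layer(layer)
            if self.mode == "analog":
                Z = self._mac_layer(A, layer)
                if not np.all((Z >= -1.0 - 1e-12) & (Z <= 1.0 + 1e-12)):
                    raise AssertionError(
                        f"layer {layer}: analog pre-activation escaped [-1, 1]"
                    )
                A_next = act(Z)
            else:
                W, b = self.weights[layer], self.biases[layer]
                Z = A @ W.T + (b if self.use_bias else 0.0)
                if act.kind == "tanh":
                    A_next = np.tanh(Z)
                else:
                    A_next = 1.0 / (1.0 + np.exp(-Z))
            cache.append({"A_in": A, "Z": Z})
            A = A_next
        scores = A[:, 0]
        if return_hidden:
            return scores, cache
        return scores

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)

    # --- persistence ----------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "layer_sizes": list(self.layer_sizes),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "dac_bits": self.dac_bits,
            "mode": self.mode,
            "use_bias": self.use_bias,
            "hidden_activation": {"kind": "tanh", **self.hidden_activation.params},
            "output_activation": {"kind": "sigmoid", **self.output_activation.params},
            "scaler": None
            if self.scaler is None
            else {"lo": self.scaler.lo.tolist(), "hi": self.scaler.hi.tolist()},
            "feature_names": list(FEATURE_NAMES),
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "AnalogANN":
        d = json.loads(text)
        hid = d["hidden_activation"]
        out = d["output_activation"]
        ann = cls(
            layer_sizes=tuple(d["layer_sizes"]),
            weights=[np.asarray(w) for w in d["weights"]],
            biases=[np.asarray(b) for b in d["biases"]],
            hidden_activation=characterize_activation(
                "tanh", gain=hid["gain"], offset=hid["offset"],
                sat_lo=hid["sat_lo"], sat_hi=hid["sat_hi"],
            ),
            output_activation=characterize_activation(
                "sigmoid", gain=out["gain"], offset=out["offset"],
                sat_lo=out["sat_lo"], sat_hi=out["sat_hi"],
            ),
            dac_bits=d["dac_bits"],
            mode=d["mode"],
            use_bias=d["use_bias"],
        )
        if d["scaler"] is not None:
            ann.scaler = FeatureScaler(
                lo=np.asarray(d["scaler"]["lo"]), hi=np.asarray(d["scaler"]["hi"])
            )
        return ann


@dataclass(frozen=True)
class TrainConfig:
    split: float = 0.8
    epochs: int = 200
    learning_rate: float = 0.5
    batch_size: int = 32
    seed: int = 0
    surrogate: str = "lookup-gradient"  # or "ideal-gradient"

    def __post_init__(self) -> None:
        if not 0 < self.split < 1:
            raise ValueError("split must be in (0, 1)")
        if self.surrogate not in ("lookup-gradient", "ideal-gradient"):
            raise ValueError(f"unknown surrogate {self.surrogate!r}")


def _ideal_derivative(kind: str, Z: np.ndarray, A: np.ndarray) -> np.ndarray:
    if kind == "tanh":
        return 1.0 - A**2
    return A * (1.0 - A)


def patient_split(
    patient_ids: np.ndarray, split: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean train/test row masks from a patient-level random split.

    Splitting at the patient (not window) level prevents windows of one
    patient from leaking across the partition.
    """
    ids = np.asarray(patient_ids)
    unique = np.unique(ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(unique)
    n_train = int(round(split * unique.size))
    train_set = set(perm[:n_train].tolist())
    train_mask = np.asarray([p in train_set for p in ids])
    return train_mask, ~train_mask


def train_error_aware(
    X: np.ndarray,
    y: np.ndarray,
    patient_ids: np.ndarray | None = None,
    ann: AnalogANN | None = None,
    cfg: TrainConfig = TrainConfig(),
    masks: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[AnalogANN, pd.DataFrame]:
    """Error-aware co-design training of the analog classifier.

    The forward pass runs the *deployed* analog path (DAC quantization,
    charge-sharing MAC normalization, lookup-table activations); the
    backward pass uses straight-through quantization and the lookup
    table's piecewise-linear derivative, so gradients flow through the
    same non-idealities inference will see.  Binary cross-entropy loss,
    mini-batch SGD, 80/20 patient-level split.  Fully deterministic given
    ``cfg.seed``.

    Returns the trained network and a per-epoch report with train/test
    accuracy and loss.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if np.unique(y).size < 2:
        raise ValueError("training requires both classes present")
    if patient_ids is None:
        patient_ids = np.arange(len(y)).astype(str)
    if ann is None:
        ann = AnalogANN()
    if not ann.weights:
        ann.init_weights(cfg.seed)

    if masks is not None:
        train_mask, test_mask = masks
    else:
        train_mask, test_mask = patient_split(np.asarray(patient_ids), cfg.split, cfg.seed)
    X_tr, y_tr = X[train_mask], y[train_mask]
    X_te, y_te = X[test_mask], y[test_mask]
    if ann.mode == "analog" and ann.scaler is None:
        ann.scaler = FeatureScaler.fit(X_tr)

    rng = np.random.default_rng(cfg.seed + 1)
    rows = []
    n = len(y_tr)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            _sgd_step(ann, X_tr[idx], y_tr[idx], cfg)
        tr_scores = ann.forward(X_tr)
        te_scores = ann.forward(X_te) if len(y_te) else np.asarray([])
        rows.append(
            {
                "epoch": epoch,
                "train_loss": _bce(y_tr, tr_scores),
                "train_accuracy": float(np.mean((tr_scores >= 0.5) == y_tr)),
                "test_accuracy": float(np.mean((te_scores >= 0.5) == y_te))
                if len(y_te)
                else np.nan,
            }
        )
    report = pd.DataFrame(rows)
    report.attrs["train_mask"] = train_mask
    report.attrs["test_mask"] = test_mask
    return ann, report


def _bce(y: np.ndarray, s: np.ndarray) -> float:
    s = np.clip(s, 1e-12, 1.0 - 1e-12)
    return float(-np.mean(y * np.log(s) + (1 - y) * np.log(1 - s)))


def _sgd_step(ann: AnalogANN, Xb: np.ndarray, yb: np.ndarray, cfg: TrainConfig) -> None:
    scores, cache = ann.forward(Xb, return_hidden=True)
    m = len(yb)
    s = np.clip(scores, 1e-12, 1.0 - 1e-12)

    n_layers = len(ann.weights)
    # dL/dA for the output activation column
    grad_A = ((s - yb) / (s * (1 - s)))[:, None] / m
    for layer in reversed(range(n_layers)):
        act = ann._activation_for_layer(layer)
        Z = cache[layer]["Z"]
        A_in = cache[layer]["A_in"]
        A_out = act(Z) if ann.mode == "analog" else (
            np.tanh(Z) if act.kind == "tanh" else 1.0 / (1.0 + np.exp(-Z))
        )
        if ann.mode == "analog" and cfg.surrogate == "lookup-gradient":
            dAdZ = act.derivative(Z)
        else:
            dAdZ = _ideal_derivative(act.kind, Z, A_out)
        grad_Z = grad_A * dAdZ

        W, b = ann.weights[layer], ann.biases[layer]
        if ann.mode == "analog":
            denom = np.abs(W).sum(axis=1)
            if ann.use_bias:
                denom = denom + np.abs(b)
            # z_i = n_i / D_i with D_i = Σ|w| (+|b|): the denominator also
            # depends on the weights through |w|.
            gW = (grad_Z.T @ A_in - (grad_Z * Z).sum(axis=0)[:, None] * np.sign(W)) / denom[:, None]
            if ann.use_bias:
                gb = (grad_Z.sum(axis=0) - (grad_Z * Z).sum(axis=0) * np.sign(b)) / denom
            grad_A = (grad_Z / denom) @ W
        else:
            gW = grad_Z.T @ A_in
            if ann.use_bias:
                gb = grad_Z.sum(axis=0)
            grad_A = grad_Z @ W
        ann.weights[layer] = W - cfg.learning_rate * gW
        if ann.use_bias:
            ann.biases[layer] = b - cfg.learning_rate * gb


def sweep_table(results: list[dict], axis: str) -> pd.DataFrame:
    """Tidy one-axis sweep results (plot-ready)."""
    df = pd.DataFrame(results)
    df.attrs["axis"] = axis
    return df.sort_values(axis).reset_index(drop=True)
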