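"""Stacked denoising autoencoder with a logistic-regression head.

Each layer is a tied-weight denoising autoencoder: the input is
corrupted (masking noise or additive Gaussian), encoded through
z = sigmoid(W x + b) and reconstructed through x' = sigmoid(W^T z + b'),
trained by full-batch gradient descent on the mean squared
reconstruction error against the CLEAN input. Layers are pretrained
greedily: layer k+1 trains on the clean encodings of layer k. After
pretraining the decoders are dropped; a single sigmoid output unit
S(V.z + c) is stacked on the top-layer features and the whole network
is fine-tuned by full-batch backpropagation (cross-entropy by default,
squared error optionally).

All randomness flows through one numpy Generator seeded from the
config, so identical configs produce bit-identical models.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .errors import (
    DivergenceError,
    InvalidArgumentError,
    InvalidLabelError,
    ShapeError,
)

logger = logging.getLogger(__name__)


def sigmoid(t):
    """Numerically stable logistic function 1/(1+exp(-t))."""
    t = np.asarray(t, dtype=np.float64)
    out = np.empty_like(t)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    e = np.exp(t[~pos])
    out[~pos] = e / (1.0 + e)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class CorruptionSpec:
    """How to corrupt inputs before encoding.

    kind='masking': each component is independently set to 0 with
    probability ``level`` (level in [0, 1]).
    kind='gaussian': i.i.d. N(0, level^2) is added (level >= 0).
    """

    kind: str = "masking"
    level: float = 0.3

    def __post_init__(self):
        if self.kind not in ("masking", "gaussian"):
            raise InvalidArgumentError(f"unknown corruption kind {self.kind!r}")
        if self.kind == "masking" and not (0.0 <= self.level <= 1.0):
            raise InvalidArgumentError("masking level must be in [0, 1]")
        if self.kind == "gaussian" and self.level < 0:
            raise InvalidArgumentError("gaussian level must be >= 0")


def corrupt(x: np.ndarray, spec: CorruptionSpec, rng: np.random.Generator) -> np.ndarray:
    """Apply the corruption described by ``spec``; deterministic given rng state."""
    x = np.asarray(x, dtype=np.float64)
    if spec.level == 0.0 and spec.kind == "masking":
        return x.copy()
    if spec.kind == "masking":
        keep = rng.random(x.shape) >= spec.level
        return x * keep
    return x + rng.normal(0.0, spec.level, size=x.shape)


@dataclass
class DAELayer:
    """Tied-weight denoising autoencoder layer.

    W: (n_hidden, n_visible) encoder weights; the decoder weight is
    always W^T and never stored. b: encoder bias; b_prime: decoder bias
    (None once the decoder has been dropped).
    """

    W: np.ndarray
    b: np.ndarray
    b_prime: np.ndarray | None = None

    @property
    def n_hidden(self) -> int:
        return self.W.shape[0]

    @property
    def n_visible(self) -> int:
        return self.W.shape[1]


def encode(layer: DAELayer, x: np.ndarray) -> np.ndarray:
    """z = sigmoid(W x + b); x may be a vector or an (n, n_visible) batch."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape[-1] != layer.n_visible:
        raise ShapeError(f"expected visible dim {layer.n_visible}, got {x.shape[-1]}")
    return sigmoid(x @ layer.W.T + layer.b)


def decode(layer: DAELayer, z: np.ndarray) -> np.ndarray:
    """x' = sigmoid(W^T z + b'), the tied-weight reconstruction."""
    z = np.asarray(z, dtype=np.float64)
    if z.shape[-1] != layer.n_hidden:
        raise ShapeError(f"expected hidden dim {layer.n_hidden}, got {z.shape[-1]}")
    if layer.b_prime is None:
        raise InvalidArgumentError("decoder bias has been dropped from this layer")
    return sigmoid(z @ layer.W + layer.b_prime)


def reconstruction_loss(layer: DAELayer, x_clean: np.ndarray, x_tilde: np.ndarray) -> float:
    """Mean over the batch of (1/2)||x - x'||^2 with x' = decode(encode(x_tilde))."""
    x_clean = np.atleast_2d(x_clean)
    x_tilde = np.atleast_2d(x_tilde)
    xp = decode(layer, encode(layer, x_tilde))
    diff = xp - x_clean
    return float(0.5 * np.einsum("ij,ij->", diff, diff) / x_clean.shape[0])


def dae_gradients(
    layer: DAELayer, x_clean: np.ndarray, x_tilde: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradients of the mean batch reconstruction error.

    Loss = (1/n) sum_d (1/2)||x_d - x'_d||^2. The W gradient carries both
    the encoder path and the tied decoder path. Returns (gW, gb, gb_prime).
    """
    x_clean = np.atleast_2d(np.asarray(x_clean, dtype=np.float64))
    x_tilde = np.atleast_2d(np.asarray(x_tilde, dtype=np.float64))
    if x_clean.shape != x_tilde.shape:
        raise ShapeError("clean and corrupted batches must share a shape")
    n = x_clean.shape[0]
    if n == 0:
        raise InvalidArgumentError("empty batch")

    z = encode(layer, x_tilde)                # (n, nh)
    xp = decode(layer, z)                     # (n, nv)
    delta_u = (xp - x_clean) * xp * (1.0 - xp)        # d loss / d preact of decoder
    delta_z = delta_u @ layer.W.T                     # (n, nh)
    delta_a = delta_z * z * (1.0 - z)                 # d loss / d preact of encoder

    gW = (delta_a.T @ x_tilde + z.T @ delta_u) / n    # encoder path + tied decoder path
    gb = delta_a.mean(axis=0)
    gb_prime = delta_u.mean(axis=0)
    return gW, gb, gb_prime


@dataclass
class TrainConfig:
    """Hyperparameters for pretraining and fine-tuning.

    Defaults follow the package's synthetic 28x28 experiment: two
    encoding layers [256, 64], masking corruption at level 0.3, a 0.1
    learning rate and 400 full-batch epochs for each stage.
    """

    hidden_sizes: tuple[int, ...] = (256, 64)
    alpha: float = 0.5
    epochs_pretrain: int = 1000
    epochs_finetune: int = 10000
    corruption: CorruptionSpec = field(default_factory=CorruptionSpec)
    finetune_loss: str = "cross_entropy"
    seed: int = 0
    # plateau-restart protocol: full-batch descent through saturating
    # sigmoids sometimes never leaves the ln(2) plateau; retraining from a
    # derived seed is deterministic optimizer hygiene, not extra data
    max_restarts: int = 4
    plateau_loss: float = 0.2
    min_train_accuracy: float = 0.85

    def __post_init__(self):
        if isinstance(self.corruption, dict):
            self.corruption = CorruptionSpec(**self.corruption)
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if len(self.hidden_sizes) < 1 or any(h < 1 for h in self.hidden_sizes):
            raise InvalidArgumentError("hidden_sizes must be non-empty positive ints")
        if self.alpha <= 0:
            raise InvalidArgumentError("alpha must be > 0")
        if self.finetune_loss not in ("cross_entropy", "squared_error"):
            raise InvalidArgumentError(f"unknown finetune_loss {self.finetune_loss!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden_sizes"] = list(self.hidden_sizes)
        return d


@dataclass
class SDAEClassifier:
    """Pretrained encoder stack plus sigmoid logistic-regression head."""

    layers: list[DAELayer]
    V: np.ndarray  # (n_top,)
    c: float

    def features(self, x: np.ndarray) -> np.ndarray:
        """Top-layer feature description Z^L of the input."""
        z = np.asarray(x, dtype=np.float64)
        for layer in self.layers:
            z = encode(layer, z)
        return z

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        z = self.features(x)
        return sigmoid(z @ self.V + self.c)

    def predict(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Probability of malignancy and hard label (>= 0.5 -> malignant)."""
        p = np.atleast_1d(self.predict_proba(x))
        return p, (p >= 0.5).astype(int)


def init_layer(n_visible: int, n_hidden: int, rng: np.random.Generator) -> DAELayer:
    """Uniform(-r, r) weights with r = sqrt(6/(fan_in+fan_out)); zero biases."""
    r = np.sqrt(6.0 / (n_visible + n_hidden))
    W = rng.uniform(-r, r, size=(n_hidden, n_visible))
    return DAELayer(W=W, b=np.zeros(n_hidden), b_prime=np.zeros(n_visible))


def pretrain_layer(
    data: np.ndarray,
    n_hidden: int,
    config: TrainConfig,
    rng: np.random.Generator,
) -> tuple[DAELayer, list[float]]:
    """Train one DAE layer by full-batch gradient descent.

    Corruption is resampled every epoch; the loss trace records each
    epoch's pre-update reconstruction error. Raises DivergenceError if
    the loss turns non-finite.
    """
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    if data.shape[0] == 0:
        raise InvalidArgumentError("empty training batch")
    layer = init_layer(data.shape[1], n_hidden, rng)
    trace: list[float] = []
    for epoch in range(config.epochs_pretrain):
        x_tilde = corrupt(data, config.corruption, rng)
        loss = reconstruction_loss(layer, data, x_tilde)
        if not np.isfinite(loss):
            raise DivergenceError(epoch, "pretraining")
        trace.append(loss)
        gW, gb, gbp = dae_gradients(layer, data, x_tilde)
        layer.W -= config.alpha * gW
        layer.b -= config.alpha * gb
        layer.b_prime -= config.alpha * gbp
    return layer, trace


def pretrain_stack(
    data: np.ndarray, config: TrainConfig
) -> tuple[SDAEClassifier, list[list[float]]]:
    """Greedy layer-wise pretraining.

    Layer k+1 trains on the CLEAN (uncorrupted) encodings of layer k.
    Decoder biases are kept during pretraining and dropped from the
    returned model; the head is zero-initialised (untrained).
    """
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    rng = np.random.default_rng(config.seed)
    layers: list[DAELayer] = []
    traces: list[list[float]] = []
    current = data
    for n_hidden in config.hidden_sizes:
        layer, trace = pretrain_layer(current, n_hidden, config, rng)
        current = encode(layer, current)
        layer.b_prime = None
        layers.append(layer)
        traces.append(trace)
    model = SDAEClassifier(layers=layers, V=np.zeros(config.hidden_sizes[-1]), c=0.0)
    return model, traces


def _finetune_loss_and_grads(
    model: SDAEClassifier, data: np.ndarray, labels: np.ndarray, loss_kind: str
):
    """Full forward/backward pass; returns (loss, grads per layer, gV, gc)."""
    n = data.shape[0]
    acts = [data]
    z = data
    for layer in model.layers:
        z = encode(layer, z)
        acts.append(z)
    logits = z @ model.V + model.c
    y = sigmoid(logits)

    eps = 1e-12
    t = labels
    if loss_kind == "cross_entropy":
        loss = float(-np.mean(t * np.log(y + eps) + (1 - t) * np.log(1 - y + eps)))
        delta = (y - t) / n                       # d loss / d logit, mean form
    else:
        loss = float(0.5 * np.mean((t - y) ** 2))
        delta = (y - t) * y * (1.0 - y) / n

    gV = acts[-1].T @ delta
    gc = float(delta.sum())
    d_z = np.outer(delta, model.V)
    layer_grads: list[tuple[np.ndarray, np.ndarray]] = []
    for k in range(len(model.layers) - 1, -1, -1):
        zk = acts[k + 1]
        d_a = d_z * zk * (1.0 - zk)
        gW = d_a.T @ acts[k]
        gb = d_a.sum(axis=0)
        layer_grads.append((gW, gb))
        if k > 0:
            d_z = d_a @ model.layers[k].W
    layer_grads.reverse()
    return loss, layer_grads, gV, gc


def finetune(
    model: SDAEClassifier,
    data: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig,
) -> list[float]:
    """Supervised full-batch fine-tuning of the whole network in place.

    The head (V, c) starts at zero, so with epochs_finetune=0 every
    prediction is exactly 0.5. Labels must be in {0, 1} (1 = malignant).
    Returns the per-epoch loss trace.
    """
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    labels = np.asarray(labels, dtype=np.float64).ravel()
    if data.shape[0] != labels.size:
        raise ShapeError("data and labels length mismatch")
    if not np.all(np.isin(labels, (0.0, 1.0))):
        raise InvalidLabelError("labels must be 0 (benign) or 1 (malignant)")
    model.V = np.zeros(model.layers[-1].n_hidden)
    model.c = 0.0
    trace: list[float] = []
    for epoch in range(config.epochs_finetune):
        loss, layer_grads, gV, gc = _finetune_loss_and_grads(
            model, data, labels, config.finetune_loss
        )
        if not np.isfinite(loss):
            raise DivergenceError(epoch, "fine-tuning")
        trace.append(loss)
        for layer, (gW, gb) in zip(model.layers, layer_grads):
            layer.W -= config.alpha * gW
            layer.b -= config.alpha * gb
        model.V -= config.alpha * gV
        model.c -= config.alpha * gc
    return trace


def train_classifier(
    data: np.ndarray, labels: np.ndarray, config: TrainConfig
) -> tuple[SDAEClassifier, dict]:
    """Pretrain the stack, then fine-tune with labels.

    If fine-tuning fails to leave the chance-level plateau (final loss
    above ``plateau_loss`` or training accuracy below
    ``min_train_accuracy``), the whole procedure restarts from a seed
    derived deterministically from the configured one, up to
    ``max_restarts`` attempts; the last attempt is returned regardless.
    """
    labels = np.asarray(labels).ravel()
    attempts = max(1, config.max_restarts)
    model = None
    traces: dict = {}
    for k in range(attempts):
        # late restarts shed pretraining: on low-variance inputs the
        # reconstruction objective can collapse the features into
        # saturation, and fine-tuning from a fresh random init is then
        # the only full-batch route off the plateau
        if k < 2:
            ep_pt = config.epochs_pretrain
        elif k == 2:
            ep_pt = config.epochs_pretrain // 4
        else:
            ep_pt = 0
        cfg_k = replace(config, seed=config.seed + 1000 * k, epochs_pretrain=ep_pt)
        model, pretrain_traces = pretrain_stack(data, cfg_k)
        finetune_trace = finetune(model, data, labels, cfg_k)
        traces = {
            "pretrain": pretrain_traces,
            "finetune": finetune_trace,
            "restarts": k,
        }
        if config.epochs_finetune == 0:
            break
        _, pred = model.predict(data)
        train_acc = float((pred == labels).mean())
        if finetune_trace[-1] < config.plateau_loss and train_acc >= config.min_train_accuracy:
            break
        logger.info(
            "training stuck near the plateau (loss %.3f, train acc %.3f); restart %d",
            finetune_trace[-1], train_acc, k + 1,
        )
    return model, traces


FORMAT_VERSION = 1


def save_model(path, model: SDAEClassifier, config: TrainConfig | None = None) -> None:
    """Serialise a model to a single .npz archive with JSON metadata."""
    arrays = {}
    for k, layer in enumerate(model.layers):
        arrays[f"W_{k}"] = layer.W
        arrays[f"b_{k}"] = layer.b
    arrays["V"] = model.V
    arrays["c"] = np.asarray(model.c)
    meta = {
        "format_version": FORMAT_VERSION,
        "n_layers": len(model.layers),
        "hidden_sizes": [l.n_hidden for l in model.layers],
        "config": config.to_dict() if config is not None else None,
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path) -> tuple[SDAEClassifier, dict]:
    """Load a model archive written by :func:`save_model`."""
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta_json"]).decode())
        layers = [
            DAELayer(W=npz[f"W_{k}"], b=npz[f"b_{k}"], b_prime=None)
            for k in range(meta["n_layers"])
        ]
        model = SDAEClassifier(layers=layers, V=npz["V"], c=float(npz["c"]))
    return model, meta
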