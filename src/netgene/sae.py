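"""Stacked autoencoder for compressing embedding features.

The encoder maps inputs through a strictly decreasing stack of
nonlinear layers (e.g. 512-256-128-64); the decoder mirrors it, ending
in a linear output layer.  Training minimizes the summed squared
reconstruction error  sum_i ||xhat_i - x_i||^2  by plain SGD, optionally
after greedy layer-wise pretraining (each stage trained as a shallow
autoencoder on the previous stage's codes — the historical meaning of
"stacked").  The bottleneck codes are the reduced features used
downstream.

Inputs are standardized per-feature by default so the squared loss is
scale-free; statistics are stored on the model and reapplied at encode
time, which keeps train/test separation clean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .embedding import Embedding

__all__ = ["SAEConfig", "SAEModel", "train_sae", "encode", "reconstruction_loss",
           "sae_loss_and_grads"]


@dataclass
class SAEConfig:
    """Stacked-autoencoder hyperparameters.

    ``layer_dims`` runs input -> ... -> bottleneck and must be strictly
    decreasing with at least two entries, e.g. ``[512, 256, 128, 64]``.
    Hidden activation is tanh by default (odd, zero-centred — matched to
    standardized inputs); sigmoid is available.  The output layer is
    always linear.
    """

    layer_dims: list[int] = field(default_factory=lambda: [512, 256, 128, 64])
    activation: str = "tanh"  # {"tanh", "sigmoid"}
    epochs: int = 100
    learning_rate: float = 0.01
    pretrain: bool = True
    standardize: bool = True
    batch_size: int = 128  # used only above the full-batch cutoff
    full_batch_max_n: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        dims = list(self.layer_dims)
        if len(dims) < 2:
            raise ValueError("layer_dims needs at least input and bottleneck")
        if any(b >= a for a, b in zip(dims, dims[1:])):
            raise ValueError("layer_dims must be strictly decreasing")
        if self.activation not in ("tanh", "sigmoid"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("epochs >= 1 and learning_rate > 0 required")


@dataclass
class SAEModel:
    """Trained encoder/decoder weights plus input-standardization state."""

    layer_dims: list[int]
    activation: str
    weights: list[np.ndarray]   # encoder then decoder, in forward order
    biases: list[np.ndarray]
    mean_: np.ndarray | None
    scale_: np.ndarray | None
    loss_history: list[float] = field(default_factory=list)
    pretrain_history: list[list[float]] = field(default_factory=list)

    @property
    def input_dim(self) -> int:
        return self.layer_dims[0]

    @property
    def bottleneck_dim(self) -> int:
        return self.layer_dims[-1]

    @property
    def n_encoder_layers(self) -> int:
        return len(self.layer_dims) - 1

    def save(self, path) -> None:
        np.savez(
            path,
            layer_dims=np.asarray(self.layer_dims),
            activation=np.asarray(self.activation),
            mean=self.mean_ if self.mean_ is not None else np.array([]),
            scale=self.scale_ if self.scale_ is not None else np.array([]),
            **{f"W{i}": w for i, w in enumerate(self.weights)},
            **{f"b{i}": b for i, b in enumerate(self.biases)},
        )

    @classmethod
    def load(cls, path) -> "SAEModel":
        z = np.load(path, allow_pickle=False)
        dims = [int(d) for d in z["layer_dims"]]
        n_layers = 2 * (len(dims) - 1)
        mean = z["mean"] if z["mean"].size else None
        scale = z["scale"] if z["scale"].size else None
        return cls(
            layer_dims=dims,
            activation=str(z["activation"]),
            weights=[z[f"W{i}"] for i in range(n_layers)],
            biases=[z[f"b{i}"] for i in range(n_layers)],
            mean_=mean,
            scale_=scale,
        )


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    return np.tanh(z) if kind == "tanh" else expit(z)


def _act_deriv(a: np.ndarray, kind: str) -> np.ndarray:
    # derivative expressed through the activation value
    return 1.0 - a * a if kind == "tanh" else a * (1.0 - a)


def _forward(Ws, bs, kind: str, X: np.ndarray) -> list[np.ndarray]:
    """Activations per layer; every layer nonlinear except the last (linear)."""
    acts = [X]
    h = X
    for li, (W, b) in enumerate(zip(Ws, bs)):
        z = h @ W.T + b
        h = z if li == len(Ws) - 1 else _act(z, kind)
        acts.append(h)
    return acts


def sae_loss_and_grads(Ws, bs, kind: str, X: np.ndarray):
    """Loss sum_i ||out_i - x_i||^2 and its analytic parameter gradients.

    Shared by SGD training and the finite-difference gradient check.
    """
    acts = _forward(Ws, bs, kind, X)
    out = acts[-1]
    diff = out - X
    loss = float((diff * diff).sum())
    gWs = [np.zeros_like(W) for W in Ws]
    gbs = [np.zeros_like(b) for b in bs]
    delta = 2.0 * diff  # linear output layer
    for li in range(len(Ws) - 1, -1, -1):
        gWs[li] = delta.T @ acts[li]
        gbs[li] = delta.sum(axis=0)
        if li > 0:
            delta = (delta @ Ws[li]) * _act_deriv(acts[li], kind)
    return loss, gWs, gbs


def _init_layer(rng: np.random.Generator, fan_out: int, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_out, fan_in))


def _sgd(Ws, bs, kind, X, epochs, lr, batch_size, full_batch_max_n, rng):
    n = X.shape[0]
    history: list[float] = []
    full = n <= full_batch_max_n
    for _ in range(epochs):
        if full:
            loss, gWs, gbs = sae_loss_and_grads(Ws, bs, kind, X)
            for W, gW in zip(Ws, gWs):
                W -= lr * gW / n
            for b, gb in zip(bs, gbs):
                b -= lr * gb / n
            history.append(loss / n)
        else:
            order = rng.permutation(n)
            total = 0.0
            for lo in range(0, n, batch_size):
                idx = order[lo : lo + batch_size]
                loss, gWs, gbs = sae_loss_and_grads(Ws, bs, kind, X[idx])
                m = idx.size
                for W, gW in zip(Ws, gWs):
                    W -= lr * gW / m
                for b, gb in zip(bs, gbs):
                    b -= lr * gb / m
                total += loss
            history.append(total / n)
    return history


def train_sae(features: np.ndarray, config: SAEConfig) -> SAEModel:
    """Train a stacked autoencoder on ``features`` (n x input_dim).

    With ``pretrain=True`` each encoder stage is first trained as a
    shallow autoencoder on the codes of the previous stage, then the
    full mirrored network is fine-tuned end to end.  Deterministic under
    a fixed seed.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("features must be a 2-D matrix with n >= 2 rows")
    if X.shape[1] != config.layer_dims[0]:
        raise ValueError(
            f"feature width {X.shape[1]} != layer_dims[0] {config.layer_dims[0]}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature entries")
    rng = np.random.default_rng(config.seed)

    mean = scale = None
    if config.standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale < 1e-12, 1.0, scale)
        X = (X - mean) / scale

    dims = list(config.layer_dims)
    kind = config.activation
    enc_W = [_init_layer(rng, dims[i + 1], dims[i]) for i in range(len(dims) - 1)]
    enc_b = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
    dec_W = [_init_layer(rng, dims[i], dims[i + 1]) for i in range(len(dims) - 2, -1, -1)]
    dec_b = [np.zeros(dims[i]) for i in range(len(dims) - 2, -1, -1)]

    pretrain_history: list[list[float]] = []
    if config.pretrain:
        H = X
        for i in range(len(dims) - 1):
            Ws = [enc_W[i], dec_W[len(dims) - 2 - i]]
            bs = [enc_b[i], dec_b[len(dims) - 2 - i]]
            hist = _sgd(
                Ws, bs, kind, H, config.epochs, config.learning_rate,
                config.batch_size, config.full_batch_max_n, rng,
            )
            pretrain_history.append(hist)
            H = _act(H @ Ws[0].T + bs[0], kind)

    Ws = enc_W + dec_W
    bs = enc_b + dec_b
    history = _sgd(
        Ws, bs, kind, X, config.epochs, config.learning_rate,
        config.batch_size, config.full_batch_max_n, rng,
    )
    return SAEModel(
        layer_dims=dims,
        activation=kind,
        weights=Ws,
        biases=bs,
        mean_=mean,
        scale_=scale,
        loss_history=history,
        pretrain_history=pretrain_history,
    )


def _standardize(model: SAEModel, X: np.ndarray) -> np.ndarray:
    if model.mean_ is None:
        return X
    return (X - model.mean_) / model.scale_


def encode(model: SAEModel, features: np.ndarray) -> np.ndarray:
    """Bottleneck codes for ``features``; a row-wise map."""
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.input_dim:
        raise ValueError(f"expected width {model.input_dim}, got {X.shape}")
    h = _standardize(model, X)
    for li in range(model.n_encoder_layers):
        h = _act(h @ model.weights[li].T + model.biases[li], model.activation)
    return h


def reconstruct(model: SAEModel, features: np.ndarray) -> np.ndarray:
    """Decoder output mapped back to the original feature units."""
    X = np.asarray(features, dtype=np.float64)
    acts = _forward(model.weights, model.biases, model.activation, _standardize(model, X))
    out = acts[-1]
    if model.mean_ is not None:
        out = out * model.scale_ + model.mean_
    return out


def reconstruction_loss(model: SAEModel, features: np.ndarray) -> float:
    """sum_i ||xhat_i - x_i||^2 in original feature units; 0 iff perfect."""
    X = np.asarray(features, dtype=np.float64)
    if X.shape[1] != model.input_dim:
        raise ValueError(f"expected width {model.input_dim}, got {X.shape}")
    diff = reconstruct(model, X) - X
    return float((diff * diff).sum())


def encode_embedding(model: SAEModel, emb: Embedding) -> Embedding:
    """Convenience: SAE-compress a whole Embedding, preserving metadata."""
    return Embedding(
        nodes=list(emb.nodes),
        vectors=encode(model, emb.vectors),
        visited=emb.visited.copy() if emb.visited is not None else None,
    )
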