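"""A symmetric feed-forward autoencoder for document embedding.

The encoder stacks four hidden layers tapering down to a low-dimensional
bottleneck; the decoder mirrors them back up to the input dimension.  Hidden
layers use relu (configurable); the bottleneck and output layers are linear.
Training minimizes the mean squared reconstruction error

    Loss(y, y') = sum_i (y_i - y'_i)^2 / n

where i indexes samples, y_i is the input row, y'_i its reconstruction and n
the sample size (so each term is the squared Euclidean norm of one row's
residual).  Optimization is adaptive-moment gradient descent (Adam) with the
default coefficients learning_rate 1e-4, beta1 0.9, beta2 0.999, epsilon
1e-8, run for ``epochs`` x ``steps_per_epoch`` optimizer steps over shuffled
mini-batches of ``batch_size`` rows.  Everything is seeded and runs on plain
numpy, so training is exactly reproducible.

The bottleneck activations of the trained encoder are the document
embeddings handed to clustering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, DivergenceError

_ACTIVATIONS = ("relu", "sigmoid", "tanh")


@dataclass
class AutoencoderConfig:
    input_dim: int
    hidden_dims: tuple[int, ...] = (1024, 512, 128, 64)
    bottleneck_dim: int = 32
    learning_rate: float = 0.0001
    batch_size: int = 7
    steps_per_epoch: int = 300
    epochs: int = 100
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    activation: str = "relu"
    seed: int = 0
    early_stopping: bool = False
    patience: int = 10
    min_delta: float = 1e-6

    def validate(self) -> None:
        if self.input_dim < 1 or self.bottleneck_dim < 1:
            raise ConfigurationError("input_dim and bottleneck_dim must be positive")
        dims = tuple(self.hidden_dims)
        if any(d < 1 for d in dims):
            raise ConfigurationError("hidden dims must be positive")
        if any(a <= b for a, b in zip(dims, dims[1:])):
            raise ConfigurationError("hidden_dims must be strictly decreasing")
        if dims and dims[-1] <= self.bottleneck_dim:
            raise ConfigurationError("hidden_dims must all exceed bottleneck_dim")
        for name in ("learning_rate", "batch_size", "steps_per_epoch", "epochs"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("beta1", "beta2"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1)")
        if self.activation not in _ACTIVATIONS:
            raise ConfigurationError(f"activation must be one of {_ACTIVATIONS}")


@dataclass
class EmbeddingMatrix:
    doc_ids: list[str]
    vectors: np.ndarray  # rows of dimension bottleneck_dim


@dataclass
class LossHistory:
    per_epoch: list[float] = field(default_factory=list)


def _act(name, z):
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    return np.tanh(z)


def _act_grad(name, a):
    # expressed in terms of the activation output a
    if name == "relu":
        return (a > 0.0).astype(a.dtype)
    if name == "sigmoid":
        return a * (1.0 - a)
    return 1.0 - a * a


def mse_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean over samples of the squared reconstruction error."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("y and y' must have identical shapes")
    if y.ndim == 1:
        y, y_hat = y[None, :], y_hat[None, :]
    return float(((y - y_hat) ** 2).sum(axis=1).mean())


class AutoencoderModel:
    """Weights plus forward passes.  ``layer_dims`` chains
    input -> hidden... -> bottleneck -> mirrored hidden... -> input; hidden
    layers are activated, the bottleneck and the output are linear."""

    def __init__(self, config: AutoencoderConfig, rng: np.random.Generator):
        config.validate()
        self.config = config
        dims = (
            [config.input_dim]
            + list(config.hidden_dims)
            + [config.bottleneck_dim]
            + list(reversed(config.hidden_dims))
            + [config.input_dim]
        )
        self.layer_dims = dims
        self.n_encoder = len(config.hidden_dims) + 1  # layers up to the bottleneck
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    def _linear_layers(self):
        # indices of layers with linear output: bottleneck and final
        return {self.n_encoder - 1, len(self.weights) - 1}

    def _forward(self, X: np.ndarray) -> list[np.ndarray]:
        """Return the list of layer outputs, input first."""
        acts = [X]
        linear = self._linear_layers()
        a = X
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            a = z if i in linear else _act(self.config.activation, z)
            acts.append(a)
        return acts

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(X, dtype=float))[-1]

    def encode_rows(self, X: np.ndarray) -> np.ndarray:
        a = np.asarray(X, dtype=float)
        linear = self._linear_layers()
        for i in range(self.n_encoder):
            z = a @ self.weights[i] + self.biases[i]
            a = z if i in linear else _act(self.config.activation, z)
        return a

    def save(self, outdir) -> None:
        """Checkpoint: JSON manifest (config, dims, version) + npz weights."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {"format_version": 1, "config": asdict(self.config),
                    "layer_dims": self.layer_dims}
        (outdir / "model.json").write_text(json.dumps(manifest, indent=2))
        arrays = {}
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        np.savez(outdir / "weights.npz", **arrays)

    @classmethod
    def load(cls, indir) -> "AutoencoderModel":
        indir = Path(indir)
        manifest = json.loads((indir / "model.json").read_text())
        cfg_dict = manifest["config"]
        cfg_dict["hidden_dims"] = tuple(cfg_dict["hidden_dims"])
        config = AutoencoderConfig(**cfg_dict)
        model = cls(config, np.random.default_rng(0))
        blob = np.load(indir / "weights.npz")
        for i in range(len(model.weights)):
            model.weights[i] = blob[f"W{i}"]
            model.biases[i] = blob[f"b{i}"]
        return model


def _as_rows(matrix) -> tuple[list[str], np.ndarray]:
    if hasattr(matrix, "weights"):  # DocTermMatrix
        return list(matrix.doc_ids), matrix.toarray()
    if hasattr(matrix, "vectors"):  # EmbeddingMatrix
        return list(matrix.doc_ids), np.asarray(matrix.vectors, dtype=float)
    X = np.asarray(matrix, dtype=float)
    return [str(i) for i in range(X.shape[0])], X


def train_autoencoder(matrix, config: AutoencoderConfig):
    """Train on the rows of ``matrix`` and return ``(model, LossHistory)``.

    Mini-batches are drawn from a per-epoch reshuffled cyclic stream, so each
    epoch performs exactly ``steps_per_epoch`` Adam steps regardless of corpus
    size.  Raises :class:`DivergenceError` on a non-finite epoch loss.
    """
    config.validate()
    _, X = _as_rows(matrix)
    if X.shape[1] != config.input_dim:
        raise ConfigurationError(
            f"matrix has {X.shape[1]} columns but config.input_dim={config.input_dim}"
        )
    if X.shape[0] < config.batch_size:
        raise ConfigurationError("need at least batch_size rows to train")

    rng = np.random.default_rng(config.seed)
    model = AutoencoderModel(config, rng)
    m_w = [np.zeros_like(W) for W in model.weights]
    v_w = [np.zeros_like(W) for W in model.weights]
    m_b = [np.zeros_like(b) for b in model.biases]
    v_b = [np.zeros_like(b) for b in model.biases]
    linear = model._linear_layers()
    act_name = config.activation

    n = X.shape[0]
    order = rng.permutation(n)
    cursor = 0
    t = 0
    history = LossHistory()
    best = np.inf
    stale = 0
    for epoch in range(config.epochs):
        epoch_losses = np.empty(config.steps_per_epoch)
        for step in range(config.steps_per_epoch):
            if cursor + config.batch_size > n:
                order = rng.permutation(n)
                cursor = 0
            batch_idx = order[cursor : cursor + config.batch_size]
            cursor += config.batch_size
            B = X[batch_idx]

            acts = model._forward(B)
            resid = acts[-1] - B
            epoch_losses[step] = (resid**2).sum(axis=1).mean()

            # backprop: dL/d(output) for loss = mean_rows ||resid||^2
            delta = 2.0 * resid / config.batch_size
            t += 1
            lr_t = config.learning_rate * (
                np.sqrt(1.0 - config.beta2**t) / (1.0 - config.beta1**t)
            )
            for i in range(len(model.weights) - 1, -1, -1):
                a_prev = acts[i]
                gW = a_prev.T @ delta
                gb = delta.sum(axis=0)
                if i > 0:
                    delta = delta @ model.weights[i].T
                    if (i - 1) not in linear:
                        delta = delta * _act_grad(act_name, acts[i])
                for g, mm, vv, param in (
                    (gW, m_w[i], v_w[i], model.weights[i]),
                    (gb, m_b[i], v_b[i], model.biases[i]),
                ):
                    mm *= config.beta1
                    mm += (1.0 - config.beta1) * g
                    vv *= config.beta2
                    vv += (1.0 - config.beta2) * g * g
                    param -= lr_t * mm / (np.sqrt(vv) + config.epsilon)
        epoch_loss = float(epoch_losses.mean())
        if not np.isfinite(epoch_loss):
            raise DivergenceError(epoch)
        history.per_epoch.append(epoch_loss)
        if config.early_stopping:
            if epoch_loss < best - config.min_delta:
                best = epoch_loss
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
    return model, history


def encode(model: AutoencoderModel, matrix) -> EmbeddingMatrix:
    """Map rows through the encoder half only; deterministic given the model."""
    doc_ids, X = _as_rows(matrix)
    if X.shape[1] != model.config.input_dim:
        raise ConfigurationError(
            f"matrix has {X.shape[1]} columns but model expects {model.config.input_dim}"
        )
    return EmbeddingMatrix(doc_ids=doc_ids, vectors=model.encode_rows(X))


def reconstruction_loss(model: AutoencoderModel, matrix) -> float:
    """Mean squared reconstruction error of ``matrix`` under ``model``."""
    _, X = _as_rows(matrix)
    if X.shape[1] != model.config.input_dim:
        raise ConfigurationError("dimension mismatch")
    return mse_loss(X, model.reconstruct(X))


def save_embeddings(emb: EmbeddingMatrix, path) -> None:
    """TSV export with doc_id first column."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc_id, row in zip(emb.doc_ids, emb.vectors):
            fh.write(doc_id + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
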