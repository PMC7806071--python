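"""Bottleneck autoencoders over independent feature frames.

Each speaker in a dyad gets one fully-connected bottleneck autoencoder
trained to reconstruct that speaker's per-frame feature vectors (frames are
treated as i.i.d. instances; temporal structure is deliberately ignored).
Reconstruction error on the *partner's* frames then acts as a novelty
score: frames far from the training speaker's acoustic distribution
reconstruct poorly, frames close to it reconstruct well, so a downward
drift of the partner's error trace over the session indicates the partners'
feature distributions approaching each other.

The reference configuration mirrors the study setup: a 3-layer encoder with
mirrored decoder whose widths halve toward the bottleneck
(130-64-32-12-32-64-130 for delta-augmented LLDs,
4096-2048-1024-512-1024-2048-4096 for CNN spectrogram embeddings), mean
squared reconstruction error minimised by Adagrad (learning rate 0.01) with
batch size 256 for 512 epochs. Training is plain numpy with hand-written
backprop — the networks are small and the workload is CPU-bound minibatch
SGD, so no deep-learning framework is required — and is exactly
reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .features_io import FeatureSequence


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""

    def __init__(self, epoch: int):
        super().__init__(f"non-finite training loss at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class Architecture:
    """Palindromic layer sizes, input -> bottleneck -> output."""

    layer_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.layer_sizes)
        object.__setattr__(self, "layer_sizes", sizes)
        if len(sizes) < 3 or len(sizes) % 2 == 0:
            raise ValueError("architecture needs an odd number (>= 3) of layer sizes")
        if sizes != sizes[::-1]:
            raise ValueError(f"architecture must be palindromic: {sizes}")
        mid = len(sizes) // 2
        encoder = sizes[: mid + 1]
        if any(a <= b for a, b in zip(encoder, encoder[1:])):
            raise ValueError(f"sizes must strictly decrease to the bottleneck: {sizes}")
        if sizes[mid] < 1:
            raise ValueError("bottleneck must have >= 1 unit")

    @property
    def input_dim(self) -> int:
        return self.layer_sizes[0]

    @property
    def bottleneck(self) -> int:
        return self.layer_sizes[len(self.layer_sizes) // 2]


def default_architecture(input_dim: int) -> Architecture:
    """Reference bottleneck architecture for a given feature dimensionality.

    130 and 4096 inputs map to the exact reference architectures; any other
    dimensionality gets three encoder layers of floor(d/2), floor(d/4),
    floor(d/8) units, mirrored in the decoder.
    """
    if input_dim == 130:
        return Architecture((130, 64, 32, 12, 32, 64, 130))
    if input_dim == 4096:
        return Architecture((4096, 2048, 1024, 512, 1024, 2048, 4096))
    if input_dim < 8:
        raise ValueError(f"input_dim {input_dim} too small: bottleneck would be < 1")
    h1, h2, h3 = input_dim // 2, input_dim // 4, input_dim // 8
    return Architecture((input_dim, h1, h2, h3, h2, h1, input_dim))


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation hyperparameters; defaults follow the reference setup."""

    batch_size: int = 256
    epochs: int = 512
    optimizer: str = "adagrad"
    learning_rate: float = 0.01
    seed: int = 0
    loss: str = "mean_squared_error"
    hidden_activation: str = "relu"

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("batch_size, epochs >= 1 and learning_rate > 0 required")
        if self.optimizer not in ("adagrad", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.loss != "mean_squared_error":
            raise ValueError("only mean_squared_error loss is supported")
        if self.hidden_activation not in ("relu", "tanh", "linear"):
            raise ValueError(f"unknown activation {self.hidden_activation!r}")


_ACTS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z, a: (z > 0).astype(z.dtype)),
    "tanh": (np.tanh, lambda z, a: 1.0 - a * a),
    "linear": (lambda z: z, lambda z, a: np.ones_like(z)),
}


@dataclass
class TrainedAutoencoder:
    """Fitted network: weights, biases, training log and provenance."""

    architecture: Architecture
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    training_loss_curve: np.ndarray  # per-epoch mean MSE over training frames
    config: TrainingConfig
    init_scheme: str = "he_uniform"

    def reconstruct_array(self, x: np.ndarray) -> np.ndarray:
        """Forward pass on a (n, input_dim) array; no training occurs."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        if x.shape[1] != self.architecture.input_dim:
            raise ValueError(
                f"input dim {x.shape[1]} != network input {self.architecture.input_dim}"
            )
        act, _ = _ACTS[self.config.hidden_activation]
        h = x
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i < last:  # linear output layer
                h = act(h)
        return h

    def save(self, path: str | Path) -> None:
        """Persist as a single .npz archive (weights, config, loss curve)."""
        arrays = {f"w{i}": w for i, w in enumerate(self.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.biases)})
        np.savez(
            Path(path),
            layer_sizes=np.array(self.architecture.layer_sizes),
            loss_curve=self.training_loss_curve,
            n_layers=np.array([len(self.weights)]),
            cfg_batch_size=np.array([self.config.batch_size]),
            cfg_epochs=np.array([self.config.epochs]),
            cfg_lr=np.array([self.config.learning_rate]),
            cfg_seed=np.array([self.config.seed]),
            cfg_optimizer=np.array([self.config.optimizer]),
            cfg_activation=np.array([self.config.hidden_activation]),
            init_scheme=np.array([self.init_scheme]),
            **arrays,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedAutoencoder":
        with np.load(Path(path), allow_pickle=False) as z:
            n = int(z["n_layers"][0])
            cfg = TrainingConfig(
                batch_size=int(z["cfg_batch_size"][0]),
                epochs=int(z["cfg_epochs"][0]),
                optimizer=str(z["cfg_optimizer"][0]),
                learning_rate=float(z["cfg_lr"][0]),
                seed=int(z["cfg_seed"][0]),
                hidden_activation=str(z["cfg_activation"][0]),
            )
            return cls(
                architecture=Architecture(tuple(int(s) for s in z["layer_sizes"])),
                weights=[z[f"w{i}"] for i in range(n)],
                biases=[z[f"b{i}"] for i in range(n)],
                training_loss_curve=z["loss_curve"],
                config=cfg,
                init_scheme=str(z["init_scheme"][0]),
            )


def _init_params(
    arch: Architecture, rng: np.random.Generator
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """He-uniform weight init, zero biases."""
    weights, biases = [], []
    for d_in, d_out in zip(arch.layer_sizes, arch.layer_sizes[1:]):
        limit = np.sqrt(6.0 / d_in)
        weights.append(rng.uniform(-limit, limit, size=(d_in, d_out)))
        biases.append(np.zeros(d_out))
    return weights, biases


def train_autoencoder(
    frames: FeatureSequence | np.ndarray,
    arch: Optional[Architecture] = None,
    cfg: TrainingConfig = TrainingConfig(),
) -> TrainedAutoencoder:
    """Fit a bottleneck autoencoder on per-frame instances.

    Minibatch gradient descent on the mean squared reconstruction error;
    frames are reshuffled every epoch and the last partial batch is kept.
    Fully reproducible for a fixed seed and config. The per-epoch loss curve
    records the frame-weighted mean minibatch loss.
    """
    x = frames.values if isinstance(frames, FeatureSequence) else np.atleast_2d(np.asarray(frames, dtype=np.float64))
    n, d = x.shape
    if arch is None:
        arch = default_architecture(d)
    if d != arch.input_dim:
        raise ValueError(f"frame dim {d} != architecture input {arch.input_dim}")

    rng = np.random.default_rng(cfg.seed)
    weights, biases = _init_params(arch, rng)
    accum_w = [np.zeros_like(w) for w in weights]
    accum_b = [np.zeros_like(b) for b in biases]
    act, act_grad = _ACTS[cfg.hidden_activation]
    eps = 1e-10
    last = len(weights) - 1
    loss_curve = np.empty(cfg.epochs)

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, cfg.batch_size):
            batch = x[order[lo : lo + cfg.batch_size]]
            m = batch.shape[0]
            # forward
            pre: list[np.ndarray] = []
            acts = [batch]
            h = batch
            for i, (w, b) in enumerate(zip(weights, biases)):
                z = h @ w + b
                pre.append(z)
                h = act(z) if i < last else z
                acts.append(h)
            err = h - batch
            loss = float(np.mean(err * err))
            epoch_loss += loss * m
            # backward: d(mean over batch*dims of err^2)/dz
            delta = 2.0 * err / (m * d)
            for i in range(last, -1, -1):
                gw = acts[i].T @ delta
                gb = delta.sum(axis=0)
                if i > 0:  # propagate through pre-update weights
                    delta = (delta @ weights[i].T) * act_grad(pre[i - 1], acts[i])
                if cfg.optimizer == "adagrad":
                    accum_w[i] += gw * gw
                    accum_b[i] += gb * gb
                    weights[i] -= cfg.learning_rate * gw / (np.sqrt(accum_w[i]) + eps)
                    biases[i] -= cfg.learning_rate * gb / (np.sqrt(accum_b[i]) + eps)
                else:
                    weights[i] -= cfg.learning_rate * gw
                    biases[i] -= cfg.learning_rate * gb
        loss_curve[epoch] = epoch_loss / n
        if not np.isfinite(loss_curve[epoch]):
            raise DivergenceError(epoch)

    return TrainedAutoencoder(
        architecture=arch,
        weights=weights,
        biases=biases,
        training_loss_curve=loss_curve,
        config=cfg,
    )


def reconstruct(ae: TrainedAutoencoder, frames: FeatureSequence) -> FeatureSequence:
    """Reconstruct frames in order through a trained autoencoder.

    Output has identical shape, frame order and timing metadata; row ``i``
    is the deterministic forward pass of input row ``i``.
    """
    return frames.with_values(ae.reconstruct_array(frames.values), dim_names=frames.dim_names)
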