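"""Class-weight-aware deep feature learning on the 800-dim mixed g-gap vector.

Two training phases produce a 50-dim representation of each protein:

1. **Autoencoder pre-training.** A 7-layer mirrored autoencoder
   (800 -> 650 -> 500 -> 300 -> 500 -> 650 -> 800; ReLU hidden layers,
   sigmoid reconstruction layer since inputs are frequencies in [0, 1]) is
   trained jointly with Adadelta to minimize the sample-weighted mean of
   per-sample squared reconstruction error

       L(P, P') = sum_i w_i * ||P_i - P'_i||^2 / sum_i w_i.

   Positives carry weight 6 and negatives weight 1 by default, countering
   the ~6:1 class imbalance's pull on the reconstruction objective.

2. **Supervised fine-tuning.** The decoder is discarded and a fully
   connected head 300 -> 50 (tanh) -> 25 (tanh) -> 1 (sigmoid) is stacked
   on the encoder. The whole network (encoder included) is trained on the
   same 6:1 sample-weighted binary cross-entropy with mini-batch gradient
   descent (lr 0.0025, decay 1e-6, momentum 0.6, batch 12), dropout 0.2 /
   0.3 on the two hidden FC layers, and a max-norm cap of 3 on every FC
   unit's incoming-weight vector, re-applied after each update. FC weights
   initialize uniformly on [-0.05, 0.05] with zero biases.

The output of the first FC layer (50 units, dropout disabled) is the
learned representation handed to the t-SNE + SVM stage.

All of this is plain NumPy: the architecture is small enough that batched
dense matmuls on one CPU train it in seconds, and an explicit implementation
keeps the weighted-loss accounting, constraint enforcement and seeding
bit-reproducible and auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConfigError,
    DegenerateTrainingError,
    DivergenceError,
    ValidationError,
)
from .features import MIXED_DIM

logger = logging.getLogger(__name__)

__all__ = [
    "LabeledDataset",
    "AutoencoderConfig",
    "FineTuneConfig",
    "Dense",
    "FeatureLearner",
    "pretrain_autoencoder",
    "fine_tune",
    "build_fc_stack",
    "extract_representation",
    "default_sample_weights",
]

_BCE_EPS = 1e-7  # probability clip for log terms


# ---------------------------------------------------------------------------
# data container


def default_sample_weights(
    labels: np.ndarray, positive_weight: float = 6.0
) -> np.ndarray:
    """Per-sample loss weights: ``positive_weight`` for class 1, 1 for class 0."""
    labels = np.asarray(labels)
    return np.where(labels == 1, float(positive_weight), 1.0)


@dataclass
class LabeledDataset:
    """Feature matrix with binary labels and per-sample loss weights."""

    features: np.ndarray  # (n, 800)
    labels: np.ndarray  # (n,) in {0, 1}
    sample_weights: np.ndarray | None = None  # (n,) > 0; None -> 6:1 default
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2 or self.features.shape[1] != MIXED_DIM:
            raise ValidationError(
                f"features must be (n, {MIXED_DIM}), got {self.features.shape}"
            )
        if self.labels.shape != (self.features.shape[0],):
            raise ValidationError("labels must align with feature rows")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValidationError("labels must be binary 0/1")
        if self.sample_weights is None:
            self.sample_weights = default_sample_weights(self.labels)
        self.sample_weights = np.asarray(self.sample_weights, dtype=np.float64)
        if self.sample_weights.shape != self.labels.shape or np.any(
            self.sample_weights <= 0
        ):
            raise ValidationError("sample_weights must be positive, one per row")

    @property
    def n(self) -> int:
        return self.features.shape[0]


# ---------------------------------------------------------------------------
# configs


@dataclass
class AutoencoderConfig:
    """Pre-training settings; widths are the fixed mirrored architecture."""

    layer_widths: tuple[int, ...] = (800, 650, 500, 300, 500, 650, 800)
    hidden_activation: str = "relu"
    output_activation: str = "sigmoid"
    optimizer: str = "adadelta"
    adadelta_rho: float = 0.95
    adadelta_eps: float = 1e-6
    epochs: int = 100
    batch_size: int = 12
    greedy_layerwise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        w = tuple(self.layer_widths)
        half = len(w) // 2
        if w[0] != w[-1]:
            raise ConfigError("autoencoder input and output widths must match")
        if list(w[:half + 1]) != sorted(w[:half + 1], reverse=True) or len(
            set(w[:half + 1])
        ) != half + 1:
            raise ConfigError("encoder widths must strictly decrease to the bottleneck")
        if w[half:] != w[:half + 1][::-1]:
            raise ConfigError("decoder must mirror the encoder")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs and batch_size must be positive")

    @property
    def bottleneck(self) -> int:
        return self.layer_widths[len(self.layer_widths) // 2]


@dataclass
class FineTuneConfig:
    """Supervised head and optimizer settings for fine-tuning."""

    fc_widths: tuple[int, ...] = (50, 25, 1)
    fc_hidden_activation: str = "tanh"
    output_activation: str = "sigmoid"
    dropout_rates: tuple[float, ...] = (0.2, 0.3)
    max_weight_norm: float = 3.0
    learning_rate: float = 0.0025
    decay: float = 1e-6
    momentum: float = 0.6
    batch_size: int = 12
    weight_init_range: float = 0.05
    epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.fc_widths) != len(self.dropout_rates) + 1:
            raise ConfigError("need one dropout rate per hidden FC layer")
        if any(not 0 <= p < 1 for p in self.dropout_rates):
            raise ConfigError("dropout rates must lie in [0, 1)")
        if self.max_weight_norm <= 0:
            raise ConfigError("max_weight_norm must be positive")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.fc_widths[-1] != 1:
            raise ConfigError("output layer must have a single logistic node")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs and batch_size must be positive")


# ---------------------------------------------------------------------------
# layers and optimizers

_ACTIVATIONS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z, a: (z > 0).astype(z.dtype)),
    "tanh": (np.tanh, lambda z, a: 1.0 - a * a),
    "sigmoid": (
        lambda z: 0.5 * (1.0 + np.tanh(0.5 * z)),  # stable logistic
        lambda z, a: a * (1.0 - a),
    ),
    "linear": (lambda z: z, lambda z, a: np.ones_like(z)),
}


class Dense:
    """Fully connected layer ``a = act(x @ W + b)`` with cached backward pass.

    ``W`` has shape (n_in, n_out); column j is unit j's incoming-weight
    vector, which is what the max-norm constraint caps. Parameters and
    activations are float32 (ample for gradient training and twice as fast
    on one CPU); losses are reduced in float64.
    """

    def __init__(self, W: np.ndarray, b: np.ndarray, activation: str):
        if activation not in _ACTIVATIONS:
            raise ConfigError(f"unknown activation {activation!r}")
        self.W = np.asarray(W, dtype=np.float32)
        self.b = np.asarray(b, dtype=np.float32)
        self.activation = activation
        self._x = self._z = self._a = None
        self.dW = self.db = None

    @classmethod
    def glorot(cls, n_in: int, n_out: int, activation: str,
               rng: np.random.Generator) -> "Dense":
        limit = np.sqrt(6.0 / (n_in + n_out))
        W = rng.uniform(-limit, limit, size=(n_in, n_out))
        return cls(W, np.zeros(n_out, dtype=np.float32), activation)

    @classmethod
    def uniform(cls, n_in: int, n_out: int, activation: str,
                rng: np.random.Generator, half_range: float) -> "Dense":
        W = rng.uniform(-half_range, half_range, size=(n_in, n_out))
        return cls(W, np.zeros(n_out, dtype=np.float32), activation)

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        z = x @ self.W + self.b
        a = _ACTIVATIONS[self.activation][0](z)
        if cache:
            self._x, self._z, self._a = x, z, a
        return a

    def backward(self, grad: np.ndarray, wrt_preactivation: bool = False) -> np.ndarray:
        """Accumulate dW/db from upstream gradient; return gradient w.r.t. x.

        ``wrt_preactivation`` lets the loss fuse with the output activation
        (e.g. sigmoid + cross-entropy) and pass dL/dz directly.
        """
        if self._x is None:
            raise ValidationError("backward called before forward")
        if wrt_preactivation:
            dz = grad
        else:
            dz = grad * _ACTIVATIONS[self.activation][1](self._z, self._a)
        self.dW = self._x.T @ dz
        self.db = dz.sum(axis=0)
        return dz @ self.W.T

    def clip_column_norms(self, max_norm: float) -> None:
        norms = np.linalg.norm(self.W.astype(np.float64), axis=0)
        over = norms > max_norm
        if np.any(over):
            # tiny margin keeps the cap strict after float32 rounding
            factor = (max_norm / norms[over]) * (1.0 - 1e-6)
            self.W[:, over] *= factor.astype(np.float32)

    def copy(self) -> "Dense":
        return Dense(self.W.copy(), self.b.copy(), self.activation)


class _Adadelta:
    """Adadelta with running squared-gradient and squared-update averages."""

    def __init__(self, layers: list[Dense], rho: float, eps: float):
        self.rho, self.eps = rho, eps
        self.state = [
            {name: (np.zeros_like(getattr(l, name)), np.zeros_like(getattr(l, name)))
             for name in ("W", "b")}
            for l in layers
        ]
        self.layers = layers

    def step(self) -> None:
        for layer, st in zip(self.layers, self.state):
            for name in ("W", "b"):
                g = getattr(layer, "d" + name)
                Eg2, Edx2 = st[name]
                Eg2 *= self.rho
                Eg2 += (1 - self.rho) * g * g
                dx = -np.sqrt(Edx2 + self.eps) / np.sqrt(Eg2 + self.eps) * g
                Edx2 *= self.rho
                Edx2 += (1 - self.rho) * dx * dx
                getattr(layer, name).__iadd__(dx)


class _SGDMomentum:
    """Mini-batch gradient descent with momentum and 1/(1 + decay*t) schedule."""

    def __init__(self, layers: list[Dense], lr: float, decay: float, momentum: float):
        self.lr, self.decay, self.momentum = lr, decay, momentum
        self.iterations = 0
        self.velocity = [
            {name: np.zeros_like(getattr(l, name)) for name in ("W", "b")}
            for l in layers
        ]
        self.layers = layers

    def step(self) -> None:
        lr_t = self.lr / (1.0 + self.decay * self.iterations)
        for layer, vel in zip(self.layers, self.velocity):
            for name in ("W", "b"):
                g = getattr(layer, "d" + name)
                v = vel[name]
                v *= self.momentum
                v -= lr_t * g
                getattr(layer, name).__iadd__(v)
        self.iterations += 1


# ---------------------------------------------------------------------------
# losses (weighted means; oracle-checkable from model outputs)


def weighted_reconstruction_loss(
    x: np.ndarray, x_hat: np.ndarray, w: np.ndarray
) -> float:
    """``sum_i w_i * ||x_i - x'_i||^2 / sum_i w_i``."""
    diff = np.asarray(x, dtype=np.float64) - np.asarray(x_hat, dtype=np.float64)
    per_sample = np.sum(diff ** 2, axis=1)
    return float(np.sum(w * per_sample) / np.sum(w))


def weighted_cross_entropy(
    t: np.ndarray, y: np.ndarray, w: np.ndarray
) -> float:
    """Sample-weighted mean binary cross-entropy, probabilities clipped."""
    y = np.clip(np.asarray(y, dtype=np.float64).ravel(), _BCE_EPS, 1 - _BCE_EPS)
    t = np.asarray(t, dtype=np.float64).ravel()
    per_sample = -(t * np.log(y) + (1 - t) * np.log(1 - y))
    return float(np.sum(w * per_sample) / np.sum(w))


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def _forward_all(layers: list[Dense], x: np.ndarray) -> np.ndarray:
    for layer in layers:
        x = layer.forward(x, cache=False)
    return x


# ---------------------------------------------------------------------------
# phase 1: autoencoder pre-training


def _train_joint_ae(
    X: np.ndarray,
    w: np.ndarray,
    config: AutoencoderConfig,
    rng: np.random.Generator,
) -> tuple[list[Dense], list[float]]:
    widths = config.layer_widths
    layers = []
    for i in range(len(widths) - 1):
        act = (
            config.output_activation
            if i == len(widths) - 2
            else config.hidden_activation
        )
        layers.append(Dense.glorot(widths[i], widths[i + 1], act, rng))
    if config.output_activation == "sigmoid":
        # Start the reconstruction at the per-feature data means: frequency
        # vectors are sparse (mean ~1/400), and a 0.5-centred sigmoid start
        # makes every output gradient point the same way, saturating the
        # output layer before it can learn.
        mu = np.clip(X.mean(axis=0), 1e-4, 1 - 1e-4)
        layers[-1].b[:] = np.log(mu / (1 - mu)).astype(np.float32)

    n = X.shape[0]
    batch_size = min(config.batch_size, n)
    if batch_size < config.batch_size:
        logger.warning(
            "batch_size %d exceeds n=%d; clipped to %d",
            config.batch_size, n, batch_size,
        )
    opt = _Adadelta(layers, config.adadelta_rho, config.adadelta_eps)

    losses: list[float] = []
    for epoch in range(config.epochs):
        for idx in _batches(n, batch_size, rng):
            xb, wb = X[idx], w[idx]
            a = xb
            for layer in layers:
                a = layer.forward(a)
            # d/dx_hat of sum w_i ||x_i - x_hat_i||^2 / sum w_i
            grad = (2.0 * wb[:, None] * (a - xb) / np.sum(wb)).astype(np.float32)
            for layer in reversed(layers):
                grad = layer.backward(grad)
            opt.step()
        epoch_loss = weighted_reconstruction_loss(X, _forward_all(layers, X), w)
        if not np.isfinite(epoch_loss):
            raise DivergenceError("autoencoder loss diverged", epoch=epoch)
        losses.append(epoch_loss)
    return layers, losses


def _train_greedy_ae(
    X: np.ndarray,
    w: np.ndarray,
    config: AutoencoderConfig,
    rng: np.random.Generator,
) -> tuple[list[Dense], list[float]]:
    # Greedy alternative: train each encoder layer inside a shallow
    # one-hidden-layer autoencoder on the previous layer's representation.
    # The first stage reconstructs [0,1] frequencies (sigmoid output);
    # later stages reconstruct unbounded ReLU codes (linear output).
    widths = config.layer_widths
    n_enc = (len(widths) - 1) // 2
    reps = X
    encoders: list[Dense] = []
    losses: list[float] = []
    n = X.shape[0]
    batch_size = min(config.batch_size, n)
    for i in range(n_enc):
        enc = Dense.glorot(widths[i], widths[i + 1], config.hidden_activation, rng)
        out_act = config.output_activation if i == 0 else "linear"
        dec = Dense.glorot(widths[i + 1], widths[i], out_act, rng)
        pair = [enc, dec]
        opt = _Adadelta(pair, config.adadelta_rho, config.adadelta_eps)
        for epoch in range(config.epochs):
            for idx in _batches(n, batch_size, rng):
                xb, wb = reps[idx], w[idx]
                a = dec.forward(enc.forward(xb))
                grad = (2.0 * wb[:, None] * (a - xb) / np.sum(wb)).astype(np.float32)
                grad = enc.backward(dec.backward(grad))
                opt.step()
            stage_loss = weighted_reconstruction_loss(
                reps, _forward_all(pair, reps), w
            )
            if not np.isfinite(stage_loss):
                raise DivergenceError(
                    f"greedy stage {i} loss diverged", epoch=epoch
                )
            losses.append(stage_loss)
        encoders.append(enc)
        reps = enc.forward(reps, cache=False)
    return encoders, losses


def pretrain_autoencoder(
    data: LabeledDataset,
    config: AutoencoderConfig,
    return_full: bool = False,
) -> tuple[list[Dense], list[float]]:
    """Train the mirrored autoencoder; return encoder layers and loss trace.

    The loss trace holds, per epoch, the full-dataset weighted mean squared
    reconstruction error computed from a clean forward pass after that
    epoch's updates (so it is exactly reproducible from the stored model's
    own reconstructions). With ``return_full=True`` the decoder layers are
    returned as well (needed to audit the reconstruction loss).
    """
    rng = np.random.default_rng(config.seed)
    if config.greedy_layerwise:
        encoders, losses = _train_greedy_ae(
            data.features, data.sample_weights, config, rng
        )
        if return_full:
            raise ConfigError("return_full is only meaningful for joint training")
        return encoders, losses
    all_layers, losses = _train_joint_ae(
        data.features, data.sample_weights, config, rng
    )
    n_enc = (len(config.layer_widths) - 1) // 2
    if return_full:
        return all_layers, losses
    return all_layers[:n_enc], losses


# ---------------------------------------------------------------------------
# phase 2: fine-tuning and the learned representation


def build_fc_stack(
    bottleneck: int, config: FineTuneConfig, rng: np.random.Generator
) -> list[Dense]:
    """The FC head at its initial state: weights U[-r, r], biases zero."""
    fc: list[Dense] = []
    widths = (bottleneck,) + tuple(config.fc_widths)
    for i in range(len(config.fc_widths)):
        act = (
            config.output_activation
            if i == len(config.fc_widths) - 1
            else config.fc_hidden_activation
        )
        fc.append(
            Dense.uniform(widths[i], widths[i + 1], act, rng,
                          config.weight_init_range)
        )
    return fc


class FeatureLearner:
    """Trained encoder + FC head; its 50-dim layer is the representation."""

    def __init__(
        self,
        encoder_layers: list[Dense],
        fc_layers: list[Dense],
        ae_config: AutoencoderConfig,
        ft_config: FineTuneConfig,
        pretrain_losses: list[float],
        finetune_losses: list[float],
    ):
        self.encoder_layers = encoder_layers
        self.fc_layers = fc_layers
        self.ae_config = ae_config
        self.ft_config = ft_config
        self.pretrain_losses = list(pretrain_losses)
        self.finetune_losses = list(finetune_losses)

    @property
    def layers(self) -> list[Dense]:
        return self.encoder_layers + self.fc_layers

    def _check_width(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != self.encoder_layers[0].W.shape[0]:
            raise ValidationError(
                f"expected (n, {self.encoder_layers[0].W.shape[0]}) features, "
                f"got {X.shape}"
            )
        return X

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Deterministic (n, 50) representation: output of the first FC layer,
        dropout disabled."""
        X = self._check_width(X)
        a = _forward_all(self.encoder_layers, X)
        return self.fc_layers[0].forward(a, cache=False).astype(np.float64)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Logistic-output probability of the positive class, shape (n,)."""
        X = self._check_width(X)
        return _forward_all(self.layers, X).ravel().astype(np.float64)

    # -- serialization ------------------------------------------------------

    _FORMAT_VERSION = 1

    def save(self, path) -> None:
        arrays = {}
        for i, layer in enumerate(self.layers):
            arrays[f"W{i}"] = layer.W
            arrays[f"b{i}"] = layer.b
        meta = {
            "format_version": self._FORMAT_VERSION,
            "n_encoder": len(self.encoder_layers),
            "activations": [l.activation for l in self.layers],
            "ae_config": _config_dict(self.ae_config),
            "ft_config": _config_dict(self.ft_config),
            "pretrain_losses": self.pretrain_losses,
            "finetune_losses": self.finetune_losses,
        }
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        )
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)

    @classmethod
    def load(cls, path) -> "FeatureLearner":
        with np.load(path) as npz:
            meta = json.loads(bytes(npz["meta_json"]).decode())
            acts = meta["activations"]
            layers = [
                Dense(npz[f"W{i}"], npz[f"b{i}"], acts[i])
                for i in range(len(acts))
            ]
        n_enc = meta["n_encoder"]
        ae = AutoencoderConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in meta["ae_config"].items()
        })
        ft = FineTuneConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in meta["ft_config"].items()
        })
        return cls(
            layers[:n_enc], layers[n_enc:], ae, ft,
            meta["pretrain_losses"], meta["finetune_losses"],
        )


def _config_dict(cfg) -> dict:
    out = {}
    for k, v in vars(cfg).items():
        out[k] = list(v) if isinstance(v, tuple) else v
    return out


def fine_tune(
    encoder_layers: list[Dense],
    data: LabeledDataset,
    config: FineTuneConfig,
    ae_config: AutoencoderConfig | None = None,
    pretrain_losses: list[float] | None = None,
) -> FeatureLearner:
    """Supervised fine-tuning of encoder + FC head on weighted cross-entropy.

    Dropout is active only during training batches; the max-norm cap on FC
    incoming-weight columns is re-enforced after every optimizer step. The
    per-epoch loss trace is recomputed on the full dataset with dropout off.
    """
    labels = np.asarray(data.labels, dtype=np.float64)
    if len(np.unique(labels)) < 2:
        raise DegenerateTrainingError(
            "fine-tuning requires both classes present"
        )
    bottleneck = encoder_layers[-1].W.shape[1]
    rng = np.random.default_rng(config.seed)

    encoder = [l.copy() for l in encoder_layers]
    fc = build_fc_stack(bottleneck, config, rng)

    layers = encoder + fc
    n = data.n
    batch_size = min(config.batch_size, n)
    if batch_size < config.batch_size:
        logger.warning(
            "batch_size %d exceeds n=%d; clipped to %d",
            config.batch_size, n, batch_size,
        )
    opt = _SGDMomentum(layers, config.learning_rate, config.decay,
                       config.momentum)

    X, w = data.features, data.sample_weights
    n_hidden_fc = len(config.dropout_rates)
    losses: list[float] = []
    for epoch in range(config.epochs):
        for idx in _batches(n, batch_size, rng):
            xb, tb, wb = X[idx], labels[idx], w[idx]
            a = xb
            masks: list[np.ndarray | None] = []
            for li, layer in enumerate(layers):
                a = layer.forward(a)
                fc_pos = li - len(encoder)
                if 0 <= fc_pos < n_hidden_fc:
                    p = config.dropout_rates[fc_pos]
                    if p > 0:
                        mask = ((rng.random(a.shape) >= p) / (1.0 - p)).astype(np.float32)
                        a = a * mask
                        masks.append(mask)
                        continue
                masks.append(None)
            y = a.ravel()
            # fused sigmoid + weighted BCE gradient w.r.t. the output
            # pre-activation: w_i (y_i - t_i) / sum w
            grad = (((y - tb) * wb / np.sum(wb))[:, None]).astype(np.float32)
            for li in range(len(layers) - 1, -1, -1):
                if masks[li] is not None:
                    # grad arrives w.r.t. the masked output; undo the mask
                    grad = grad * masks[li]
                grad = layers[li].backward(
                    grad, wrt_preactivation=(li == len(layers) - 1)
                )
            opt.step()
            for layer in fc:
                layer.clip_column_norms(config.max_weight_norm)
        y_full = _forward_all(layers, X).ravel()
        epoch_loss = weighted_cross_entropy(labels, y_full, w)
        if not np.isfinite(epoch_loss):
            raise DivergenceError("fine-tuning loss diverged", epoch=epoch)
        losses.append(epoch_loss)

    return FeatureLearner(
        encoder_layers=encoder,
        fc_layers=fc,
        ae_config=ae_config if ae_config is not None
        else AutoencoderConfig(seed=config.seed),
        ft_config=config,
        pretrain_losses=pretrain_losses or [],
        finetune_losses=losses,
    )


def extract_representation(
    model: FeatureLearner, features: np.ndarray
) -> np.ndarray:
    """The (n, 50) learned representation: first-FC-layer output, dropout off."""
    return model.transform(features)
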