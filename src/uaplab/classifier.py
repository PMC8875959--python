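"""Small convolutional classifiers with the two initialization regimes.

Provides transfer learning (pretrain a backbone on the source pool's
surrogate texture-family task, then swap the head and fine-tune on the
target task) and training from random initialization with an epoch
multiplier. Exposes the prediction and input-gradient contracts the
attack module needs. Everything runs on the NumPy backprop core, so
training and prediction are bit-deterministic given the seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np

from . import _nn
from .exceptions import ConfigurationError, InputError, NumericalError
from .synthetic_data import ImageSet

__all__ = [
    "TrainConfig",
    "ClassifierHandle",
    "ARCHITECTURES",
    "build_model",
    "linear_classifier",
    "pretrain_backbone",
    "finetune",
    "train_scratch",
    "predict",
    "loss_gradient",
    "accuracy",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 8
    epochs_scratch_multiplier: int = 6
    learning_rate: float = 0.02
    lr_decay_every: int = 0  # 0 disables step decay
    lr_decay_factor: float = 0.5
    augment_flip: bool = False  # flips change grating orientation; off by default
    augment_shift: int = 2  # max absolute pixel shift
    freeze_features: bool = False  # finetune only: train just the new head
    augment_noise_sd: float = 0.0  # Gaussian pixel-noise augmentation
    batch_size: int = 32
    seed: int = 0
    init_mode: Literal["transfer", "scratch"] = "transfer"

    def validate(self, min_epochs: int = 1) -> None:
        if self.epochs < min_epochs:
            raise ConfigurationError(f"epochs must be >= {min_epochs}")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.epochs_scratch_multiplier < 1:
            raise ConfigurationError("epochs_scratch_multiplier must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")

    def echo(self) -> dict:
        d = self.__dict__.copy()
        if self.init_mode == "scratch":
            d["effective_epochs"] = self.epochs * self.epochs_scratch_multiplier
        else:
            d["effective_epochs"] = self.epochs
        return d


def _build_small(input_shape, n_classes, rng):
    h, w, c = input_shape
    return _nn.Sequential([
        _nn.Conv2d(c, 8, rng=rng),
        _nn.ReLU(),
        _nn.MaxPool2(),
        _nn.Conv2d(8, 16, rng=rng),
        _nn.ReLU(),
        _nn.MaxPool2(),
        _nn.Flatten(),
        _nn.Dense(16 * (h // 4) * (w // 4), n_classes, rng=rng),
    ])


def _build_medium(input_shape, n_classes, rng):
    h, w, c = input_shape
    return _nn.Sequential([
        _nn.Conv2d(c, 12, rng=rng),
        _nn.ReLU(),
        _nn.Conv2d(12, 12, rng=rng),
        _nn.ReLU(),
        _nn.MaxPool2(),
        _nn.Conv2d(12, 24, rng=rng),
        _nn.ReLU(),
        _nn.MaxPool2(),
        _nn.Flatten(),
        _nn.Dense(24 * (h // 4) * (w // 4), 48, rng=rng),
        _nn.ReLU(),
        _nn.Dense(48, n_classes, rng=rng),
    ])


def _build_linear(input_shape, n_classes, rng):
    h, w, c = input_shape
    return _nn.Sequential([_nn.Flatten(), _nn.Dense(h * w * c, n_classes, rng=rng)])


ARCHITECTURES = {"small": _build_small, "medium": _build_medium, "linear": _build_linear}


def build_model(architecture_id: str, input_shape, n_classes: int, seed: int = 0) -> _nn.Sequential:
    if architecture_id not in ARCHITECTURES:
        raise ConfigurationError(f"unknown architecture {architecture_id!r}; choose from {sorted(ARCHITECTURES)}")
    rng = np.random.default_rng(seed)
    return ARCHITECTURES[architecture_id](tuple(input_shape), n_classes, rng)


@dataclass
class ClassifierHandle:
    """A trained differentiable classifier: class prediction plus input-loss gradients."""

    model: _nn.Sequential
    n_classes: int
    input_shape: tuple[int, int, int]
    architecture_id: str
    init_mode: str
    meta: dict = field(default_factory=dict)

    def logits(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != self.input_shape:
            raise InputError(f"expected images of shape {self.input_shape}, got {x.shape[1:]}")
        if len(x) == 0:
            raise InputError("empty image batch")
        out = []
        for start in range(0, len(x), 256):
            out.append(self.model.forward(x[start : start + 256]))
        return np.concatenate(out, axis=0)


def linear_classifier(weights: np.ndarray, bias: np.ndarray, input_shape) -> ClassifierHandle:
    """Hand-built linear softmax model for oracle tests: logits = flatten(x) @ W + b."""
    h, w, c = input_shape
    model = _build_linear((h, w, c), weights.shape[1], np.random.default_rng(0))
    dense = model.layers[-1]
    if weights.shape[0] != h * w * c:
        raise InputError("weight rows must equal flattened input size")
    dense.w = np.asarray(weights, dtype=np.float64).copy()
    dense.b = np.asarray(bias, dtype=np.float64).copy()
    dense.dw = np.zeros_like(dense.w)
    dense.db = np.zeros_like(dense.b)
    return ClassifierHandle(
        model=model,
        n_classes=weights.shape[1],
        input_shape=(h, w, c),
        architecture_id="linear",
        init_mode="scratch",
    )


def _augment(x: np.ndarray, config: TrainConfig, rng: np.random.Generator) -> np.ndarray:
    if config.augment_flip:
        flips = rng.random(len(x)) < 0.5
        x = np.where(flips[:, None, None, None], x[:, :, ::-1, :], x)
    s = config.augment_shift
    if s > 0:
        x = x.copy()
        shifts = rng.integers(-s, s + 1, size=(len(x), 2))
        for i, (dy, dx_) in enumerate(shifts):
            x[i] = np.roll(x[i], (int(dy), int(dx_)), axis=(0, 1))
    if config.augment_noise_sd > 0:
        x = np.clip(x + rng.normal(0.0, config.augment_noise_sd, size=x.shape), 0.0, 1.0)
    return x


def _train(
    model: _nn.Sequential,
    images: np.ndarray,
    labels: np.ndarray,
    config: TrainConfig,
    epochs: int,
    trainable: list[_nn.Layer] | None = None,
) -> list[float]:
    layers = trainable if trainable is not None else model.layers
    params = [p for layer in layers for p in layer.params()]
    grads = [g for layer in layers for g in layer.grads()]
    rng = np.random.default_rng(config.seed)
    opt = _nn.SGD(
        params,
        lr=config.learning_rate,
        decay_every=config.lr_decay_every,
        decay_factor=config.lr_decay_factor,
    )
    history = []
    n = len(images)
    for epoch in range(epochs):
        opt.set_epoch(epoch)
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = _augment(images[idx], config, rng)
            loss, dlogits = _nn.softmax_cross_entropy(model.forward(xb), labels[idx])
            model.backward(dlogits)
            opt.step(grads)
            total += loss * len(idx)
        history.append(total / n)
    return history


def pretrain_backbone(pool: ImageSet, config: TrainConfig, architecture_id: str = "small") -> ClassifierHandle:
    """Train a backbone on the source pool's surrogate texture-family task."""
    config.validate(min_epochs=1)
    if pool.surrogate_labels is None:
        raise InputError("source pool carries no surrogate labels; regenerate with generate_source_pool")
    if len(pool) < config.batch_size:
        raise ConfigurationError("pool too small for one batch")
    n_surrogate = int(pool.surrogate_labels.max()) + 1
    model = build_model(architecture_id, pool.image_shape, n_surrogate, seed=config.seed)
    history = _train(model, pool.images, pool.surrogate_labels, config, config.epochs)
    handle = ClassifierHandle(
        model=model,
        n_classes=n_surrogate,
        input_shape=pool.image_shape,
        architecture_id=architecture_id,
        init_mode="pretrained",
        meta={"config": config.echo(), "loss_history": history, "surrogate_classes": n_surrogate},
    )
    handle.meta["surrogate_train_accuracy"] = float(
        (predict(handle, pool.images) == pool.surrogate_labels).mean()
    )
    return handle


def _replace_head(model: _nn.Sequential, n_classes: int, seed: int) -> _nn.Sequential:
    model = model.copy()
    rng = np.random.default_rng(seed + 1)
    for i in range(len(model.layers) - 1, -1, -1):
        layer = model.layers[i]
        if isinstance(layer, _nn.Dense):
            model.layers[i] = _nn.Dense(layer.w.shape[0], n_classes, rng=rng)
            return model
    raise ConfigurationError("model has no dense head to replace")


def finetune(
    backbone: ClassifierHandle,
    train: ImageSet,
    config: TrainConfig,
    test: ImageSet | None = None,
) -> ClassifierHandle:
    """Replace the classification head for the target task and fine-tune all weights."""
    config.validate(min_epochs=0)  # 0 epochs = head-swap baseline, used in tests
    if train.labels is None:
        raise InputError("training set must be labelled")
    if train.image_shape != backbone.input_shape:
        raise InputError(f"train images {train.image_shape} incompatible with backbone {backbone.input_shape}")
    n_classes = train.n_classes
    model = _replace_head(backbone.model, n_classes, config.seed)
    trainable = None
    if config.freeze_features:
        trainable = [model.layers[-1]]  # the freshly inserted head is last among Dense layers
        for i in range(len(model.layers) - 1, -1, -1):
            if isinstance(model.layers[i], _nn.Dense):
                trainable = [model.layers[i]]
                break
    history = _train(model, train.images, train.labels, config, config.epochs, trainable=trainable)
    handle = ClassifierHandle(
        model=model,
        n_classes=n_classes,
        input_shape=backbone.input_shape,
        architecture_id=backbone.architecture_id,
        init_mode="transfer",
        meta={"config": replace(config, init_mode="transfer").echo(), "loss_history": history},
    )
    if test is not None:
        handle.meta["test_accuracy"] = accuracy(handle, test)
    return handle


def train_scratch(train: ImageSet, config: TrainConfig, architecture_id: str = "small", test: ImageSet | None = None) -> ClassifierHandle:
    """Train from random initialization for epochs x multiplier."""
    config.validate(min_epochs=1)
    if train.labels is None:
        raise InputError("training set must be labelled")
    n_classes = train.n_classes
    model = build_model(architecture_id, train.image_shape, n_classes, seed=config.seed)
    epochs = config.epochs * config.epochs_scratch_multiplier
    history = _train(model, train.images, train.labels, config, epochs)
    handle = ClassifierHandle(
        model=model,
        n_classes=n_classes,
        input_shape=train.image_shape,
        architecture_id=architecture_id,
        init_mode="scratch",
        meta={"config": replace(config, init_mode="scratch").echo(), "loss_history": history},
    )
    if test is not None:
        handle.meta["test_accuracy"] = accuracy(handle, test)
    return handle


def predict(clf: ClassifierHandle, images: ImageSet | np.ndarray) -> np.ndarray:
    """Argmax class per image; ties break to the lowest class index."""
    x = images.images if isinstance(images, ImageSet) else np.asarray(images, dtype=np.float64)
    single = x.ndim == 3
    labels = np.argmax(clf.logits(x), axis=-1)
    return labels[0] if single else labels


def loss_gradient(
    clf: ClassifierHandle,
    image: np.ndarray,
    label: int,
    mode: Literal["nontargeted", "targeted"] = "nontargeted",
) -> np.ndarray:
    """Gradient of the cross-entropy loss at ``label`` w.r.t. the input image.

    For ``nontargeted`` attacks the caller passes the current predicted
    class (the loss to be increased); for ``targeted`` the target class
    (the loss to be decreased -- the sign flip lives in the attack step).
    """
    if mode not in ("nontargeted", "targeted"):
        raise InputError(f"unknown gradient mode {mode!r}")
    if not 0 <= label < clf.n_classes:
        raise InputError(f"label {label} out of range [0, {clf.n_classes})")
    x = np.asarray(image, dtype=np.float64)
    if x.shape != clf.input_shape:
        raise InputError(f"expected image of shape {clf.input_shape}, got {x.shape}")
    logits = clf.model.forward(x[None])
    _, dlogits = _nn.softmax_cross_entropy(logits, np.asarray([label]))
    grad = clf.model.backward(dlogits)[0]
    if not np.isfinite(grad).all():
        raise NumericalError("non-finite input gradient")
    return grad


def accuracy(clf: ClassifierHandle, data: ImageSet) -> float:
    if data.labels is None:
        raise InputError("accuracy requires a labelled ImageSet")
    return float((predict(clf, data) == data.labels).mean())


def save_model(clf: ClassifierHandle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(out / "weights.npz", *clf.model.params())
    sidecar = {
        "n_classes": clf.n_classes,
        "input_shape": list(clf.input_shape),
        "architecture_id": clf.architecture_id,
        "init_mode": clf.init_mode,
        "meta": {k: v for k, v in clf.meta.items() if not isinstance(v, np.ndarray)},
    }
    (out / "model.json").write_text(json.dumps(sidecar, indent=2, default=float))


def load_model(model_dir: str | Path) -> ClassifierHandle:
    model_dir = Path(model_dir)
    sidecar = json.loads((model_dir / "model.json").read_text())
    model = build_model(sidecar["architecture_id"], sidecar["input_shape"], sidecar["n_classes"], seed=0)
    with np.load(model_dir / "weights.npz") as data:
        stored = [data[k] for k in sorted(data.files, key=lambda s: int(s.split("_")[1]))]
    params = model.params()
    if len(params) != len(stored):
        raise InputError("checkpoint does not match architecture")
    for p, s in zip(params, stored):
        p[...] = s
    return ClassifierHandle(
        model=model,
        n_classes=sidecar["n_classes"],
        input_shape=tuple(sidecar["input_shape"]),
        architecture_id=sidecar["architecture_id"],
        init_mode=sidecar["init_mode"],
        meta=sidecar.get("meta", {}),
    )
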