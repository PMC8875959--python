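"""Synthetic two-domain image benchmark.

Generates a labelled "target-domain" classification dataset and an
unlabelled out-of-domain "source pool" that shares low-level statistics
with the target domain but is drawn from a shifted generative
distribution. Images are parametric textures: an oriented sinusoidal
grating per class, composited with Gaussian blobs over pixel noise, so
that convolutional features learned on one domain transfer to the other.

All generators are pure functions of (spec, seed): the same inputs yield
bit-identical arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .exceptions import ConfigurationError, InputError

__all__ = [
    "ImageSet",
    "DomainSpec",
    "ShiftSpec",
    "TextureParams",
    "default_texture_params",
    "generate_target_dataset",
    "generate_source_pool",
    "gray_transform",
]


@dataclass
class ImageSet:
    """An ordered collection of same-shape images with pixel values in [0, 1].

    ``labels`` are task labels (target domain); ``surrogate_labels`` are
    generator-side texture-family indices attached to unlabelled source
    pools so that a pretraining surrogate task can be defined without
    leaking task labels.
    """

    images: np.ndarray  # (N, H, W, C) float64 in [0, 1]
    labels: np.ndarray | None = None
    class_names: list[str] = field(default_factory=list)
    domain_tag: str = "target"
    surrogate_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        if self.images.ndim != 4:
            raise InputError(f"images must be rank-4 (N,H,W,C), got shape {self.images.shape}")
        if self.images.size and (self.images.min() < 0.0 or self.images.max() > 1.0):
            raise InputError("pixel values must lie in [0, 1]")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if len(self.labels) != len(self.images):
                raise InputError("labels length must match number of images")
            k = len(self.class_names) if self.class_names else int(self.labels.max()) + 1
            if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= k):
                raise InputError(f"labels must lie in [0, {k})")
        if self.surrogate_labels is not None:
            self.surrogate_labels = np.asarray(self.surrogate_labels, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.images)

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.images)

    @property
    def image_shape(self) -> tuple[int, int, int]:
        return tuple(self.images.shape[1:])  # type: ignore[return-value]

    @property
    def n_classes(self) -> int:
        if self.class_names:
            return len(self.class_names)
        if self.labels is not None and self.labels.size:
            return int(self.labels.max()) + 1
        raise InputError("ImageSet has no class structure")

    def save_npz(self, path: str | Path) -> None:
        payload: dict[str, np.ndarray] = {"images": self.images}
        if self.labels is not None:
            payload["labels"] = self.labels
        if self.surrogate_labels is not None:
            payload["surrogate_labels"] = self.surrogate_labels
        payload["class_names"] = np.asarray(self.class_names, dtype=np.str_)
        payload["domain_tag"] = np.asarray(self.domain_tag)
        np.savez(path, **payload)

    @classmethod
    def load_npz(cls, path: str | Path) -> "ImageSet":
        with np.load(path) as data:
            return cls(
                images=data["images"],
                labels=data["labels"] if "labels" in data else None,
                class_names=[str(c) for c in data["class_names"]],
                domain_tag=str(data["domain_tag"]),
                surrogate_labels=data["surrogate_labels"] if "surrogate_labels" in data else None,
            )


@dataclass(frozen=True)
class TextureParams:
    """Generative parameters of one texture family (one class).

    ``phase`` is a family-level constant with per-image jitter
    ``phase_jitter``: images within a family are spatially registered, the
    way clinical imaging protocols align anatomy across patients. Fully
    random phase would leave no image-agnostic adversarial direction to
    find.
    """

    orientation: float  # grating orientation, radians
    frequency: float  # cycles per image side
    phase: float = 0.0  # family-level grating phase, radians
    phase_jitter: float = 0.5  # sd of per-image phase offset
    blob_count: tuple[int, int] = (1, 4)  # inclusive range
    blob_amplitude: float = 0.10
    grating_amplitude: float = 0.12  # small margins keep the task attackable


def default_texture_params(n_classes: int) -> list[TextureParams]:
    """Evenly spread orientations with a mild frequency gradient."""
    params = []
    for k in range(n_classes):
        params.append(
            TextureParams(
                orientation=np.pi * k / n_classes,
                frequency=3.0 + 4.0 * k / max(n_classes - 1, 1),
                phase=2 * np.pi * k / n_classes,
                blob_count=(1 + k % 2, 3 + k % 3),
            )
        )
    return params


@dataclass(frozen=True)
class DomainSpec:
    n_classes: int
    n_images: int
    image_size: int = 32
    channels: int = 1
    class_balance: tuple[float, ...] | None = None
    texture_params: tuple[TextureParams, ...] | None = None
    noise_sd: float = 0.05
    seed: int = 0

    def resolved_balance(self) -> np.ndarray:
        if self.class_balance is None:
            return np.full(self.n_classes, 1.0 / self.n_classes)
        return np.asarray(self.class_balance, dtype=np.float64)

    def resolved_textures(self) -> list[TextureParams]:
        if self.texture_params is None:
            return default_texture_params(self.n_classes)
        return list(self.texture_params)

    def validate(self, labelled: bool = True) -> None:
        if self.n_classes < 1:
            raise ConfigurationError("n_classes must be >= 1")
        if self.channels not in (1, 3):
            raise ConfigurationError("channels must be 1 or 3")
        bal = self.resolved_balance()
        if len(bal) != self.n_classes:
            raise ConfigurationError("class_balance length must equal n_classes")
        if abs(bal.sum() - 1.0) > 1e-9:
            raise ConfigurationError("class_balance must sum to 1 within 1e-9")
        if (bal < 0).any():
            raise ConfigurationError("class_balance entries must be non-negative")
        if labelled and self.n_images < self.n_classes:
            raise ConfigurationError("n_images must be >= n_classes for labelled output")
        if self.n_images < 1:
            raise ConfigurationError("n_images must be >= 1")
        if len(self.resolved_textures()) != self.n_classes:
            raise ConfigurationError("texture_params length must equal n_classes")


@dataclass(frozen=True)
class ShiftSpec:
    """Displacement of the source-pool generative distribution from the target domain.

    ``mixing_weights`` control how often each texture family appears in the
    pool; biasing them is the knob that makes the pool's predicted-label
    composition imbalanced once pushed through a trained classifier.
    """

    orientation_offset: float = 0.0
    frequency_offset: float = 0.0
    mixing_weights: tuple[float, ...] | None = None
    noise_sd_offset: float = 0.0
    blob_scale: float = 1.0

    @classmethod
    def zero(cls) -> "ShiftSpec":
        return cls()

    def apply(self, params: Sequence[TextureParams]) -> list[TextureParams]:
        return [
            replace(
                p,
                orientation=p.orientation + self.orientation_offset,
                frequency=p.frequency + self.frequency_offset,
                blob_amplitude=p.blob_amplitude * self.blob_scale,
            )
            for p in params
        ]


def _render_images(
    rng: np.random.Generator,
    labels: np.ndarray,
    textures: Sequence[TextureParams],
    size: int,
    channels: int,
    noise_sd: float,
) -> np.ndarray:
    n = len(labels)
    yy, xx = np.mgrid[0:size, 0:size] / size
    out = np.empty((n, size, size, channels))
    for i, lab in enumerate(labels):
        p = textures[int(lab)]
        theta = p.orientation + rng.normal(0.0, 0.06)
        freq = p.frequency + rng.uniform(-0.5, 0.5)
        phase = p.phase + rng.normal(0.0, p.phase_jitter)
        coord = xx * np.cos(theta) + yy * np.sin(theta)
        img = 0.5 + p.grating_amplitude * np.sin(2 * np.pi * freq * coord + phase)
        lo, hi = p.blob_count
        for _ in range(int(rng.integers(lo, hi + 1))):
            cx, cy = rng.uniform(0, 1, size=2)
            sigma = rng.uniform(0.06, 0.14)
            amp = p.blob_amplitude * rng.choice([-1.0, 1.0])
            img = img + amp * np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2)))
        stack = np.repeat(img[:, :, None], channels, axis=2)
        if channels == 3:
            # mild class-dependent tint so colour carries some signal
            tint = 0.05 * np.sin(np.arange(3) + float(lab))
            stack = stack + tint[None, None, :]
        stack = stack + rng.normal(0.0, noise_sd, size=stack.shape)
        out[i] = np.clip(stack, 0.0, 1.0)
    return out


def generate_target_dataset(spec: DomainSpec, test_fraction: float = 0.5) -> tuple[ImageSet, ImageSet]:
    """Labelled target-domain dataset as independently drawn train/test sets.

    The test set holds ``round(n_images * test_fraction)`` fresh draws (not a
    partition of the training draws), with the same class balance.
    """
    spec.validate(labelled=True)
    rng = np.random.default_rng(spec.seed)
    balance = spec.resolved_balance()
    textures = spec.resolved_textures()
    class_names = [f"class_{k}" for k in range(spec.n_classes)]

    def _draw(n: int) -> ImageSet:
        labels = rng.choice(spec.n_classes, size=n, p=balance)
        images = _render_images(rng, labels, textures, spec.image_size, spec.channels, spec.noise_sd)
        return ImageSet(images=images, labels=labels, class_names=class_names, domain_tag="target")

    train = _draw(spec.n_images)
    test = _draw(max(spec.n_classes, int(round(spec.n_images * test_fraction))))
    return train, test


def generate_source_pool(spec: DomainSpec, shift: ShiftSpec | None = None) -> ImageSet:
    """Unlabelled out-of-domain pool with generator-side surrogate labels.

    The pool reuses the target domain's texture families displaced by
    ``shift``; surrogate labels record which family generated each image.
    """
    spec.validate(labelled=False)
    shift = shift or ShiftSpec.zero()
    rng = np.random.default_rng(spec.seed)
    textures = shift.apply(spec.resolved_textures())
    if shift.mixing_weights is None:
        weights = np.full(spec.n_classes, 1.0 / spec.n_classes)
    else:
        weights = np.asarray(shift.mixing_weights, dtype=np.float64)
        if len(weights) != spec.n_classes:
            raise ConfigurationError("mixing_weights length must equal n_classes")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ConfigurationError("mixing_weights must sum to 1 within 1e-9")
    families = rng.choice(spec.n_classes, size=spec.n_images, p=weights)
    noise_sd = max(spec.noise_sd + shift.noise_sd_offset, 0.0)
    images = _render_images(rng, families, textures, spec.image_size, spec.channels, noise_sd)
    return ImageSet(images=images, labels=None, class_names=[], domain_tag="source_pool", surrogate_labels=families)


def gray_transform(images: ImageSet) -> ImageSet:
    """Collapse channels to their unweighted mean, replicated back out.

    Idempotent; values stay in [0, 1].
    """
    c = images.images.shape[-1]
    if c not in (1, 3):
        raise InputError(f"unsupported channel count: {c}")
    lum = images.images.mean(axis=-1, keepdims=True)
    gray = np.repeat(lum, c, axis=-1)
    return ImageSet(
        images=gray,
        labels=None if images.labels is None else images.labels.copy(),
        class_names=list(images.class_names),
        domain_tag=images.domain_tag,
        surrogate_labels=None if images.surrogate_labels is None else images.surrogate_labels.copy(),
    )
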