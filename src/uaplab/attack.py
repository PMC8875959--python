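"""Universal adversarial perturbation (UAP) generation under an Lp budget.

Implements the iterative non-targeted and targeted UAP algorithms: start
from rho = 0, visit the input images in a seeded random order without
replacement, and for each image that is not yet fooled (non-targeted) or
not yet on-target (targeted) add a single FGSM step evaluated at the
current adversarial point, then project back onto the Lp ball of radius
xi. Random-sphere UAPs of exactly the same norm serve as controls.

The budget ``xi`` may be given directly or derived from the relative
magnitude ``zeta`` (ratio to the mean image norm of a reference set).
Perturbed images are clipped to [0, 1] whenever they are fed to the
classifier; the stored perturbation itself is not clipped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classifier import ClassifierHandle, loss_gradient, predict
from .exceptions import ConfigurationError, InputError, NumericalError
from .synthetic_data import ImageSet

__all__ = [
    "Perturbation",
    "AttackConfig",
    "lp_norm",
    "zeta_to_xi",
    "project_lp",
    "fgsm_step",
    "generate_uap_nontargeted",
    "generate_uap_targeted",
    "random_uap",
    "save_perturbation",
    "load_perturbation",
]

_BUDGET_TOL = 1e-6


def _norm_order(p) -> float:
    if p in (2, 2.0, "2"):
        return 2.0
    if p in (np.inf, float("inf"), "inf", "Inf", "INF"):
        return float("inf")
    raise ConfigurationError(f"norm order must be 2 or inf, got {p!r}")


def lp_norm(arr: np.ndarray, p) -> float:
    p = _norm_order(p)
    flat = np.asarray(arr, dtype=np.float64).ravel()
    if p == 2.0:
        return float(np.linalg.norm(flat))
    return float(np.abs(flat).max()) if flat.size else 0.0


@dataclass
class Perturbation:
    """A single UAP rho with its norm order, budget and provenance."""

    rho: np.ndarray
    p: float
    xi: float
    zeta: float | None = None
    source_tag: str = "training"  # {training, source_pool, random}
    target_class: int | None = None
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=np.float64)
        self.p = _norm_order(self.p)
        if lp_norm(self.rho, self.p) > self.xi + _BUDGET_TOL:
            raise InputError("perturbation violates its norm budget")

    @property
    def norm(self) -> float:
        return lp_norm(self.rho, self.p)


@dataclass(frozen=True)
class AttackConfig:
    epsilon: float
    p: float | str = "inf"
    zeta: float | None = None
    xi: float | None = None
    i_max: int = 1
    target_class: int | None = None
    seed: int = 0
    max_inner_iter: int = 1  # >1 enables multi-step inner attacks (non-default)

    def validate(self) -> None:
        if self.epsilon <= 0:
            raise ConfigurationError("epsilon must be > 0")
        if self.i_max < 1:
            raise ConfigurationError("i_max must be >= 1")
        if self.max_inner_iter < 1:
            raise ConfigurationError("max_inner_iter must be >= 1")
        if (self.zeta is None) == (self.xi is None):
            raise ConfigurationError("exactly one of zeta or xi must be given")
        if self.xi is not None and self.xi <= 0:
            raise ConfigurationError("xi must be > 0")
        if self.zeta is not None and self.zeta <= 0:
            raise ConfigurationError("zeta must be > 0")
        _norm_order(self.p)


def zeta_to_xi(zeta: float, reference: ImageSet, p) -> float:
    """xi = zeta x mean Lp norm of the reference images."""
    if len(reference) == 0:
        raise InputError("reference ImageSet is empty")
    if zeta < 0:
        raise InputError("zeta must be >= 0")
    norms = [lp_norm(x, p) for x in reference.images]
    return float(zeta * np.mean(norms))


def project_lp(rho: np.ndarray, xi: float, p) -> np.ndarray:
    """Project onto the Lp ball of radius xi (identity inside the ball)."""
    if xi <= 0:
        raise InputError("xi must be > 0")
    p = _norm_order(p)
    rho = np.asarray(rho, dtype=np.float64)
    if p == np.inf:
        return np.clip(rho, -xi, xi)
    n = np.linalg.norm(rho.ravel())
    if n <= xi:
        return rho.copy()
    return rho * (xi / n)


def fgsm_step(gradient: np.ndarray, epsilon: float, p, direction: str = "ascend") -> np.ndarray:
    """One fast-gradient step: eps*sign(g) for p=inf, eps*g/||g||2 for p=2."""
    if epsilon <= 0:
        raise ConfigurationError("epsilon must be > 0")
    if direction not in ("ascend", "descend"):
        raise InputError(f"direction must be ascend or descend, got {direction!r}")
    p = _norm_order(p)
    g = np.asarray(gradient, dtype=np.float64)
    if not np.isfinite(g).all():
        raise NumericalError("non-finite gradient in fgsm_step")
    if p == np.inf:
        step = epsilon * np.sign(g)
    else:
        n = np.linalg.norm(g.ravel())
        step = np.zeros_like(g) if n == 0.0 else epsilon * g / n
    return -step if direction == "descend" else step


def _resolve_xi(config: AttackConfig, reference: ImageSet) -> tuple[float, float | None]:
    if config.xi is not None:
        return float(config.xi), config.zeta
    xi = zeta_to_xi(config.zeta, reference, config.p)
    if xi <= 0:
        raise ConfigurationError("derived xi is zero; reference norms vanish")
    return xi, config.zeta


def _clip01(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 1.0)


def _check_inputs(clf: ClassifierHandle, X: ImageSet) -> None:
    if len(X) == 0:
        raise InputError("input image set is empty")
    if X.image_shape != clf.input_shape:
        raise InputError(f"images {X.image_shape} incompatible with classifier {clf.input_shape}")


def generate_uap_nontargeted(
    clf: ClassifierHandle,
    X: ImageSet,
    config: AttackConfig,
    reference: ImageSet | None = None,
) -> Perturbation:
    """Non-targeted UAP: push each not-yet-fooled image off its clean prediction.

    ``reference`` is the image set used for the zeta -> xi conversion and
    defaults to X; pass the target-domain training set when X is an
    out-of-domain pool so budgets are comparable across sources.
    """
    config.validate()
    if config.target_class is not None:
        raise ConfigurationError("non-targeted attack must not set target_class")
    _check_inputs(clf, X)
    xi, zeta = _resolve_xi(config, reference if reference is not None else X)
    p = _norm_order(config.p)
    rng = np.random.default_rng(config.seed)
    clean_pred = predict(clf, X)
    rho = np.zeros(clf.input_shape)
    n_updates = 0
    n_skipped = 0
    pass_fooling = []
    for _ in range(config.i_max):
        for idx in rng.permutation(len(X)):
            x = X.images[idx]
            for _inner in range(config.max_inner_iter):
                adv = _clip01(x + rho)
                pred = int(predict(clf, adv))
                if pred != clean_pred[idx]:
                    if _inner == 0:
                        n_skipped += 1
                    break
                g = loss_gradient(clf, adv, int(clean_pred[idx]), mode="nontargeted")
                rho = project_lp(rho + fgsm_step(g, config.epsilon, p, "ascend"), xi, p)
                n_updates += 1
        adv_pred = predict(clf, _clip01(X.images + rho))
        pass_fooling.append(float((adv_pred != clean_pred).mean()))
    return Perturbation(
        rho=rho,
        p=p,
        xi=xi,
        zeta=zeta,
        source_tag="training" if X.domain_tag == "target" else "source_pool",
        log={"pass_fooling": pass_fooling, "n_updates": n_updates, "n_skipped": n_skipped},
    )


def generate_uap_targeted(
    clf: ClassifierHandle,
    X: ImageSet,
    config: AttackConfig,
    reference: ImageSet | None = None,
) -> Perturbation:
    """Targeted UAP: pull each not-yet-on-target image toward the target class."""
    config.validate()
    y = config.target_class
    if y is None:
        raise ConfigurationError("targeted attack requires target_class")
    _check_inputs(clf, X)
    if not 0 <= y < clf.n_classes:
        raise InputError(f"target class {y} out of range [0, {clf.n_classes})")
    xi, zeta = _resolve_xi(config, reference if reference is not None else X)
    p = _norm_order(config.p)
    rng = np.random.default_rng(config.seed)
    rho = np.zeros(clf.input_shape)
    n_updates = 0
    n_skipped = 0
    pass_success = []
    for _ in range(config.i_max):
        for idx in rng.permutation(len(X)):
            x = X.images[idx]
            for _inner in range(config.max_inner_iter):
                adv = _clip01(x + rho)
                if int(predict(clf, adv)) == y:
                    if _inner == 0:
                        n_skipped += 1
                    break
                g = loss_gradient(clf, adv, y, mode="targeted")
                rho = project_lp(rho + fgsm_step(g, config.epsilon, p, "descend"), xi, p)
                n_updates += 1
        adv_pred = predict(clf, _clip01(X.images + rho))
        pass_success.append(float((adv_pred == y).mean()))
    return Perturbation(
        rho=rho,
        p=p,
        xi=xi,
        zeta=zeta,
        source_tag="training" if X.domain_tag == "target" else "source_pool",
        target_class=int(y),
        log={"pass_success": pass_success, "n_updates": n_updates, "n_skipped": n_skipped},
    )


def random_uap(shape, xi: float, p, seed: int = 0) -> Perturbation:
    """Random control perturbation with Lp norm exactly xi.

    p=2: isotropic direction (normalized Gaussian draw) scaled to xi.
    p=inf: i.i.d. uniform in [-xi, xi], rescaled so the max-abs entry is xi.
    """
    if xi <= 0:
        raise InputError("xi must be > 0")
    p = _norm_order(p)
    rng = np.random.default_rng(seed)
    if p == 2.0:
        v = rng.standard_normal(shape)
        v *= xi / np.linalg.norm(v.ravel())
    else:
        v = rng.uniform(-xi, xi, size=shape)
        v *= xi / np.abs(v).max()
    return Perturbation(rho=v, p=p, xi=float(xi), source_tag="random")


def save_perturbation(pert: Perturbation, path: str | Path) -> None:
    path = Path(path)
    np.save(path, pert.rho)
    sidecar = {
        "p": "inf" if pert.p == np.inf else 2,
        "xi": pert.xi,
        "zeta": pert.zeta,
        "source_tag": pert.source_tag,
        "target_class": pert.target_class,
        "log": pert.log,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=float))


def load_perturbation(path: str | Path) -> Perturbation:
    path = Path(path)
    rho = np.load(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return Perturbation(
        rho=rho,
        p=sidecar["p"],
        xi=sidecar["xi"],
        zeta=sidecar.get("zeta"),
        source_tag=sidecar.get("source_tag", "training"),
        target_class=sidecar.get("target_class"),
        log=sidecar.get("log", {}),
    )
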