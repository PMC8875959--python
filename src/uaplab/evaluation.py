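"""Attack performance metrics.

Fooling rate (fraction of images whose prediction changes under the
perturbation, measured against clean predictions), targeted success rate
with its clean baseline, row-normalized confusion matrices of the
clean -> adversarial prediction transition, and the predicted-label
composition of an image pool. Adversarial images are clipped to [0, 1]
before prediction, consistent with the attack module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .attack import Perturbation
from .classifier import ClassifierHandle, predict
from .exceptions import InputError
from .synthetic_data import ImageSet

__all__ = [
    "EvalReport",
    "fooling_rate",
    "success_rate",
    "confusion_matrices",
    "label_composition",
    "evaluate",
]


@dataclass
class EvalReport:
    r_f: float
    r_s: float | None
    r_s_baseline: float | None
    confusion: np.ndarray
    confusion_counts: np.ndarray
    dominant_class: int
    n_images: int
    metadata: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "r_f": self.r_f,
            "r_s": self.r_s,
            "r_s_baseline": self.r_s_baseline,
            "dominant_class": int(self.dominant_class),
            "n_images": int(self.n_images),
            "metadata": self.metadata,
        }

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(self.to_json_dict(), indent=2, default=float))
        np.savetxt(out / "confusion_counts.csv", self.confusion_counts, fmt="%d", delimiter=",")
        np.savetxt(out / "confusion_row_normalized.csv", self.confusion, delimiter=",")


def _adv_predict(clf: ClassifierHandle, X: ImageSet, pert: Perturbation) -> np.ndarray:
    if len(X) == 0:
        raise InputError("image set is empty")
    if pert.rho.shape != X.image_shape:
        raise InputError(f"perturbation shape {pert.rho.shape} incompatible with images {X.image_shape}")
    return predict(clf, np.clip(X.images + pert.rho, 0.0, 1.0))


def fooling_rate(clf: ClassifierHandle, X: ImageSet, pert: Perturbation) -> float:
    """Fraction of images whose prediction changes: compares adversarial
    predictions against clean predictions, not against true labels."""
    clean = predict(clf, X)
    adv = _adv_predict(clf, X, pert)
    return float((clean != adv).mean())


def success_rate(clf: ClassifierHandle, X: ImageSet, pert: Perturbation, y: int) -> tuple[float, float]:
    """(rate, baseline): fraction of perturbed images predicted as class y,
    and the same fraction for clean images."""
    if not 0 <= y < clf.n_classes:
        raise InputError(f"target class {y} out of range [0, {clf.n_classes})")
    clean = predict(clf, X)
    adv = _adv_predict(clf, X, pert)
    return float((adv == y).mean()), float((clean == y).mean())


def confusion_matrices(
    clf: ClassifierHandle,
    X: ImageSet,
    pert: Perturbation,
    rows: str = "clean_prediction",
) -> tuple[np.ndarray, np.ndarray, int]:
    """(counts, row_normalized, dominant_class).

    Entry (i, j) counts images with row-index class i and adversarial
    prediction j. Rows index clean predictions by default; pass
    rows="true_label" for matrices keyed by ground truth. Zero-count rows
    normalize to all-zero. dominant_class is the column with the largest
    total count, ties to the lowest index.
    """
    if rows not in ("clean_prediction", "true_label"):
        raise InputError(f"rows must be clean_prediction or true_label, got {rows!r}")
    adv = _adv_predict(clf, X, pert)
    if rows == "true_label":
        if X.labels is None:
            raise InputError("rows='true_label' requires a labelled ImageSet")
        row_idx = X.labels
    else:
        row_idx = predict(clf, X)
    k = clf.n_classes
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (row_idx, adv), 1)
    row_sums = counts.sum(axis=1, keepdims=True)
    normalized = np.divide(counts, row_sums, out=np.zeros((k, k)), where=row_sums > 0)
    dominant = int(np.argmax(counts.sum(axis=0)))
    return counts, normalized, dominant


def label_composition(clf: ClassifierHandle, pool: ImageSet) -> np.ndarray:
    """Frequency of each predicted class over the pool; sums to 1."""
    if len(pool) == 0:
        raise InputError("pool is empty")
    preds = predict(clf, pool)
    return np.bincount(preds, minlength=clf.n_classes) / len(pool)


def evaluate(
    clf: ClassifierHandle,
    X: ImageSet,
    pert: Perturbation,
    target_class: int | None = None,
    metadata: dict | None = None,
) -> EvalReport:
    """Full report: Rf, Rs (+baseline) when a target class is given, and
    the clean->adversarial confusion structure."""
    r_f = fooling_rate(clf, X, pert)
    if target_class is None and pert.target_class is not None:
        target_class = pert.target_class
    r_s = r_s_base = None
    if target_class is not None:
        r_s, r_s_base = success_rate(clf, X, pert, target_class)
    counts, normalized, dominant = confusion_matrices(clf, X, pert)
    meta = {
        "architecture_id": clf.architecture_id,
        "init_mode": clf.init_mode,
        "perturbation": {
            "p": "inf" if pert.p == np.inf else 2,
            "xi": pert.xi,
            "zeta": pert.zeta,
            "source_tag": pert.source_tag,
            "target_class": pert.target_class,
        },
    }
    if metadata:
        meta.update(metadata)
    return EvalReport(
        r_f=r_f,
        r_s=r_s,
        r_s_baseline=r_s_base,
        confusion=normalized,
        confusion_counts=counts,
        dominant_class=dominant,
        n_images=len(X),
        metadata=meta,
    )
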