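"""Evaluation metrics: global-statistics SSIM, Dice, confusion-matrix
metrics and the Proportion of Correct Patches (PCP).

The SSIM here is the *global* form — one score from the means, variances
and covariance of the two whole grids with stabilizers C1=(K1 L)^2 and
C2=(K2 L)^2 — not the sliding-window SSIM of the image-quality literature.
A windowed variant (scikit-image) is available behind a flag.

PCP is a tiling statistic: the fraction of non-overlapping patches whose
pixel agreement reaches a threshold.  The defaults (patch 16, threshold
0.9) are this package's choice; treat absolute PCP values as comparable
only under a fixed PatchSpec.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "SsimMoments",
    "PatchSpec",
    "ClassificationMetrics",
    "ssim_global",
    "ssim_moments",
    "dice_coefficient",
    "confusion_metrics",
    "proportion_correct_patches",
]


@dataclass(frozen=True)
class SsimMoments:
    mu_p: float
    mu_g: float
    var_p: float
    var_g: float
    cov_pg: float
    c1: float
    c2: float


@dataclass(frozen=True)
class PatchSpec:
    patch_size: int = 16
    correctness_threshold: float = 0.9

    def validate(self) -> None:
        if self.patch_size < 1:
            raise ValidationError("patch_size must be >= 1")
        if not 0 < self.correctness_threshold <= 1:
            raise ValidationError("correctness_threshold must be in (0, 1]")


@dataclass
class ClassificationMetrics:
    """Accuracy plus per-class precision/recall/specificity/F1.

    ``per_class`` maps each label to its one-vs-rest metrics; ``overall``
    holds the macro averages.  Ratios with a zero denominator are reported
    as 0 and the (class, metric) pair is recorded in ``undefined``.
    """

    accuracy: float
    per_class: dict
    overall: dict
    undefined: list = field(default_factory=list)


def ssim_moments(p: np.ndarray, g: np.ndarray, k1: float = 0.01, k2: float = 0.03,
                 dynamic_range: float = 1.0) -> SsimMoments:
    p = np.asarray(p, dtype=float)
    g = np.asarray(g, dtype=float)
    if p.shape != g.shape:
        raise ValidationError("grids must share shape")
    if dynamic_range <= 0:
        raise ValidationError("dynamic_range must be > 0")
    mu_p, mu_g = p.mean(), g.mean()
    var_p = p.var()
    var_g = g.var()
    cov = ((p - mu_p) * (g - mu_g)).mean()
    return SsimMoments(mu_p, mu_g, var_p, var_g, cov,
                       (k1 * dynamic_range) ** 2, (k2 * dynamic_range) ** 2)


def ssim_global(p: np.ndarray, g: np.ndarray, k1: float = 0.01, k2: float = 0.03,
                dynamic_range: float = 1.0, *, windowed: bool = False) -> float:
    """Structural similarity of two grids from their global statistics.

    Returns a value in [-1, 1].  With ``windowed=True`` delegates to
    scikit-image's sliding-window SSIM instead.
    """
    if windowed:
        from skimage.metrics import structural_similarity

        return float(structural_similarity(
            np.asarray(p, float), np.asarray(g, float),
            data_range=dynamic_range, K1=k1, K2=k2))
    m = ssim_moments(p, g, k1, k2, dynamic_range)
    num = (2 * m.mu_p * m.mu_g + m.c1) * (2 * m.cov_pg + m.c2)
    den = (m.mu_p ** 2 + m.mu_g ** 2 + m.c1) * (m.var_p + m.var_g + m.c2)
    return float(num / den)


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(arr)
    if not np.isin(a, (0, 1)).all():
        raise ValidationError(f"{name} must be binary (0/1)")
    return a.astype(bool)


def dice_coefficient(p: np.ndarray, g: np.ndarray) -> float:
    """Dice similarity 2|P∩G| / (|P|+|G|) of two binary masks.

    Both masks empty -> 1.0 (the masks agree there is nothing to segment);
    one empty, one not -> 0.0.
    """
    pb = _check_binary(p, "P")
    gb = _check_binary(g, "G")
    if pb.shape != gb.shape:
        raise ValidationError("masks must share shape")
    denom = pb.sum() + gb.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(pb, gb).sum() / denom)


def _safe_ratio(num: float, den: float, undefined: list, tag) -> float:
    if den == 0:
        undefined.append(tag)
        return 0.0
    return num / den


def confusion_metrics(predicted, truth, labels=None) -> ClassificationMetrics:
    """One-vs-rest accuracy/precision/recall/specificity/F1 per class plus
    macro averages."""
    y_pred = np.asarray(predicted).ravel()
    y_true = np.asarray(truth).ravel()
    if y_pred.shape != y_true.shape or y_true.size == 0:
        raise ValidationError("label vectors must be equal-length and non-empty")
    if labels is None:
        labels = np.unique(np.concatenate([y_true, y_pred]))
    else:
        labels = np.asarray(labels)
        known = np.isin(y_pred, labels).all() and np.isin(y_true, labels).all()
        if not known:
            raise ValidationError("labels outside the declared set")

    n = y_true.size
    accuracy = float((y_pred == y_true).mean())
    undefined: list = []
    per_class = {}
    for lab in labels:
        tp = int(np.sum((y_pred == lab) & (y_true == lab)))
        fp = int(np.sum((y_pred == lab) & (y_true != lab)))
        fn = int(np.sum((y_pred != lab) & (y_true == lab)))
        tn = n - tp - fp - fn
        precision = _safe_ratio(tp, tp + fp, undefined, (lab, "precision"))
        recall = _safe_ratio(tp, tp + fn, undefined, (lab, "recall"))
        specificity = _safe_ratio(tn, tn + fp, undefined, (lab, "specificity"))
        f1 = _safe_ratio(2 * precision * recall, precision + recall,
                         undefined, (lab, "f1"))
        per_class[lab if not isinstance(lab, np.generic) else lab.item()] = {
            "precision": precision, "recall": recall,
            "specificity": specificity, "f1": f1,
            "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        }
    overall = {
        key: float(np.mean([c[key] for c in per_class.values()]))
        for key in ("precision", "recall", "specificity", "f1")
    }
    return ClassificationMetrics(accuracy, per_class, overall, undefined)


def proportion_correct_patches(p: np.ndarray, g: np.ndarray,
                               spec: PatchSpec = PatchSpec()) -> float:
    """Fraction of non-overlapping patches whose pixel-agreement fraction
    reaches the correctness threshold.  Grids whose sides are not multiples
    of the patch size are padded with background (0) in both masks."""
    spec.validate()
    pb = _check_binary(p, "P")
    gb = _check_binary(g, "G")
    if pb.shape != gb.shape:
        raise ValidationError("masks must share shape")
    ps = spec.patch_size
    h, w = pb.shape
    ph = (-h) % ps
    pw = (-w) % ps
    if ph or pw:
        pb = np.pad(pb, ((0, ph), (0, pw)))
        gb = np.pad(gb, ((0, ph), (0, pw)))
    hh, ww = pb.shape
    agree = (pb == gb).reshape(hh // ps, ps, ww // ps, ps)
    frac = agree.mean(axis=(1, 3))
    return float((frac >= spec.correctness_threshold).mean())
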