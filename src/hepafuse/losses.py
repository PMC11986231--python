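"""The hybrid training objective: Dice + cross-entropy + SSIM losses and
their weighted sum, plus the autoencoder reconstruction loss.

Every loss accepts either plain numpy arrays (returning floats, for
evaluation) or autodiff :class:`~hepafuse._nn.Tensor` inputs (returning a
taped Tensor, for training) through the same code path, so the training
objective and the reported numbers cannot drift apart.

Conventions: the Dice loss is the soft formulation (|P∩G| = Σ P·G) so it is
differentiable; with smoothing 0 and binary inputs it reduces to the hard
Dice complement.  Cross-entropy clips probabilities at 1e-7.  The SSIM loss
is 1 minus the global-statistics SSIM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn.autodiff import Tensor
from .exceptions import ValidationError

__all__ = [
    "LossWeights",
    "LossBreakdown",
    "CE_CLIP_EPS",
    "dice_loss",
    "cross_entropy_loss",
    "ssim_loss",
    "ssim_value",
    "hybrid_loss",
    "reconstruction_loss",
]

CE_CLIP_EPS = 1e-7


@dataclass(frozen=True)
class LossWeights:
    """Weights (lambda1, lambda2, lambda3) of Dice / CE / SSIM components."""

    dice: float = 0.5
    ce: float = 0.3
    ssim: float = 0.2

    def validate(self) -> None:
        if min(self.dice, self.ce, self.ssim) < 0:
            raise ValidationError("loss weights must be non-negative")
        if self.dice + self.ce + self.ssim <= 0:
            raise ValidationError("at least one loss weight must be positive")


@dataclass
class LossBreakdown:
    dice: float
    ce: float
    ssim: float
    total: float
    intersection: float
    p_sum: float
    g_sum: float

    def as_dict(self) -> dict:
        return {"LDice": self.dice, "LCE": self.ce, "LSSIM": self.ssim,
                "total": self.total}


# -- numpy/Tensor dispatch helpers ------------------------------------------

def _is_tensor(x) -> bool:
    return isinstance(x, Tensor)

def _xsum(x):
    return x.sum() if _is_tensor(x) else np.sum(x)

def _xmean(x):
    return x.mean() if _is_tensor(x) else np.mean(x)

def _xlog(x):
    return x.log() if _is_tensor(x) else np.log(x)

def _xclip(x, lo, hi):
    return x.clip(lo, hi) if _is_tensor(x) else np.clip(x, lo, hi)

def _raw(x):
    return x.data if _is_tensor(x) else np.asarray(x)

def _scalar(x):
    return float(x.data) if _is_tensor(x) else float(x)


def _validate_pair(p, g):
    pr, gr = _raw(p), _raw(g)
    if pr.shape != gr.shape:
        raise ValidationError("prediction and target must share shape")
    if pr.size == 0:
        raise ValidationError("empty inputs")
    return pr, gr


# -- losses ------------------------------------------------------------------

def dice_loss(p, g, smoothing: float = 1e-6):
    """Soft Dice loss 1 - (2 ΣPG + eps) / (ΣP + ΣG + eps).

    ``smoothing=0`` reproduces the exact mask formulation (undefined only
    when both masks are empty); the small default keeps empty-mask batches
    finite.
    """
    pr, gr = _validate_pair(p, g)
    if pr.min() < 0 or gr.min() < 0:
        raise ValidationError("dice loss inputs must be non-negative")
    inter = _xsum(p * g)
    denom = _xsum(p) + _xsum(g)
    return 1.0 - (2.0 * inter + smoothing) / (denom + smoothing)


def cross_entropy_loss(p, g, eps: float = CE_CLIP_EPS):
    """Mean binary cross-entropy over pixels, probabilities clipped to
    [eps, 1-eps]."""
    pr, gr = _validate_pair(p, g)
    if pr.size == 0:
        raise ValidationError("cross-entropy needs at least one pixel")
    pc = _xclip(p, eps, 1.0 - eps)
    return -_xmean(g * _xlog(pc) + (1.0 - g) * _xlog(1.0 - pc))


def ssim_value(p, g, k1: float = 0.01, k2: float = 0.03, dynamic_range: float = 1.0):
    """Global-statistics SSIM, differentiable when given Tensors.

    On numpy input this equals :func:`hepafuse.metrics.ssim_global`.
    """
    _validate_pair(p, g)
    c1 = (k1 * dynamic_range) ** 2
    c2 = (k2 * dynamic_range) ** 2
    mu_p = _xmean(p)
    mu_g = _xmean(g)
    dp = p - mu_p
    dg = g - mu_g
    var_p = _xmean(dp * dp)
    var_g = _xmean(dg * dg)
    cov = _xmean(dp * dg)
    num = (2.0 * mu_p * mu_g + c1) * (2.0 * cov + c2)
    den = (mu_p * mu_p + mu_g * mu_g + c1) * (var_p + var_g + c2)
    return num / den


def ssim_loss(p, g, k1: float = 0.01, k2: float = 0.03, dynamic_range: float = 1.0):
    """1 - SSIM(P, G); in [0, 2]."""
    return 1.0 - ssim_value(p, g, k1, k2, dynamic_range)


def hybrid_loss(p, g, weights: LossWeights = LossWeights(),
                smoothing: float = 1e-6):
    """Weighted Dice + CE + SSIM objective.

    Returns ``(total, LossBreakdown)`` where ``total`` is a Tensor when the
    prediction is a Tensor (for training) and a float otherwise.  The
    breakdown always carries plain floats satisfying
    total = l1*dice + l2*ce + l3*ssim.
    """
    weights.validate()
    l_dice = dice_loss(p, g, smoothing=smoothing)
    l_ce = cross_entropy_loss(p, g)
    l_ssim = ssim_loss(p, g)
    total = weights.dice * l_dice + weights.ce * l_ce + weights.ssim * l_ssim
    pr, gr = _raw(p), _raw(g)
    breakdown = LossBreakdown(
        dice=_scalar(l_dice), ce=_scalar(l_ce), ssim=_scalar(l_ssim),
        total=_scalar(total),
        intersection=float((pr * gr).sum()),
        p_sum=float(pr.sum()), g_sum=float(gr.sum()),
    )
    if not _is_tensor(total):
        total = float(total)
    return total, breakdown


def reconstruction_loss(x, x_hat):
    """Autoencoder objective: mean over samples of the squared Euclidean
    norm of the per-sample residual (the norm sums over all markers)."""
    xr, hr = _validate_pair(x, x_hat)
    if xr.ndim != 2:
        raise ValidationError("expected n x m matrices")
    n = xr.shape[0]
    diff = x - x_hat
    return _xsum(diff * diff) / n
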