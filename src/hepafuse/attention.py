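"""Spatial and channel attention.

The spatial module (SAM) squashes the element-wise product of two 1x1
convolutions of the feature map through a sigmoid, giving a per-pixel map
in (0, 1).  The channel module (CAM) passes the global-average-pooled
channel vector through a bottleneck MLP (ReLU, then sigmoid), giving a
per-channel weight vector in (0, 1).  The two are combined by a weighted
broadcast sum ``A[c, i, j] = alpha * As[i, j] + beta * Ac[c]`` — the only
shape-consistent reading of a "linear weighted sum" of a map and a vector —
and the combined map gates the features element-wise.

Functional forms (numpy, explicit parameters) mirror the trainable modules
used inside the segmenter; a test pins them together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import Conv2d, Dense, Module, Tensor
from .exceptions import ValidationError

__all__ = [
    "SpatialAttentionParams",
    "ChannelAttentionParams",
    "spatial_attention",
    "channel_attention",
    "combine_attention",
    "refine_features",
    "SAMLayer",
    "CAMLayer",
    "AttentionBlock",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class SpatialAttentionParams:
    """Weights of the two 1x1 C->1 convolutions f1 and f2."""

    w1: np.ndarray  # (C,)
    b1: float
    w2: np.ndarray  # (C,)
    b2: float


@dataclass(frozen=True)
class ChannelAttentionParams:
    """Bottleneck weights: w1 (C, C/r), then w2 (C/r, C)."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray


def spatial_attention(x: np.ndarray, params: SpatialAttentionParams) -> np.ndarray:
    """sigma(f1(X) * f2(X)) with 1x1 convolutions; returns a 1 x H x W map."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise ValidationError("expected a C x H x W feature map")
    c = x.shape[0]
    w1 = np.asarray(params.w1, float).ravel()
    w2 = np.asarray(params.w2, float).ravel()
    if w1.shape != (c,) or w2.shape != (c,):
        raise ValidationError("params channel count does not match the feature map")
    f1 = np.tensordot(w1, x, axes=([0], [0])) + params.b1
    f2 = np.tensordot(w2, x, axes=([0], [0])) + params.b2
    return _sigmoid(f1 * f2)[None, :, :]


def channel_attention(x: np.ndarray, params: ChannelAttentionParams,
                      reduction_ratio: int | None = None) -> np.ndarray:
    """sigma(W2 . ReLU(W1 . GAP(X))); returns a length-C vector."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise ValidationError("expected a C x H x W feature map")
    c = x.shape[0]
    w1 = np.asarray(params.w1, float)
    w2 = np.asarray(params.w2, float)
    if w1.shape[0] != c or w2.shape[1] != c or w1.shape[1] != w2.shape[0]:
        raise ValidationError("bottleneck weight shapes do not match the feature map")
    if reduction_ratio is not None:
        if reduction_ratio < 1 or c // reduction_ratio < 1:
            raise ValidationError("invalid reduction ratio")
        if w1.shape[1] != max(c // reduction_ratio, 1):
            raise ValidationError("bottleneck width inconsistent with reduction ratio")
    gap = x.mean(axis=(1, 2))
    hidden = np.maximum(gap @ w1 + np.asarray(params.b1, float), 0.0)
    return _sigmoid(hidden @ w2 + np.asarray(params.b2, float))


def combine_attention(a_s: np.ndarray, a_c: np.ndarray,
                      alpha: float, beta: float) -> np.ndarray:
    """Broadcast combination A[c,i,j] = alpha*As[i,j] + beta*Ac[c]."""
    if alpha < 0 or beta < 0:
        raise ValidationError("attention mixing weights must be non-negative")
    a_s = np.asarray(a_s, dtype=float)
    a_c = np.asarray(a_c, dtype=float).ravel()
    if a_s.ndim == 2:
        a_s = a_s[None]
    if a_s.ndim != 3 or a_s.shape[0] != 1:
        raise ValidationError("spatial map must be 1 x H x W")
    return alpha * a_s + beta * a_c[:, None, None]


def refine_features(x: np.ndarray, attention: np.ndarray) -> np.ndarray:
    """Gate features element-wise by the combined attention map."""
    x = np.asarray(x, dtype=float)
    attention = np.asarray(attention, dtype=float)
    if x.shape != attention.shape:
        raise ValidationError("feature map and attention map must share shape")
    return x * attention


# ---------------------------------------------------------------------------
# trainable modules (Tensor path, used inside the segmenter)
# ---------------------------------------------------------------------------

class SAMLayer(Module):
    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.f1 = Conv2d(channels, 1, kernel=1, rng=rng)
        self.f2 = Conv2d(channels, 1, kernel=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return (self.f1(x) * self.f2(x)).sigmoid()  # (N,1,H,W)


class CAMLayer(Module):
    def __init__(self, channels: int, reduction_ratio: int, rng: np.random.Generator):
        super().__init__()
        hidden = max(channels // reduction_ratio, 1)
        if reduction_ratio < 1:
            raise ValidationError("reduction_ratio must be >= 1")
        self.fc1 = Dense(channels, hidden, rng)
        # the GAP input is non-negative (post-ReLU features), so an
        # unlucky all-negative draw could freeze the whole module; making
        # one reduction unit non-negative plus a small positive bias
        # guarantees an active path at initialization
        self.fc1.w.data[:, 0] = np.abs(self.fc1.w.data[:, 0])
        self.fc1.b.data += 0.1
        self.fc2 = Dense(hidden, channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        gap = x.mean(axis=(2, 3))  # (N,C)
        return self.fc2(self.fc1(gap).relu()).sigmoid()  # (N,C)


class AttentionBlock(Module):
    """SAM + CAM, combined with mixing weights and applied as a gate."""

    def __init__(self, channels: int, reduction_ratio: int,
                 alpha: float, beta: float, rng: np.random.Generator,
                 trainable_mix: bool = False):
        super().__init__()
        if alpha < 0 or beta < 0:
            raise ValidationError("attention mixing weights must be non-negative")
        self.sam = SAMLayer(channels, rng)
        self.cam = CAMLayer(channels, reduction_ratio, rng)
        self.alpha = Tensor(np.asarray(alpha, float), requires_grad=trainable_mix)
        self.beta = Tensor(np.asarray(beta, float), requires_grad=trainable_mix)

    def combined_map(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        a_s = self.sam(x)                      # (N,1,H,W)
        a_c = self.cam(x).reshape(n, c, 1, 1)  # (N,C,1,1)
        return self.alpha * a_s + self.beta * a_c

    def forward(self, x: Tensor) -> Tensor:
        return x * self.combined_map(x)
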