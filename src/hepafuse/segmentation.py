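"""Attention-guided convolutional segmenter (AG-CNN).

An encoder-decoder backbone (3x3 convolutions + batch norm + ReLU, 2x2
max-pooling) with one spatial+channel attention block at the bottleneck and
at every decoder level.  A terminal 1x1 convolution + sigmoid produces the
soft tumor mask.  Per-depth 1x1 projection heads expose the decoder pyramid
for SSIM-based deep supervision: the auxiliary objective pushes each
depth's projection toward the ground-truth mask by minimizing
``sum_d w_d * (1 - SSIM(proj_d, G))``.

Training minimizes the hybrid Dice/cross-entropy/SSIM objective from
:mod:`hepafuse.losses` (plus the optional deep-supervision term) with Adam.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._nn import (Adam, BatchNorm2d, Conv2d, Module, Tensor, concatenate,
                  maxpool2x2, upsample2x)
from .attention import AttentionBlock
from .exceptions import ValidationError
from .losses import LossWeights, hybrid_loss, ssim_value
from .metrics import dice_coefficient, proportion_correct_patches, ssim_global, PatchSpec
from .preprocessing import AugmentationSpec, augment_pair

__all__ = [
    "SegmenterConfig",
    "DepthFeatureSet",
    "AttentionSegmenter",
    "SegmenterResults",
    "forward_segment",
    "hdfo_terms",
]


@dataclass(frozen=True)
class SegmenterConfig:
    """Architecture and attention defaults.

    ``attention_alpha``/``attention_beta`` are the spatial/channel mixing
    weights (defaults 0.6/0.4); they are fixed unless
    ``attention_trainable`` is set.  ``hdfo_weights`` are the per-depth
    deep-supervision weights, coarse to fine; ``None`` disables the
    auxiliary term so training reduces exactly to the hybrid loss.
    """

    n_levels: int = 3
    base_channels: int = 16
    reduction_ratio: int = 4
    attention_alpha: float = 0.6
    attention_beta: float = 0.4
    attention_trainable: bool = False
    hdfo_weights: tuple[float, ...] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_levels < 2:
            raise ValidationError("n_levels must be >= 2")
        if self.base_channels < 1:
            raise ValidationError("base_channels must be >= 1")
        if self.attention_alpha < 0 or self.attention_beta < 0:
            raise ValidationError("attention mixing weights must be non-negative")
        if self.hdfo_weights is not None and len(self.hdfo_weights) != self.n_levels:
            raise ValidationError("hdfo_weights needs one weight per depth "
                                  f"({self.n_levels})")
        if self.reduction_ratio < 1:
            raise ValidationError("reduction_ratio must be >= 1")


@dataclass
class DepthFeatureSet:
    """Per-depth decoder features and their single-channel projections,
    ordered coarse -> fine; projections are upsampled to mask resolution."""

    features: list  # numpy arrays (N, C_d, H_d, W_d)
    projections: list  # numpy arrays (N, H, W) in (0, 1)
    bottleneck: np.ndarray  # attention-refined bottleneck features (N, C, h, w)


class _ConvBlock(Module):
    def __init__(self, c_in, c_out, rng):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, kernel=3, rng=rng)
        self.bn = BatchNorm2d(c_out)

    def forward(self, x):
        return self.bn(self.conv(x)).relu()


class _UNet(Module):
    def __init__(self, cfg: SegmenterConfig):
        super().__init__()
        rng = np.random.default_rng(cfg.seed)
        nl, base = cfg.n_levels, cfg.base_channels
        widths = [base * 2 ** i for i in range(nl)]
        self.widths = widths
        self.enc = []
        c_in = 1
        for i in range(nl - 1):
            blk = _ConvBlock(c_in, widths[i], rng)
            setattr(self, f"enc{i}", blk)
            self.enc.append(blk)
            c_in = widths[i]
        self.bottleneck = _ConvBlock(c_in, widths[-1], rng)
        self.bottleneck_attn = AttentionBlock(
            widths[-1], cfg.reduction_ratio, cfg.attention_alpha,
            cfg.attention_beta, rng, cfg.attention_trainable)
        self.dec_reduce, self.dec_conv, self.dec_attn = [], [], []
        c_cur = widths[-1]
        for i in reversed(range(nl - 1)):
            reduce = Conv2d(c_cur, widths[i], kernel=1, rng=rng)
            conv = _ConvBlock(2 * widths[i], widths[i], rng)
            attn = AttentionBlock(widths[i], cfg.reduction_ratio,
                                  cfg.attention_alpha, cfg.attention_beta,
                                  rng, cfg.attention_trainable)
            setattr(self, f"dec_reduce{i}", reduce)
            setattr(self, f"dec_conv{i}", conv)
            setattr(self, f"dec_attn{i}", attn)
            self.dec_reduce.append(reduce)
            self.dec_conv.append(conv)
            self.dec_attn.append(attn)
            c_cur = widths[i]
        self.head = Conv2d(widths[0], 1, kernel=1, rng=rng)
        # one 1x1 projection head per depth (bottleneck + decoder levels)
        self.aux_heads = []
        aux_channels = [widths[-1]] + [widths[i] for i in reversed(range(nl - 1))]
        for d, c in enumerate(aux_channels):
            head = Conv2d(c, 1, kernel=1, rng=rng)
            setattr(self, f"aux{d}", head)
            self.aux_heads.append(head)

    def forward(self, x: Tensor):
        skips = []
        h = x
        for blk in self.enc:
            h = blk(h)
            skips.append(h)
            h = maxpool2x2(h)
        h = self.bottleneck_attn(self.bottleneck(h))
        depth_feats = [h]
        for reduce, conv, attn, skip in zip(self.dec_reduce, self.dec_conv,
                                            self.dec_attn, reversed(skips)):
            h = reduce(upsample2x(h))
            h = conv(concatenate([h, skip], axis=1))
            h = attn(h)
            depth_feats.append(h)
        probs = self.head(h).sigmoid()  # (N,1,H,W)
        aux = []
        n_up = len(self.enc)
        for d, (head, feat) in enumerate(zip(self.aux_heads, depth_feats)):
            a = head(feat).sigmoid()
            for _ in range(n_up - d):
                a = upsample2x(a)
            aux.append(a)
        return probs, depth_feats, aux


@dataclass
class SegmenterResults:
    """Training outcome: per-epoch history, early-stopping bookkeeping and
    held-out metrics; the fitted model is reachable as ``.model``."""

    model: "AttentionSegmenter"
    history: list
    best_epoch: int
    stopped_early: bool
    n_train: int
    n_val: int

    @property
    def loss_history(self) -> list[float]:
        return [h["train_total"] for h in self.history]

    def evaluate(self, images, masks, threshold: float = 0.5,
                 patch_spec: PatchSpec = PatchSpec()) -> dict:
        """Mean Dice / SSIM / PCP of thresholded predictions on a set."""
        probs = self.model.predict(images)
        masks = _as_mask_batch(masks)
        dice, ssim, pcp = [], [], []
        for p, g in zip(probs, masks):
            hard = (p >= threshold).astype(np.uint8)
            dice.append(dice_coefficient(hard, g))
            ssim.append(ssim_global(p, g.astype(float)))
            pcp.append(proportion_correct_patches(hard, g, patch_spec))
        return {"dice": float(np.mean(dice)), "ssim": float(np.mean(ssim)),
                "pcp": float(np.mean(pcp)), "n": len(dice)}

    def summary(self) -> str:
        lines = ["AttentionSegmenter fit",
                 "=" * 40,
                 f"epochs run        : {len(self.history)}",
                 f"best epoch        : {self.best_epoch + 1}",
                 f"stopped early     : {self.stopped_early}",
                 f"train/val samples : {self.n_train}/{self.n_val}"]
        if self.history:
            h0, h1 = self.history[0], self.history[-1]
            lines.append(f"train loss        : {h0['train_total']:.4f} -> "
                         f"{h1['train_total']:.4f}")
            if "val_total" in h1:
                lines.append(f"val loss          : {h1['val_total']:.4f}")
        return "\n".join(lines)


def _as_image_batch(images) -> np.ndarray:
    arr = np.asarray(images, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim == 3:
        arr = arr[:, None, :, :]
    if arr.ndim != 4 or arr.shape[1] != 1:
        raise ValidationError("expected images of shape (N, H, W)")
    return arr


def _as_mask_batch(masks) -> np.ndarray:
    arr = np.asarray(masks)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValidationError("expected masks of shape (N, H, W)")
    return arr.astype(np.uint8)


class AttentionSegmenter:
    """The AG-CNN model object.  Build from a :class:`SegmenterConfig`,
    then :meth:`fit` on (images, masks); ``fit`` returns a
    :class:`SegmenterResults`."""

    def __init__(self, config: SegmenterConfig = SegmenterConfig()):
        config.validate()
        self.config = config
        self.net = _UNet(config)

    # -- forward passes ------------------------------------------------------
    def _check_shape(self, arr: np.ndarray):
        h, w = arr.shape[-2:]
        div = 2 ** (self.config.n_levels - 1)
        if h % div or w % div:
            raise ValidationError(
                f"input {h}x{w} must be divisible by {div} for {self.config.n_levels} levels")

    def forward_tensors(self, images: np.ndarray):
        """Taped forward pass; returns (probs, depth features, aux probs)."""
        x = _as_image_batch(images)
        self._check_shape(x)
        return self.net(Tensor(x))

    def forward(self, images) -> tuple[np.ndarray, DepthFeatureSet]:
        """Deterministic (eval-mode) forward pass on numpy images."""
        self.net.eval()
        probs_t, feats_t, aux_t = self.forward_tensors(images)
        probs = probs_t.data[:, 0]
        depthset = DepthFeatureSet(
            features=[f.data for f in feats_t],
            projections=[a.data[:, 0] for a in aux_t],
            bottleneck=feats_t[0].data,
        )
        return probs, depthset

    def predict(self, images, batch_size: int = 16) -> np.ndarray:
        x = _as_image_batch(images)
        out = []
        for i in range(0, len(x), batch_size):
            out.append(self.forward(x[i : i + batch_size])[0])
        return np.concatenate(out, axis=0)

    # -- training ------------------------------------------------------------
    def fit(self, images, masks, *, epochs: int = 100, batch_size: int = 16,
            lr: float = 0.001, weight_decay: float = 1e-5,
            loss_weights: LossWeights = LossWeights(),
            validation_split: float = 0.2, validation_data=None,
            early_stopping: bool = True, patience: int = 10,
            augment: AugmentationSpec | None = None,
            seed: int = 0, log_path: str | Path | None = None,
            verbose: bool = False) -> SegmenterResults:
        x = _as_image_batch(images)
        g = _as_mask_batch(masks)
        self._check_shape(x)
        if len(x) != len(g):
            raise ValidationError("images and masks must align")
        loss_weights.validate()
        rng = np.random.default_rng(seed)

        if validation_data is not None:
            xv = _as_image_batch(validation_data[0])
            gv = _as_mask_batch(validation_data[1])
            xt, gt = x, g
        elif validation_split > 0 and len(x) >= 5:
            perm = rng.permutation(len(x))
            n_val = max(1, int(round(validation_split * len(x))))
            xv, gv = x[perm[:n_val]], g[perm[:n_val]]
            xt, gt = x[perm[n_val:]], g[perm[n_val:]]
        else:
            xt, gt, xv, gv = x, g, None, None

        hdfo_w = self.config.hdfo_weights
        opt = Adam(self.net.parameters(), lr=lr, weight_decay=weight_decay)
        history: list[dict] = []
        best = np.inf
        best_epoch = 0
        best_state = None
        wait = 0
        stopped = False
        log_file = open(log_path, "a") if log_path else None
        step = 0
        try:
            for epoch in range(epochs):
                self.net.train()
                order = rng.permutation(len(xt))
                ep_terms = []
                for start in range(0, len(order), batch_size):
                    idx = order[start : start + batch_size]
                    xb, gb = xt[idx], gt[idx]
                    if augment is not None:
                        xb = xb.copy()
                        gb = gb.copy()
                        for j in range(len(idx)):
                            xb[j, 0], gb[j] = augment_pair(xb[j, 0], gb[j], augment,
                                                           rng=rng)
                    total_t, terms = self._batch_loss(xb, gb, loss_weights, hdfo_w)
                    if not np.isfinite(terms["total"]):
                        raise RuntimeError(
                            f"non-finite loss at epoch {epoch + 1}: {terms}")
                    opt.zero_grad()
                    total_t.backward()
                    opt.step()
                    ep_terms.append(terms)
                    step += 1
                    if log_file:
                        log_file.write(json.dumps({"step": step, **terms}) + "\n")

                record = {f"train_{k}": float(np.mean([t[k] for t in ep_terms]))
                          for k in ep_terms[0]}
                record["epoch"] = epoch + 1
                if xv is not None:
                    record["val_total"] = self._eval_loss(xv, gv, loss_weights, hdfo_w)
                    monitor = record["val_total"]
                else:
                    monitor = record["train_total"]
                history.append(record)
                if verbose:
                    print(f"epoch {epoch + 1}: " +
                          " ".join(f"{k}={v:.4f}" for k, v in record.items()
                                   if k != "epoch"))
                if monitor < best:
                    best = monitor
                    best_epoch = epoch
                    best_state = self.net.state_dict()
                    wait = 0
                else:
                    wait += 1
                    if early_stopping and wait >= patience:
                        stopped = True
                        break
        finally:
            if log_file:
                log_file.close()
        if best_state is not None:
            self.net.load_state_dict(best_state)
        self.net.eval()
        return SegmenterResults(self, history, best_epoch, stopped,
                                len(xt), 0 if xv is None else len(xv))

    def _batch_loss(self, xb, gb, weights: LossWeights, hdfo_w):
        probs_t, _feats, aux_t = self.net(Tensor(xb))
        n = len(xb)
        totals = None
        acc = {"dice": 0.0, "ce": 0.0, "ssim": 0.0}
        hdfo_acc = 0.0
        for i in range(n):
            p_i = probs_t[i, 0]
            g_i = gb[i].astype(float)
            t_i, br = hybrid_loss(p_i, g_i, weights)
            if hdfo_w is not None:
                for w_d, a in zip(hdfo_w, aux_t):
                    if w_d != 0:
                        s = ssim_value(a[i, 0], g_i)
                        t_i = t_i + w_d * (1.0 - s)
                        hdfo_acc += w_d * (1.0 - float(s.data))
            totals = t_i if totals is None else totals + t_i
            for k in acc:
                acc[k] += getattr(br, k)
        total_t = totals / n
        terms = {k: v / n for k, v in acc.items()}
        terms["hdfo"] = hdfo_acc / n
        terms["total"] = float(total_t.data)
        return total_t, terms

    def _eval_loss(self, xv, gv, weights, hdfo_w, batch_size: int = 16) -> float:
        self.net.eval()
        vals = []
        for i in range(0, len(xv), batch_size):
            xb, gb = xv[i : i + batch_size], gv[i : i + batch_size]
            probs_t, _f, aux_t = self.net(Tensor(xb))
            for j in range(len(xb)):
                g_j = gb[j].astype(float)
                total, _ = hybrid_loss(probs_t.data[j, 0], g_j, weights)
                if hdfo_w is not None:
                    for w_d, a in zip(hdfo_w, aux_t):
                        total += w_d * (1.0 - ssim_value(a.data[j, 0], g_j))
                vals.append(total)
        self.net.train()
        return float(np.mean(vals))

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path):
        path = Path(path)
        state = self.net.state_dict()
        cfg = json.dumps(dataclasses.asdict(self.config))
        np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8),
                 **state)

    @classmethod
    def load(cls, path: str | Path) -> "AttentionSegmenter":
        with np.load(Path(path).with_suffix(".npz") if not str(path).endswith(".npz")
                     else path) as data:
            cfg = json.loads(bytes(data["__config__"].tobytes()).decode())
            if cfg.get("hdfo_weights") is not None:
                cfg["hdfo_weights"] = tuple(cfg["hdfo_weights"])
            model = cls(SegmenterConfig(**cfg))
            state = {k: data[k] for k in data.files if k != "__config__"}
        model.net.load_state_dict(state)
        model.net.eval()
        return model


def forward_segment(model: AttentionSegmenter, images) -> tuple[np.ndarray, DepthFeatureSet]:
    """Functional alias: soft masks and the depth-feature pyramid."""
    return model.forward(images)


def hdfo_terms(depthset: DepthFeatureSet, masks, weights=None
               ) -> tuple[np.ndarray, float]:
    """Per-depth SSIM of the projections against the ground truth and the
    weighted auxiliary penalty ``sum_d w_d * (1 - SSIM_d)``.

    ``weights=None`` means uniform 1/D.  SSIM per depth is averaged over the
    batch.
    """
    g = _as_mask_batch(masks).astype(float)
    n_depths = len(depthset.projections)
    if weights is None:
        weights = np.full(n_depths, 1.0 / n_depths)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (n_depths,):
        raise ValidationError("need one weight per depth")
    ssims = np.empty(n_depths)
    for d, proj in enumerate(depthset.projections):
        if proj.shape != g.shape:
            raise ValidationError("projection resolution does not match masks")
        ssims[d] = np.mean([ssim_global(proj[i], g[i]) for i in range(len(g))])
    aux = float(np.sum(weights * (1.0 - ssims)))
    return ssims, aux
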