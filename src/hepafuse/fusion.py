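"""Multimodal fusion: project imaging and genomic features to a shared
space, adaptively blend them, refine by a learned gate, and classify
subtypes.

The imaging vector is the global average pool of the attention-refined
bottleneck feature map; the genomic vector is the autoencoder code.  Both
are affinely projected into a common d_f-dimensional space and fused by a
convex combination ``F = alpha * F_img + (1 - alpha) * F_gen`` where alpha
is trainable (sigmoid-parameterized, so it stays in (0, 1)).  The fused
vector passes through a multiplicative sigmoid gate — the smallest
mechanism that can amplify informative coordinates and suppress noisy ones,
and the source of the cross-modal interactions a convex blend alone cannot
express — and a softmax layer yields row-stochastic subtype probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._nn import Adam, Dense, Module, Tensor, softmax_cross_entropy
from .exceptions import ValidationError
from .losses import LossWeights, hybrid_loss
from .segmentation import AttentionSegmenter, DepthFeatureSet

__all__ = [
    "ProjectionParams",
    "ProjectedFeatures",
    "GateParams",
    "SubtypePrediction",
    "pool_image_features",
    "project",
    "fuse",
    "attend_fused",
    "classify",
    "FusionClassifier",
    "FusionResults",
    "train_joint",
]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# functional ops
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProjectionParams:
    w_img: np.ndarray  # (d_img, d_f)
    b_img: np.ndarray
    w_gen: np.ndarray  # (d_gen, d_f)
    b_gen: np.ndarray


@dataclass
class ProjectedFeatures:
    f_img: np.ndarray  # (n, d_f)
    f_gen: np.ndarray  # (n, d_f)


@dataclass(frozen=True)
class GateParams:
    w: np.ndarray  # (d_f, d_f)
    b: np.ndarray


@dataclass
class SubtypePrediction:
    """Row-stochastic class probabilities and their argmax labels."""

    probabilities: np.ndarray  # (n, S), rows sum to 1
    labels: np.ndarray  # (n,)


def pool_image_features(source, images=None) -> np.ndarray:
    """Global average pooling of the attention-refined bottleneck features.

    ``source`` is either a :class:`DepthFeatureSet` or an
    :class:`AttentionSegmenter` (in which case ``images`` must be given).
    Output dimension equals the bottleneck channel count.
    """
    if isinstance(source, AttentionSegmenter):
        if images is None:
            raise ValidationError("images required when pooling from a model")
        out = []
        for i in range(0, len(images), 16):
            _, depthset = source.forward(np.asarray(images)[i : i + 16])
            out.append(depthset.bottleneck.mean(axis=(2, 3)))
        return np.concatenate(out, axis=0)
    if not isinstance(source, DepthFeatureSet):
        raise ValidationError("expected a DepthFeatureSet or an AttentionSegmenter")
    if source.bottleneck is None:
        raise ValidationError("depth feature set is missing bottleneck features")
    return source.bottleneck.mean(axis=(2, 3))


def project(img_vectors: np.ndarray, gen_latent: np.ndarray,
            params: ProjectionParams) -> ProjectedFeatures:
    """Affine maps of both modalities into the shared d_f space."""
    xi = np.atleast_2d(np.asarray(img_vectors, float))
    xg = np.atleast_2d(np.asarray(gen_latent, float))
    if xi.shape[1] != params.w_img.shape[0] or xg.shape[1] != params.w_gen.shape[0]:
        raise ValidationError("feature dimensions do not match projection params")
    if params.w_img.shape[1] != params.w_gen.shape[1]:
        raise ValidationError("projections must land in the same shared dimension")
    return ProjectedFeatures(xi @ params.w_img + params.b_img,
                             xg @ params.w_gen + params.b_gen)


def fuse(features: ProjectedFeatures, alpha: float) -> np.ndarray:
    """Convex combination alpha * F_img + (1 - alpha) * F_gen."""
    if not 0.0 <= alpha <= 1.0:
        warnings.warn(f"fusion alpha {alpha} outside [0, 1]; clamping",
                      RuntimeWarning, stacklevel=2)
        alpha = min(max(alpha, 0.0), 1.0)
    return alpha * features.f_img + (1.0 - alpha) * features.f_gen


def attend_fused(fused: np.ndarray, gate: GateParams) -> np.ndarray:
    """Learned sigmoid feature gate F * sigma(F W + b)."""
    f = np.atleast_2d(np.asarray(fused, float))
    if not np.all(np.isfinite(f)):
        raise ValidationError("fused features must be finite")
    return f * _sigmoid(f @ gate.w + gate.b)


def classify(f_attn: np.ndarray, w_fc: np.ndarray, b_fc: np.ndarray
             ) -> SubtypePrediction:
    """Softmax classification of the attended features."""
    f = np.atleast_2d(np.asarray(f_attn, float))
    logits = f @ w_fc + b_fc
    if logits.shape[1] < 2:
        raise ValidationError("need at least two subtype classes")
    if not np.all(np.isfinite(logits)):
        raise ValidationError("non-finite logits")
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    return SubtypePrediction(probs, probs.argmax(axis=1))


# ---------------------------------------------------------------------------
# trainable fusion classifier
# ---------------------------------------------------------------------------

class _FusionNet(Module):
    def __init__(self, d_img, d_gen, d_f, n_subtypes, rng):
        super().__init__()
        self.proj_img = Dense(d_img, d_f, rng)
        self.proj_gen = Dense(d_gen, d_f, rng)
        self.alpha_logit = Tensor(np.asarray(0.0), requires_grad=True)
        self.gate = Dense(d_f, d_f, rng)
        self.fc = Dense(d_f, n_subtypes, rng)

    def forward(self, xi: Tensor, xg: Tensor, fixed_alpha: float | None = None):
        fi = self.proj_img(xi)
        fg = self.proj_gen(xg)
        if fixed_alpha is None:
            alpha = self.alpha_logit.sigmoid()
        else:
            alpha = Tensor(np.asarray(float(fixed_alpha)))
        fused = alpha * fi + (1.0 - alpha) * fg
        attn = fused * self.gate(fused).sigmoid()
        return self.fc(attn)


@dataclass
class FusionResults:
    """Fit outcome: loss/accuracy history and the fusion-weight trajectory."""

    model: "FusionClassifier"
    history: list
    alpha_trajectory: list

    @property
    def final_alpha(self) -> float:
        return self.alpha_trajectory[-1]

    def summary(self) -> str:
        h1 = self.history[-1]
        lines = ["FusionClassifier fit",
                 "=" * 40,
                 f"epochs        : {len(self.history)}",
                 f"final loss    : {h1['loss']:.4f}",
                 f"train accuracy: {h1['accuracy']:.3f}",
                 f"fusion alpha  : {self.final_alpha:.3f}"
                 + ("  (frozen)" if self.model.fixed_alpha is not None else "")]
        return "\n".join(lines)


class FusionClassifier:
    """Adaptive imaging-genomic fusion with a softmax subtype head.

    ``fixed_alpha`` freezes the fusion weight (1.0 = imaging only,
    0.0 = genomics only) for modality-ablation baselines; otherwise alpha is
    learned through a sigmoid parameterization and stays strictly in (0, 1).
    """

    def __init__(self, d_img: int, d_gen: int, n_subtypes: int,
                 shared_dim: int = 64, fixed_alpha: float | None = None,
                 standardize: str = "block", seed: int = 0):
        if n_subtypes < 2:
            raise ValidationError("n_subtypes must be >= 2")
        if fixed_alpha is not None and not 0.0 <= fixed_alpha <= 1.0:
            raise ValidationError("fixed_alpha must lie in [0, 1]")
        if standardize not in ("per-feature", "block", "none"):
            raise ValidationError("standardize must be per-feature|block|none")
        self.d_img, self.d_gen = d_img, d_gen
        self.n_subtypes = n_subtypes
        self.shared_dim = shared_dim
        self.fixed_alpha = fixed_alpha
        self.standardize = standardize
        self.net = _FusionNet(d_img, d_gen, shared_dim, n_subtypes,
                              np.random.default_rng(seed))
        self._stats = None  # feature standardization (mean_i, sd_i, mean_g, sd_g)

    @property
    def fusion_alpha(self) -> float:
        if self.fixed_alpha is not None:
            return float(self.fixed_alpha)
        return float(_sigmoid(self.net.alpha_logit.data))

    def _standardize(self, xi, xg, fit: bool):
        """Center features; scale per-dimension ("per-feature") or by each
        modality's mean standard deviation ("block").

        Block scaling keeps the relative variance structure within a
        modality: strongly responding channels stay dominant instead of
        being flattened to unit variance alongside noise channels.
        """
        xi = np.atleast_2d(np.asarray(xi, float))
        xg = np.atleast_2d(np.asarray(xg, float))
        if fit and self.standardize != "none":
            if self.standardize == "per-feature":
                sd_i = xi.std(axis=0)
                sd_g = xg.std(axis=0)
            else:
                sd_i = np.full(xi.shape[1], xi.std(axis=0).mean())
                sd_g = np.full(xg.shape[1], xg.std(axis=0).mean())
            self._stats = (xi.mean(axis=0), np.where(sd_i > 0, sd_i, 1.0),
                           xg.mean(axis=0), np.where(sd_g > 0, sd_g, 1.0))
        if self._stats is None:
            return xi, xg
        mi, si, mg, sg = self._stats
        return (xi - mi) / si, (xg - mg) / sg

    def fit(self, img_features, gen_features, labels, *, epochs: int = 300,
            batch_size: int = 32, lr: float = 0.001, weight_decay: float = 1e-5,
            seed: int = 0, verbose: bool = False) -> FusionResults:
        y = np.asarray(labels, dtype=int)
        if y.min() < 0 or y.max() >= self.n_subtypes:
            raise ValidationError("labels outside [0, n_subtypes)")
        xi, xg = self._standardize(img_features, gen_features, fit=True)
        if len(xi) != len(xg) or len(xi) != len(y):
            raise ValidationError("modalities and labels must align on samples")
        rng = np.random.default_rng(seed)
        opt = Adam(self.net.parameters(), lr=lr, weight_decay=weight_decay)
        history, alphas = [], []
        n = len(y)
        for epoch in range(epochs):
            order = rng.permutation(n)
            losses, correct = [], 0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                logits = self.net(Tensor(xi[idx]), Tensor(xg[idx]),
                                  self.fixed_alpha)
                loss, probs = softmax_cross_entropy(logits, y[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
                correct += int((probs.argmax(axis=1) == y[idx]).sum())
            alphas.append(self.fusion_alpha)
            history.append({"epoch": epoch + 1,
                            "loss": float(np.mean(losses)),
                            "accuracy": correct / n,
                            "alpha": alphas[-1]})
            if verbose and (epoch + 1) % 50 == 0:
                print(f"epoch {epoch + 1}: loss {history[-1]['loss']:.4f} "
                      f"acc {history[-1]['accuracy']:.3f} alpha {alphas[-1]:.3f}")
        return FusionResults(self, history, alphas)

    def predict_proba(self, img_features, gen_features) -> np.ndarray:
        xi, xg = self._standardize(img_features, gen_features, fit=False)
        logits = self.net(Tensor(xi), Tensor(xg), self.fixed_alpha).data
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return ez / ez.sum(axis=1, keepdims=True)

    def predict(self, img_features, gen_features) -> SubtypePrediction:
        probs = self.predict_proba(img_features, gen_features)
        return SubtypePrediction(probs, probs.argmax(axis=1))

    def score(self, img_features, gen_features, labels) -> float:
        pred = self.predict(img_features, gen_features)
        return float((pred.labels == np.asarray(labels)).mean())


def train_joint(samples, segmenter: AttentionSegmenter,
                autoencoder, *, shared_dim: int = 64,
                epochs: int = 300, batch_size: int = 32, lr: float = 0.001,
                weight_decay: float = 1e-5, fixed_alpha: float | None = None,
                seed: int = 0, end_to_end: bool = False,
                seg_loss_weight: float = 0.1,
                loss_weights: LossWeights = LossWeights()) -> FusionResults:
    """Two-stage fusion training on a paired cohort.

    Extracts pooled imaging features from the (pretrained) segmenter and
    latent codes from the (pretrained) autoencoder, then fits the fusion
    classifier on subtype labels.  With ``end_to_end=True`` the classifier
    gradient also flows into both upstream networks and the hybrid
    segmentation loss is added with weight ``seg_loss_weight``.
    """
    images = np.stack([s.image for s in samples])
    masks = np.stack([s.mask for s in samples])
    genomic = np.stack([s.genomic_row for s in samples])
    y = np.asarray([s.subtype_label for s in samples], dtype=int)

    if not end_to_end:
        xi = pool_image_features(segmenter, images)
        xg = autoencoder.encode(genomic)
        clf = FusionClassifier(xi.shape[1], xg.shape[1], int(y.max()) + 1,
                               shared_dim=shared_dim, fixed_alpha=fixed_alpha,
                               seed=seed)
        return clf.fit(xi, xg, y, epochs=epochs, batch_size=batch_size, lr=lr,
                       weight_decay=weight_decay, seed=seed)

    # end-to-end: backprop classification loss through both branches
    d_img = segmenter.config.base_channels * 2 ** (segmenter.config.n_levels - 1)
    d_gen = autoencoder.latent_dim
    clf = FusionClassifier(d_img, d_gen, int(y.max()) + 1,
                           shared_dim=shared_dim, fixed_alpha=fixed_alpha,
                           seed=seed)
    gen_std = autoencoder._standardize(genomic, fit=autoencoder.col_mean is None)
    rng = np.random.default_rng(seed)
    params = (clf.net.parameters() + segmenter.net.parameters()
              + autoencoder.net.parameters())
    opt = Adam(params, lr=lr, weight_decay=weight_decay)
    history, alphas = [], []
    n = len(y)
    for epoch in range(epochs):
        segmenter.net.train()
        autoencoder.net.train()
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            probs_t, feats_t, _aux = segmenter.forward_tensors(images[idx])
            xi_t = feats_t[0].mean(axis=(2, 3))
            xg_t = autoencoder.net.encode(Tensor(gen_std[idx]))
            logits = clf.net(xi_t, xg_t, clf.fixed_alpha)
            loss, probs = softmax_cross_entropy(logits, y[idx])
            if seg_loss_weight > 0:
                seg_terms = None
                for j, smp in enumerate(idx):
                    t_j, _ = hybrid_loss(probs_t[j, 0], masks[smp].astype(float),
                                         loss_weights)
                    seg_terms = t_j if seg_terms is None else seg_terms + t_j
                loss = loss + seg_loss_weight * (seg_terms / len(idx))
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((probs.argmax(axis=1) == y[idx]).sum())
        alphas.append(clf.fusion_alpha)
        history.append({"epoch": epoch + 1, "loss": float(np.mean(losses)),
                        "accuracy": correct / n, "alpha": alphas[-1]})
    segmenter.net.eval()
    autoencoder.net.eval()
    return FusionResults(clf, history, alphas)
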