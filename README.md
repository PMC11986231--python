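# hepafuse

Attention-guided liver-tumor segmentation fused with autoencoder-based
genomic subtype discovery, for 2-D tomographic slices paired with
samples × markers genomic matrices.

Tumor heterogeneity makes single-modality prediction brittle: imaging shows
morphology (size, irregular margins) while molecular profiles carry subtype
information that imaging cannot resolve, and some subtype distinctions only
emerge from the *interaction* of the two. `hepafuse` is aimed at
methods-oriented users who want a fully testable reference implementation of
a radiogenomic pipeline — including the synthetic phantom/cohort generators
needed to verify every stage without any external download.

## The model

Three components, each a model object whose `fit()` returns a results
object with history, diagnostics and `summary()`:

**Attention-guided segmenter** (`AttentionSegmenter`) — an encoder–decoder
CNN (3×3 conv + batch-norm + ReLU per level, 2×2 max-pooling) with a
spatial-attention module `A_s = σ(f₁(X) ⊙ f₂(X))` (two 1×1 convolutions),
a channel-attention module `A_c = σ(W₂·ReLU(W₁·GAP(X)))`, and their
weighted broadcast combination `A = α·A_s + β·A_c` (defaults α = 0.6,
β = 0.4) gating the features at the bottleneck and each decoder level.
Training minimizes the hybrid objective

    L = λ₁·L_Dice + λ₂·L_CE + λ₃·L_SSIM,   (λ₁, λ₂, λ₃) = (0.5, 0.3, 0.2)

where `L_SSIM = 1 − SSIM(P, G)` uses a global-statistics SSIM
(`C₁ = (0.01 L)²`, `C₂ = (0.03 L)²`). Optional depth-wise supervision adds
`Σ_d w_d (1 − SSIM(proj_d, G))` over per-depth 1×1 projection heads.

**Genomic autoencoder** (`GenomicAutoencoder`) — a four-layer fully
connected autoencoder `m → h → k → h → m` (ReLU hidden layers, linear code
and output, dropout 0.3) minimizing the mean per-sample squared
reconstruction error `L_recon = (1/n) Σᵢ ‖xᵢ − x̂ᵢ‖²` with Adam
(lr 0.001, weight decay 1e-5). The code is clustered with k-means to
recover subtypes; `rank_markers` scores each marker by its multiple
correlation with the between-cluster latent structure.

**Fusion classifier** (`FusionClassifier`) — projects pooled imaging
features and the genomic code to a shared space, blends them convexly,
`F = α·F_img + (1−α)·F_gen` with α trainable in (0, 1), refines the fused
vector with a learned sigmoid gate and classifies subtypes by softmax.
Freezing α at 1 or 0 gives the single-modality ablation baselines.

All networks run on a small numpy reverse-mode autodiff core
(`hepafuse._nn`) — no GPU framework required.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from hepafuse.synthetic import PhantomSpec, CohortSpec, generate_paired_cohort
from hepafuse.segmentation import AttentionSegmenter, SegmenterConfig
from hepafuse.genomics import GenomicAutoencoder, cluster_latent

phantom = PhantomSpec(height=64, width=64, radius_range=(5, 12),
                      boundary_irregularity=0.25, seed=1)
cohort = CohortSpec(n_samples=48, n_markers=60, latent_rank=4,
                    n_subtypes=2, cluster_separation=6.0, seed=2)
samples = generate_paired_cohort(phantom, cohort, joint_rule="image_only")

images = np.stack([s.image for s in samples])
masks = np.stack([s.mask for s in samples])

seg = AttentionSegmenter(SegmenterConfig(seed=0))
res = seg.fit(images[:40], masks[:40], epochs=8, batch_size=16, seed=0)
print(res.summary())
print(res.evaluate(images[40:], masks[40:]))

genomic = np.stack([s.genomic_row for s in samples])
ae = GenomicAutoencoder(n_markers=60, latent_dim=8, seed=0)
print(ae.fit(genomic, epochs=150, lr=0.003, seed=0).summary())
labels = cluster_latent(ae.encode(genomic), n_clusters=2, seed=0)
print("cluster ARI vs planted genomic clusters:",
      adjusted_rand_score([s.genomic_cluster for s in samples], labels))
```

prints

```
AttentionSegmenter fit
========================================
epochs run        : 8
best epoch        : 8
stopped early     : False
train/val samples : 32/8
train loss        : 0.8355 -> 0.6833
val loss          : 0.7593
{'dice': 0.8352692829340064, 'ssim': 0.1486660575514695, 'pcp': 0.9296875, 'n': 8}
GenomicAutoencoder fit
========================================
markers -> latent : 60 -> 8
epochs            : 150
reconstruction    : 415.658 -> 11.353  (ratio 0.0273)
cluster ARI vs planted genomic clusters: 1.0
```

Eight epochs on 40 phantoms already reach a held-out Dice of 0.84 (the
30-epoch reference run in `hepafuse.experiments` exceeds 0.95); the low
SSIM reflects still-soft probability maps at this budget. The autoencoder
drives the reconstruction error to 2.7% of its initial value and its latent
k-means recovers the two planted genomic clusters exactly (ARI = 1.0).

A command-line surface wraps the full pipeline — cohort simulation, k-fold
training, metric reports:

```bash
hepafuse simulate --config cfg.yaml --out cohort/ --seed 1
hepafuse train    --config cfg.yaml --cohort cohort/ --out run/
hepafuse evaluate --config cfg.yaml --checkpoints run/ --cohort cohort/ --out report/
```

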