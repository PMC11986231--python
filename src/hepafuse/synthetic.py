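"""Synthetic paired imaging-genomic cohorts with planted subtype structure.

Phantom images emulate liver-like slices: a smoothed random-field background
carrying one or more blob "tumors" of controllable size, eccentricity and
boundary irregularity, plus additive Gaussian noise.  Genomic cohorts are
drawn from a low-rank latent factor model with well-separated subtype
centroids.  Paired cohorts tie the subtype label to tumor morphology and/or
the genomic cluster; under the ``joint_xor`` rule neither modality alone
determines the label, which is exactly the property the fusion classifier is
evaluated on.

Everything here is a pure function of (spec, seed): same spec + same seed is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .exceptions import ValidationError

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "SyntheticSample",
    "generate_phantom",
    "generate_genomic_cohort",
    "generate_paired_cohort",
    "modality_ceilings",
    "write_cohort",
    "read_cohort",
    "JOINT_RULES",
    "JOINT_XOR_TABLE",
    "N_JOINT_STRATA",
]

# 4x4 interaction table for the joint rule: every row and every column is a
# 3-1 split, so the Bayes accuracy of either modality alone is exactly 0.75
# while both strata together determine the label; labels are globally
# balanced (8 ones / 8 zeros).
JOINT_XOR_TABLE = np.array(
    [
        [1, 1, 1, 0],
        [1, 1, 0, 1],
        [1, 0, 0, 0],
        [0, 1, 0, 0],
    ],
    dtype=int,
)
N_JOINT_STRATA = 4

JOINT_RULES = ("image_only", "genomic_only", "joint_xor")


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a single phantom slice.

    ``radius_range`` is in pixels, ``eccentricity_range`` in [0, 1),
    ``boundary_irregularity`` is the amplitude of the radial perturbation as
    a fraction of the radius, ``tumor_contrast`` the intensity offset added
    inside the tumor, ``background_texture_scale`` the correlation length of
    the background texture in pixels, ``noise_sigma`` the additive Gaussian
    noise level in intensity units.
    """

    height: int = 512
    width: int = 512
    n_tumors: int = 1
    radius_range: tuple[float, float] = (20.0, 60.0)
    eccentricity_range: tuple[float, float] = (0.0, 0.6)
    boundary_irregularity: float = 0.3
    tumor_contrast: float = 0.35
    background_texture_scale: float = 16.0
    noise_sigma: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValidationError("image dimensions must be positive")
        if self.n_tumors < 0:
            raise ValidationError("n_tumors must be >= 0")
        lo, hi = self.radius_range
        if not (0 < lo <= hi):
            raise ValidationError("radius_range must satisfy 0 < lo <= hi")
        if 2 * hi * (1 + self.boundary_irregularity) >= min(self.height, self.width):
            raise ValidationError("largest tumor radius does not fit inside the image")
        elo, ehi = self.eccentricity_range
        if not (0 <= elo <= ehi < 1):
            raise ValidationError("eccentricity_range must lie in [0, 1) with lo <= hi")
        if self.boundary_irregularity < 0:
            raise ValidationError("boundary_irregularity must be >= 0")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a genomic cohort with planted subtype clusters.

    Rows are generated as (subtype centroid in ``latent_rank`` space) x a
    fixed loading matrix + Gaussian marker noise.  ``cluster_separation`` is
    the minimum pairwise distance between subtype centroids in latent units;
    ``marker_noise_sigma`` the per-marker noise standard deviation.
    """

    n_samples: int = 100
    n_markers: int = 200
    latent_rank: int = 8
    n_subtypes: int = 3
    cluster_separation: float = 4.0
    marker_noise_sigma: float = 0.5
    morphology_link: str = "size"
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValidationError("n_samples must be >= 1")
        if self.latent_rank >= self.n_markers:
            raise ValidationError("latent_rank must be < n_markers")
        if self.n_subtypes < 2:
            raise ValidationError("n_subtypes must be >= 2")
        if self.n_subtypes > self.n_samples:
            raise ValidationError("n_subtypes cannot exceed n_samples")
        if self.cluster_separation < 0 or self.marker_noise_sigma < 0:
            raise ValidationError("separation and noise must be >= 0")


@dataclass
class SyntheticSample:
    image: np.ndarray
    mask: np.ndarray
    genomic_row: np.ndarray
    subtype_label: int
    morphology_stratum: int = 0
    genomic_cluster: int = 0
    sample_id: str = ""


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------

def _blob_mask(h: int, w: int, center: tuple[float, float], radius: float,
               eccentricity: float, angle: float, irregularity: float,
               rng: np.random.Generator) -> np.ndarray:
    """Rasterize one blob: an ellipse whose radius is perturbed by a random
    low-order sinusoid (harmonics 2-5, random phase)."""
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dy = yy - center[0]
    dx = xx - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    b_over_a = np.sqrt(1.0 - eccentricity ** 2)  # minor/major axis ratio
    rho = np.sqrt(u ** 2 + (v / b_over_a) ** 2)
    theta = np.arctan2(v / b_over_a, u)
    boundary = np.full_like(theta, radius)
    if irregularity > 0:
        harmonics = rng.integers(2, 6, size=3)
        phases = rng.uniform(0, 2 * np.pi, size=3)
        amps = rng.uniform(0.3, 1.0, size=3)
        amps = amps / amps.sum()
        wobble = np.zeros_like(theta)
        for hh, ph, am in zip(harmonics, phases, amps):
            wobble += am * np.sin(hh * theta + ph)
        boundary = radius * (1.0 + irregularity * wobble)
    return rho < boundary


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate one phantom image and its binary tumor mask.

    The image is textured background + ``tumor_contrast`` inside the mask +
    Gaussian noise, clipped to [0, 1]; the mask is the union of the blob
    interiors.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    # liver-like background: Gaussian-filtered white noise rescaled to a
    # mid-gray band so positive tumor contrast stays inside [0, 1]
    noise_field = rng.standard_normal((h, w))
    smooth = ndimage.gaussian_filter(noise_field, sigma=spec.background_texture_scale)
    lo, hi = smooth.min(), smooth.max()
    if hi > lo:
        smooth = (smooth - lo) / (hi - lo)
    else:
        smooth = np.zeros_like(smooth)
    background = 0.25 + 0.3 * smooth

    mask = np.zeros((h, w), dtype=bool)
    margin_factor = 1.0 + spec.boundary_irregularity
    for _ in range(spec.n_tumors):
        radius = rng.uniform(*spec.radius_range)
        ecc = rng.uniform(*spec.eccentricity_range)
        angle = rng.uniform(0, np.pi)
        margin = radius * margin_factor + 1
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        mask |= _blob_mask(h, w, (cy, cx), radius, ecc, angle,
                           spec.boundary_irregularity, rng)

    image = background + spec.tumor_contrast * mask
    if spec.noise_sigma > 0:
        image = image + rng.normal(0, spec.noise_sigma, size=(h, w))
    image = np.clip(image, 0.0, 1.0)
    return image, mask.astype(np.uint8)


# ---------------------------------------------------------------------------
# genomic cohorts
# ---------------------------------------------------------------------------

def _centroids(rng: np.random.Generator, n_subtypes: int, rank: int,
               separation: float) -> np.ndarray:
    c = rng.standard_normal((n_subtypes, rank))
    c = c - c.mean(axis=0)
    dists = [np.linalg.norm(c[i] - c[j])
             for i in range(n_subtypes) for j in range(i + 1, n_subtypes)]
    min_d = min(dists)
    if min_d == 0:
        raise ValidationError("degenerate centroid draw; change the seed")
    return c * (separation / min_d)


def balanced_labels(n: int, n_classes: int) -> np.ndarray:
    """Round-robin label assignment, balanced within +/- 1 sample."""
    return np.arange(n) % n_classes


def generate_genomic_cohort(
    spec: CohortSpec, labels: np.ndarray | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Generate an n x m genomic matrix with planted subtype clusters.

    Returns a DataFrame (index ``sample_id``, columns ``marker_0001``...)
    and the subtype labels.  With ``marker_noise_sigma == 0`` rows of the
    same subtype are identical and the matrix rank equals
    ``min(n_subtypes, latent_rank)``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, m, r, s = spec.n_samples, spec.n_markers, spec.latent_rank, spec.n_subtypes
    if labels is None:
        labels = balanced_labels(n, s)
    else:
        labels = np.asarray(labels, dtype=int)
        if labels.shape != (n,) or labels.min() < 0 or labels.max() >= s:
            raise ValidationError("labels must be length n with values in [0, n_subtypes)")

    centroids = _centroids(rng, s, r, spec.cluster_separation)
    loadings = rng.standard_normal((r, m))
    latent = centroids[labels]
    x = latent @ loadings
    if spec.marker_noise_sigma > 0:
        x = x + rng.normal(0, spec.marker_noise_sigma, size=(n, m))

    marker_names = [f"marker_{j + 1:04d}" for j in range(m)]
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    frame = pd.DataFrame(x, index=pd.Index(sample_ids, name="sample_id"),
                         columns=marker_names)
    return frame, labels


# ---------------------------------------------------------------------------
# paired cohorts
# ---------------------------------------------------------------------------

def modality_ceilings(joint_rule: str, n_subtypes: int = 2) -> tuple[float, float]:
    """Bayes accuracy ceiling of (imaging alone, genomics alone) under a rule,
    computed by enumerating the rule's truth table over uniform strata."""
    if joint_rule == "image_only":
        return 1.0, 1.0 / n_subtypes  # genomics carries no label information
    if joint_rule == "genomic_only":
        return 1.0 / n_subtypes, 1.0
    if joint_rule == "joint_xor":
        t = JOINT_XOR_TABLE
        img = np.mean([max(np.mean(row), 1 - np.mean(row)) for row in t])
        gen = np.mean([max(np.mean(col), 1 - np.mean(col)) for col in t.T])
        return float(img), float(gen)
    raise ValidationError(f"unknown joint_rule {joint_rule!r}")


def _stratum_radius_range(spec: PhantomSpec, stratum: int, n_strata: int
                          ) -> tuple[float, float]:
    """Partition radius_range into n_strata bands with 30% guard gaps so the
    morphology strata are cleanly separated by tumor size."""
    lo, hi = spec.radius_range
    width = (hi - lo) / n_strata
    return (lo + (stratum + 0.15) * width, lo + (stratum + 0.85) * width)


def generate_paired_cohort(
    phantom: PhantomSpec, cohort: CohortSpec, joint_rule: str = "joint_xor"
) -> list[SyntheticSample]:
    """Generate paired (image, mask, genomic row, label) samples.

    * ``image_only``: the label is the tumor-size stratum; the genomic
      cluster is an independent nuisance.
    * ``genomic_only``: the label is the genomic cluster; tumor size is an
      independent nuisance.
    * ``joint_xor``: the label is a balanced interaction of 4 tumor-size
      strata and 4 genomic clusters in which either modality alone attains a
      Bayes accuracy of 0.75 (requires ``n_subtypes == 2``).
    """
    if joint_rule not in JOINT_RULES:
        raise ValidationError(f"unknown joint_rule {joint_rule!r}")
    phantom.validate()
    cohort.validate()
    n, s = cohort.n_samples, cohort.n_subtypes

    rng = np.random.default_rng(cohort.seed)
    if joint_rule == "joint_xor":
        if s != 2:
            raise ValidationError("joint_xor requires n_subtypes == 2")
        n_img, n_gen = N_JOINT_STRATA, N_JOINT_STRATA
        # round-robin over the 16 cells keeps every stratum and the labels
        # balanced within +/- 1
        cells = np.arange(n) % (n_img * n_gen)
        img_strata = cells // n_gen
        gen_clusters = cells % n_gen
        labels = JOINT_XOR_TABLE[img_strata, gen_clusters]
    elif joint_rule == "image_only":
        n_img, n_gen = s, s
        labels = balanced_labels(n, s)
        img_strata = labels.copy()
        gen_clusters = rng.permutation(balanced_labels(n, n_gen))
    else:  # genomic_only
        n_img, n_gen = s, s
        labels = balanced_labels(n, s)
        gen_clusters = labels.copy()
        img_strata = rng.permutation(balanced_labels(n, n_img))

    genomic_spec = dataclasses.replace(cohort, n_subtypes=n_gen)
    genomic, _ = generate_genomic_cohort(genomic_spec, labels=gen_clusters)

    seed_seq = np.random.SeedSequence(phantom.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in seed_seq.spawn(n)]

    samples: list[SyntheticSample] = []
    for i in range(n):
        rr = _stratum_radius_range(phantom, int(img_strata[i]), n_img)
        pspec = dataclasses.replace(phantom, radius_range=rr, seed=child_seeds[i])
        image, mask = generate_phantom(pspec)
        samples.append(
            SyntheticSample(
                image=image,
                mask=mask,
                genomic_row=genomic.iloc[i].to_numpy(),
                subtype_label=int(labels[i]),
                morphology_stratum=int(img_strata[i]),
                genomic_cluster=int(gen_clusters[i]),
                sample_id=str(genomic.index[i]),
            )
        )
    return samples


# ---------------------------------------------------------------------------
# on-disk cohort layout
# ---------------------------------------------------------------------------

def write_cohort(samples: list[SyntheticSample], out_dir: str | Path, *,
                 phantom: PhantomSpec, cohort: CohortSpec, joint_rule: str,
                 force: bool = False) -> Path:
    """Write PNG images/masks, a cohort-level CSV and a manifest JSON."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise ValidationError(f"output directory {out} is not empty (use force)")
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)

    rows = []
    for smp in samples:
        img8 = np.round(smp.image * 255).astype(np.uint8)
        Image.fromarray(img8, mode="L").save(out / "images" / f"{smp.sample_id}.png")
        Image.fromarray((smp.mask * 255).astype(np.uint8), mode="L").save(
            out / "masks" / f"{smp.sample_id}.png")
        rows.append([smp.sample_id, smp.subtype_label, smp.morphology_stratum,
                     smp.genomic_cluster, *smp.genomic_row])

    m = len(samples[0].genomic_row)
    cols = ["sample_id", "subtype_label", "morphology_stratum", "genomic_cluster"]
    cols += [f"marker_{j + 1:04d}" for j in range(m)]
    pd.DataFrame(rows, columns=cols).to_csv(out / "cohort.csv", index=False)

    manifest = {
        "phantom_spec": dataclasses.asdict(phantom),
        "cohort_spec": dataclasses.asdict(cohort),
        "joint_rule": joint_rule,
        "n_samples": len(samples),
        "sample_ids": [s.sample_id for s in samples],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def read_cohort(cohort_dir: str | Path) -> tuple[list[SyntheticSample], dict]:
    """Read a cohort written by :func:`write_cohort`."""
    root = Path(cohort_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    table = pd.read_csv(root / "cohort.csv")
    marker_cols = [c for c in table.columns if c.startswith("marker_")]
    samples = []
    for _, row in table.iterrows():
        sid = row["sample_id"]
        image = np.asarray(Image.open(root / "images" / f"{sid}.png"), dtype=float) / 255.0
        mask = (np.asarray(Image.open(root / "masks" / f"{sid}.png")) > 127).astype(np.uint8)
        samples.append(SyntheticSample(
            image=image, mask=mask,
            genomic_row=row[marker_cols].to_numpy(dtype=float),
            subtype_label=int(row["subtype_label"]),
            morphology_stratum=int(row["morphology_stratum"]),
            genomic_cluster=int(row["genomic_cluster"]),
            sample_id=sid,
        ))
    return samples, manifest
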