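"""Configuration, orchestration, cross-validation and reporting.

A :class:`TrainConfig` gathers every module's settings (YAML-serializable;
defaults follow the validation protocol: 100 epochs, imaging batch 16,
genomic batch 32, Adam lr 0.001 / weight decay 1e-5, early stopping with
patience 10, 20% validation split, 5-fold cross-validation).  Every
artifact written by a run carries the seed and the configuration hash that
produced it, so any run is replayable from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import StratifiedKFold

from .exceptions import ValidationError
from .fusion import FusionClassifier, pool_image_features
from .genomics import GenomicAutoencoder
from .losses import LossWeights
from .metrics import (PatchSpec, confusion_metrics, dice_coefficient,
                      proportion_correct_patches, ssim_global)
from .segmentation import AttentionSegmenter, SegmenterConfig
from .synthetic import (CohortSpec, PhantomSpec, generate_paired_cohort,
                        read_cohort, write_cohort)

__all__ = [
    "TrainSettings",
    "GfamSettings",
    "FusionSettings",
    "TrainConfig",
    "fold_partition",
    "run_simulate",
    "run_train",
    "run_evaluate",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class TrainSettings:
    epochs: int = 100
    imaging_batch: int = 16
    genomic_batch: int = 32
    lr: float = 0.001
    weight_decay: float = 1e-5
    early_stopping: bool = True
    patience: int = 10
    val_split: float = 0.2
    folds: int = 5
    seed: int = 0


@dataclass(frozen=True)
class GfamSettings:
    latent_dim: int = 128
    hidden: int | None = None
    dropout: float = 0.3
    n_clusters: int | None = None  # default: the cohort's subtype count


@dataclass(frozen=True)
class FusionSettings:
    shared_dim: int = 64
    epochs: int = 300
    batch_size: int = 32


@dataclass
class TrainConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    joint_rule: str = "joint_xor"
    segmenter: SegmenterConfig = field(default_factory=SegmenterConfig)
    gfam: GfamSettings = field(default_factory=GfamSettings)
    fusion: FusionSettings = field(default_factory=FusionSettings)
    loss: LossWeights = field(default_factory=LossWeights)
    train: TrainSettings = field(default_factory=TrainSettings)

    # -- (de)serialization ---------------------------------------------------
    _SECTIONS = {
        "phantom": PhantomSpec, "cohort": CohortSpec,
        "segmenter": SegmenterConfig, "gfam": GfamSettings,
        "fusion": FusionSettings, "loss": LossWeights, "train": TrainSettings,
    }

    def to_dict(self) -> dict:
        out = {}
        for name in self._SECTIONS:
            value = dataclasses.asdict(getattr(self, name))
            out[name] = {k: (list(v) if isinstance(v, tuple) else v)
                         for k, v in value.items()}
        out["joint_rule"] = self.joint_rule
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "TrainConfig":
        kwargs = {}
        for name, dc in cls._SECTIONS.items():
            section = dict(data.get(name, {}))
            fields = {f.name: f for f in dataclasses.fields(dc)}
            unknown = set(section) - set(fields)
            if unknown:
                raise ValidationError(f"unknown keys in '{name}': {sorted(unknown)}")
            for key, value in section.items():
                if isinstance(value, list):
                    section[key] = tuple(value)
            kwargs[name] = dc(**section)
        return cls(joint_rule=data.get("joint_rule", "joint_xor"), **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def fold_partition(labels, n_folds: int, seed: int):
    """Deterministic stratified folds; every sample lands in exactly one
    validation fold."""
    labels = np.asarray(labels)
    if n_folds < 2:
        raise ValidationError("need at least 2 folds")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(labels)), labels))


# ---------------------------------------------------------------------------
# commands
# ---------------------------------------------------------------------------

def run_simulate(config: TrainConfig, out_dir: str | Path, *,
                 seed: int | None = None, force: bool = False) -> Path:
    """Generate and write a paired synthetic cohort."""
    phantom, cohort = config.phantom, config.cohort
    if seed is not None:
        phantom = dataclasses.replace(phantom, seed=seed)
        cohort = dataclasses.replace(cohort, seed=seed + 1)
    samples = generate_paired_cohort(phantom, cohort, config.joint_rule)
    out = write_cohort(samples, out_dir, phantom=phantom, cohort=cohort,
                       joint_rule=config.joint_rule, force=force)
    meta = {"config_hash": config.config_hash(),
            "seed": {"phantom": phantom.seed, "cohort": cohort.seed}}
    (out / "run.json").write_text(json.dumps(meta, indent=2))
    return out


def _fit_fold(config: TrainConfig, samples, train_idx, val_idx, fold_dir: Path,
              seed: int):
    images = np.stack([samples[i].image for i in train_idx])
    masks = np.stack([samples[i].mask for i in train_idx])
    genomic = np.stack([samples[i].genomic_row for i in train_idx])
    labels = np.asarray([samples[i].subtype_label for i in train_idx])
    t = config.train

    seg = AttentionSegmenter(config.segmenter)
    seg_res = seg.fit(images, masks, epochs=t.epochs,
                      batch_size=t.imaging_batch, lr=t.lr,
                      weight_decay=t.weight_decay, loss_weights=config.loss,
                      validation_split=t.val_split,
                      early_stopping=t.early_stopping, patience=t.patience,
                      seed=seed, log_path=fold_dir / "segmenter_steps.jsonl")

    latent_dim = min(config.gfam.latent_dim, genomic.shape[1] - 1)
    ae = GenomicAutoencoder(genomic.shape[1], latent_dim=latent_dim,
                            hidden=config.gfam.hidden,
                            dropout=config.gfam.dropout, seed=seed)
    ae_res = ae.fit(genomic, epochs=t.epochs, batch_size=t.genomic_batch,
                    lr=t.lr, weight_decay=t.weight_decay, seed=seed)

    xi = pool_image_features(seg, images)
    xg = ae.encode(genomic)
    clf = FusionClassifier(xi.shape[1], xg.shape[1],
                           int(max(s.subtype_label for s in samples)) + 1,
                           shared_dim=config.fusion.shared_dim, seed=seed)
    fus_res = clf.fit(xi, xg, labels, epochs=config.fusion.epochs,
                      batch_size=config.fusion.batch_size, lr=t.lr,
                      weight_decay=t.weight_decay, seed=seed)

    seg.save(fold_dir / "segmenter.npz")
    return seg, ae, clf, {"segmenter_epochs": len(seg_res.history),
                          "segmenter_stopped_early": seg_res.stopped_early,
                          "ae_recon_ratio": ae_res.final_loss / ae_res.initial_loss,
                          "fusion_alpha": fus_res.final_alpha}


def run_train(config: TrainConfig, cohort_dir: str | Path,
              out_dir: str | Path) -> dict:
    """k-fold training loop over a simulated cohort; writes per-fold
    checkpoints, logs and a summary JSON.  A fold that diverges (non-finite
    loss) is recorded and skipped; the other folds continue."""
    samples, _manifest = read_cohort(cohort_dir)
    labels = np.asarray([s.subtype_label for s in samples])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t = config.train
    folds = fold_partition(labels, t.folds, t.seed)

    fold_reports = []
    for fold_id, (train_idx, val_idx) in enumerate(folds):
        fold_dir = out / f"fold_{fold_id}"
        fold_dir.mkdir(exist_ok=True)
        try:
            seg, ae, clf, info = _fit_fold(config, samples, train_idx, val_idx,
                                           fold_dir, seed=t.seed + fold_id)
        except RuntimeError as err:  # divergence: abort this fold only
            fold_reports.append({"fold": fold_id, "error": str(err)})
            continue
        val = [samples[i] for i in val_idx]
        report = evaluate_fold(config, seg, ae, clf, val)
        report.update({"fold": fold_id, **info})
        fold_reports.append(report)
        (fold_dir / "report.json").write_text(json.dumps(report, indent=2))

    ok = [r for r in fold_reports if "error" not in r]
    summary = {
        "config_hash": config.config_hash(),
        "seed": t.seed,
        "folds": fold_reports,
        "aggregate": {k: float(np.mean([r[k] for r in ok]))
                      for k in ("dice", "ssim", "pcp", "accuracy")} if ok else {},
    }
    (out / "train_summary.json").write_text(json.dumps(summary, indent=2,
                                                       sort_keys=True))
    return summary


def evaluate_fold(config: TrainConfig, seg: AttentionSegmenter,
                  ae: GenomicAutoencoder, clf: FusionClassifier,
                  val_samples) -> dict:
    images = np.stack([s.image for s in val_samples])
    masks = np.stack([s.mask for s in val_samples])
    genomic = np.stack([s.genomic_row for s in val_samples])
    y = np.asarray([s.subtype_label for s in val_samples])
    probs = seg.predict(images, batch_size=config.train.imaging_batch)
    pred_masks = (probs >= 0.5).astype(np.uint8)
    xi = pool_image_features(seg, images)
    xg = ae.encode(genomic)
    y_hat = clf.predict(xi, xg).labels
    frame = evaluate_predictions(pred_masks, probs, masks, y_hat, y)
    agg = frame[frame["sample"] == "aggregate"].iloc[0]
    return {"dice": float(agg["dice"]), "ssim": float(agg["ssim"]),
            "pcp": float(agg["pcp"]), "accuracy": float(agg["accuracy"]),
            "n_val": len(val_samples)}


def evaluate_predictions(pred_masks, soft_masks, true_masks,
                         pred_labels, true_labels,
                         patch_spec: PatchSpec = PatchSpec(),
                         sample_ids=None) -> pd.DataFrame:
    """Full metric table: one row per sample plus an aggregate row."""
    pred_masks = np.asarray(pred_masks)
    true_masks = np.asarray(true_masks)
    soft_masks = np.asarray(soft_masks, dtype=float)
    pred_labels = np.asarray(pred_labels)
    true_labels = np.asarray(true_labels)
    n = len(pred_masks)
    if sample_ids is None:
        sample_ids = [f"sample_{i}" for i in range(n)]
    rows = []
    for i in range(n):
        rows.append({
            "sample": sample_ids[i],
            "dice": dice_coefficient(pred_masks[i], true_masks[i]),
            "ssim": ssim_global(soft_masks[i], true_masks[i].astype(float)),
            "pcp": proportion_correct_patches(pred_masks[i], true_masks[i],
                                              patch_spec),
            "predicted_subtype": int(pred_labels[i]),
            "true_subtype": int(true_labels[i]),
            "correct": bool(pred_labels[i] == true_labels[i]),
        })
    cm = confusion_metrics(pred_labels, true_labels)
    agg = {
        "sample": "aggregate",
        "dice": float(np.mean([r["dice"] for r in rows])),
        "ssim": float(np.mean([r["ssim"] for r in rows])),
        "pcp": float(np.mean([r["pcp"] for r in rows])),
        "accuracy": cm.accuracy,
        "precision": cm.overall["precision"],
        "recall": cm.overall["recall"],
        "specificity": cm.overall["specificity"],
        "f1": cm.overall["f1"],
    }
    frame = pd.DataFrame(rows)
    frame["accuracy"] = (frame["correct"]).astype(float)
    return pd.concat([frame, pd.DataFrame([agg])], ignore_index=True)


def run_evaluate(config: TrainConfig, checkpoint_dir: str | Path,
                 cohort_dir: str | Path, out_dir: str | Path) -> dict:
    """Evaluate saved fold checkpoints on a cohort; writes CSV + JSON.

    Only the segmentation metrics are recomputed from checkpoints (the
    segmenter is the persisted model); subtype metrics come from the stored
    fold reports when present.
    """
    samples, _ = read_cohort(cohort_dir)
    images = np.stack([s.image for s in samples])
    masks = np.stack([s.mask for s in samples])
    ids = [s.sample_id for s in samples]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    checkpoint_dir = Path(checkpoint_dir)
    fold_dirs = sorted(checkpoint_dir.glob("fold_*/segmenter.npz"))
    if not fold_dirs:
        raise ValidationError(f"no fold checkpoints under {checkpoint_dir}")
    reports = {}
    for ckpt in fold_dirs:
        try:
            seg = AttentionSegmenter.load(ckpt)
        except (KeyError, ValueError) as err:
            raise ValidationError(
                f"checkpoint {ckpt} incompatible with config: {err}") from err
        if seg.config != config.segmenter:
            diff = [f.name for f in dataclasses.fields(SegmenterConfig)
                    if getattr(seg.config, f.name) != getattr(config.segmenter, f.name)]
            raise ValidationError(
                f"checkpoint {ckpt} differs from config in keys: {diff}")
        probs = seg.predict(images, batch_size=config.train.imaging_batch)
        hard = (probs >= 0.5).astype(np.uint8)
        rows = []
        for i in range(len(samples)):
            rows.append({"sample": ids[i],
                         "dice": dice_coefficient(hard[i], masks[i]),
                         "ssim": ssim_global(probs[i], masks[i].astype(float)),
                         "pcp": proportion_correct_patches(hard[i], masks[i])})
        frame = pd.DataFrame(rows)
        agg = frame.drop(columns="sample").mean().to_dict()
        frame = pd.concat([frame, pd.DataFrame([{"sample": "aggregate", **agg}])],
                          ignore_index=True)
        name = ckpt.parent.name
        frame.to_csv(out / f"metrics_{name}.csv", index=False)
        reports[name] = {k: float(v) for k, v in agg.items()}

    summary = {"config_hash": config.config_hash(),
               "folds": reports,
               "aggregate": {k: float(np.mean([r[k] for r in reports.values()]))
                             for k in next(iter(reports.values()))}}
    (out / "evaluate_summary.json").write_text(json.dumps(summary, indent=2,
                                                          sort_keys=True))
    return summary
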