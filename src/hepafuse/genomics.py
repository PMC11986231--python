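"""Genomic feature analysis: autoencoder compression, latent clustering
and marker ranking.

A four-layer fully connected autoencoder (encoder m -> h -> k with a ReLU
hidden layer and a linear code layer, decoder k -> h -> m with a ReLU
hidden layer and a linear output, dropout 0.3 on the hidden layers)
compresses a standardized samples x markers matrix to a k-dimensional code
minimizing the mean per-sample squared reconstruction error.  The code is
clustered with k-means to recover tumor subtypes.

Marker ranking is a transparent saliency heuristic — each marker is scored
by its multiple correlation with the between-cluster structure of the
latent space (one-way F statistics identify the discriminating dimensions).
It is NOT the "MIRSLiC" molecular-interaction method referenced in the
radiogenomics literature, which has no published definition; treat the
ranking as a reproducible stand-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from ._nn import Adam, Dense, Dropout, Module, Tensor
from .exceptions import ValidationError
from .losses import reconstruction_loss

__all__ = [
    "GenomicAutoencoder",
    "AutoencoderResults",
    "MarkerRanking",
    "cluster_latent",
    "rank_markers",
    "read_genomic_csv",
]


class _AENet(Module):
    def __init__(self, m: int, k: int, hidden: int, dropout: float,
                 rng: np.random.Generator):
        super().__init__()
        self.enc1 = Dense(m, hidden, rng)
        self.enc2 = Dense(hidden, k, rng)
        self.dec1 = Dense(k, hidden, rng)
        self.dec2 = Dense(hidden, m, rng)  # linear output
        self.drop1 = Dropout(dropout, rng)
        self.drop2 = Dropout(dropout, rng)

    def encode(self, x: Tensor) -> Tensor:
        # ReLU on the hidden layer; the code layer itself is linear so the
        # latent space can represent signed factor scores (PCA-like codes)
        return self.enc2(self.drop1(self.enc1(x).relu()))

    def forward(self, x: Tensor) -> Tensor:
        z = self.encode(x)
        return self.dec2(self.drop2(self.dec1(z).relu()))


@dataclass
class MarkerRanking:
    """Markers ordered by decreasing saliency score."""

    ranking: list  # [(marker_name, score), ...] non-increasing
    latent_weights: np.ndarray  # per-latent-dimension F-statistic weights
    constant_markers: list = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ranking, columns=["marker", "score"])


@dataclass
class AutoencoderResults:
    """Fit outcome: loss history plus before/after reconstruction error."""

    model: "GenomicAutoencoder"
    history: list  # epoch-mean reconstruction loss (standardized scale)
    initial_loss: float
    final_loss: float

    def summary(self) -> str:
        return "\n".join([
            "GenomicAutoencoder fit",
            "=" * 40,
            f"markers -> latent : {self.model.n_markers} -> {self.model.latent_dim}",
            f"epochs            : {len(self.history)}",
            f"reconstruction    : {self.initial_loss:.3f} -> {self.final_loss:.3f}"
            f"  (ratio {self.final_loss / self.initial_loss:.4f})",
        ])


class GenomicAutoencoder:
    """Deep autoencoder for a samples x markers matrix.

    Parameters
    ----------
    n_markers : input dimensionality m (must exceed ``latent_dim``).
    latent_dim : size k of the code layer (default 128; scale down for
        small cohorts).
    hidden : width of the two hidden layers; default is the rounded
        geometric mean of (m, k).
    dropout : dropout rate on the hidden layers during training.
    """

    def __init__(self, n_markers: int, latent_dim: int = 128,
                 hidden: int | None = None, dropout: float = 0.3,
                 seed: int = 0):
        if latent_dim < 1 or latent_dim >= n_markers:
            raise ValidationError("need 1 <= latent_dim < n_markers")
        if not 0 <= dropout < 1:
            raise ValidationError("dropout must be in [0, 1)")
        self.n_markers = n_markers
        self.latent_dim = latent_dim
        self.hidden = hidden or max(int(round(np.sqrt(n_markers * latent_dim))),
                                    latent_dim)
        self.dropout = dropout
        self.seed = seed
        self.net = _AENet(n_markers, latent_dim, self.hidden, dropout,
                          np.random.default_rng(seed))
        self.col_mean: np.ndarray | None = None
        self.col_std: np.ndarray | None = None

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.net.parameters())

    # -- data handling -------------------------------------------------------
    @staticmethod
    def _as_matrix(x) -> np.ndarray:
        arr = x.to_numpy(dtype=float) if isinstance(x, pd.DataFrame) else \
            np.asarray(x, dtype=float)
        if arr.ndim != 2:
            raise ValidationError("expected an n x m matrix")
        return arr

    def _standardize(self, arr: np.ndarray, fit: bool) -> np.ndarray:
        if fit:
            self.col_mean = arr.mean(axis=0)
            std = arr.std(axis=0)
            self.col_std = np.where(std > 0, std, 1.0)
        if self.col_mean is None:
            raise ValidationError("model has not been fit (no standardization stats)")
        return (arr - self.col_mean) / self.col_std

    def destandardize(self, arr: np.ndarray) -> np.ndarray:
        return arr * self.col_std + self.col_mean

    # -- fitting -------------------------------------------------------------
    def fit(self, x, *, epochs: int = 100, batch_size: int = 32,
            lr: float = 0.001, weight_decay: float = 1e-5,
            seed: int = 0, verbose: bool = False) -> AutoencoderResults:
        arr = self._as_matrix(x)
        if arr.shape[1] != self.n_markers:
            raise ValidationError(
                f"matrix has {arr.shape[1]} markers, model expects {self.n_markers}")
        xs = self._standardize(arr, fit=True)
        rng = np.random.default_rng(seed)
        opt = Adam(self.net.parameters(), lr=lr, weight_decay=weight_decay)

        initial = self._full_loss(xs)
        history: list[float] = []
        n = len(xs)
        for epoch in range(epochs):
            self.net.train()
            order = rng.permutation(n)
            ep = []
            for start in range(0, n, batch_size):
                xb = xs[order[start : start + batch_size]]
                xb_t = Tensor(xb)
                loss = reconstruction_loss(xb_t, self.net(xb_t))
                if not np.isfinite(loss.data):
                    raise RuntimeError(f"non-finite reconstruction loss at epoch {epoch + 1}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                ep.append(float(loss.data))
            history.append(float(np.mean(ep)))
            if verbose:
                print(f"epoch {epoch + 1}: recon {history[-1]:.4f}")
        final = self._full_loss(xs)
        return AutoencoderResults(self, history, initial, final)

    def _full_loss(self, xs: np.ndarray) -> float:
        self.net.eval()
        out = self.net(Tensor(xs))
        return float(reconstruction_loss(xs, out.data))

    # -- inference -----------------------------------------------------------
    def encode(self, x) -> np.ndarray:
        """Deterministic latent code (dropout disabled)."""
        arr = self._as_matrix(x)
        if arr.shape[1] != self.n_markers:
            raise ValidationError("marker count mismatch")
        xs = self._standardize(arr, fit=False)
        self.net.eval()
        return self.net.encode(Tensor(xs)).data

    def reconstruct(self, x, *, original_scale: bool = False) -> np.ndarray:
        arr = self._as_matrix(x)
        xs = self._standardize(arr, fit=False)
        self.net.eval()
        out = self.net(Tensor(xs)).data
        return self.destandardize(out) if original_scale else out


def cluster_latent(z: np.ndarray, n_clusters: int, *, seed: int = 0,
                   n_init: int = 10) -> np.ndarray:
    """k-means labels (in [0, n_clusters)) on the latent matrix."""
    z = np.asarray(z, dtype=float)
    if n_clusters < 2:
        raise ValidationError("n_clusters must be >= 2")
    if len(z) < n_clusters:
        raise ValidationError("need at least n_clusters samples")
    km = KMeans(n_clusters=n_clusters, n_init=n_init, random_state=seed)
    return km.fit_predict(z)


def rank_markers(x, z: np.ndarray, labels: np.ndarray,
                 marker_names: list[str] | None = None) -> MarkerRanking:
    """Saliency ranking of markers (stand-in for an interaction-based
    selector; see module docstring).

    A marker's score is its multiple correlation with the discriminating
    latent subspace — the span of the cluster-mean offsets in latent space
    (the directions the one-way F statistics single out).  A marker that is
    itself a cluster indicator scores ~1; pure-noise and constant markers
    score ~0, the latter flagged explicitly.  Per-latent-dimension F-statistic
    weights are returned as diagnostics.
    """
    if isinstance(x, pd.DataFrame):
        if marker_names is None:
            marker_names = list(x.columns)
        xa = x.to_numpy(dtype=float)
    else:
        xa = np.asarray(x, dtype=float)
        if marker_names is None:
            marker_names = [f"marker_{j + 1:04d}" for j in range(xa.shape[1])]
    z = np.asarray(z, dtype=float)
    labels = np.asarray(labels)
    if len(xa) != len(z) or len(xa) != len(labels):
        raise ValidationError("X, Z and labels must align on samples")
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValidationError("need at least two clusters to rank markers")

    # per-dimension F statistics: which latent dimensions separate clusters
    f_stats = np.zeros(z.shape[1])
    for d in range(z.shape[1]):
        col = z[:, d]
        if np.ptp(col) == 0:
            continue
        f, _ = stats.f_oneway(*[col[labels == g] for g in groups])
        if np.isfinite(f):
            f_stats[d] = f
    weights = f_stats / f_stats.sum() if f_stats.sum() > 0 else \
        np.full(z.shape[1], 1.0 / z.shape[1])

    # discriminating subspace: span of the cluster-mean offsets in latent
    # space, F-weighted through the cluster means themselves
    z_centered = z - z.mean(axis=0)
    offsets = np.stack([z[labels == g].mean(axis=0) - z.mean(axis=0)
                        for g in groups])  # (S, k)
    basis, _ = np.linalg.qr(offsets.T)  # (k, S) orthonormal columns
    raw_proj = z_centered @ basis  # latent coordinates along cluster structure
    # denoise: each sample takes its cluster's mean coordinates, so a marker
    # is scored against the cluster-level latent structure rather than the
    # within-cluster code noise (a perfect indicator marker then scores 1)
    proj = np.empty_like(raw_proj)
    for g in groups:
        proj[labels == g] = raw_proj[labels == g].mean(axis=0)
    keep = proj.std(axis=0) > 1e-12
    proj = proj[:, keep]
    # orthonormalize the projected coordinates so the multiple correlation
    # of a marker with the subspace is the norm of its correlation vector
    if proj.shape[1]:
        q, _ = np.linalg.qr(proj / np.sqrt(len(proj)))
        q *= np.sqrt(len(proj))  # columns: mean 0, unit variance, orthogonal
    else:
        q = np.zeros((len(z), 0))

    x_centered = xa - xa.mean(axis=0)
    x_sd = xa.std(axis=0)
    tol = 1e-10 * (np.abs(xa).max(axis=0) + 1.0)
    is_const = x_sd <= tol
    constant = [marker_names[j] for j in range(xa.shape[1]) if is_const[j]]
    safe_sd = np.where(is_const, 1.0, x_sd)
    if q.shape[1]:
        corr = (x_centered / safe_sd).T @ q / len(xa)  # (m, S-1)
        scores = np.minimum(np.linalg.norm(corr, axis=1), 1.0)
    else:
        scores = np.zeros(xa.shape[1])
    scores[is_const] = 0.0

    order = np.argsort(-scores, kind="stable")
    ranking = [(marker_names[j], float(scores[j])) for j in order]
    return MarkerRanking(ranking, weights, constant)


def read_genomic_csv(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a genomic matrix (first column sample_id, header row marker
    names) from CSV or TSV."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep, index_col=0)
    if frame.shape[1] < 2:
        raise ValidationError("genomic matrix needs at least two marker columns")
    return frame
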