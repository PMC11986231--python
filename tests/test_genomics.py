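"""Autoencoder, latent clustering and marker-ranking contracts."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

from hepafuse.exceptions import ValidationError
from hepafuse.genomics import (GenomicAutoencoder, cluster_latent,
                               rank_markers, read_genomic_csv)
from hepafuse.synthetic import CohortSpec, generate_genomic_cohort


@pytest.fixture(scope="module")
def cohort():
    spec = CohortSpec(n_samples=90, n_markers=40, latent_rank=4, n_subtypes=3,
                      cluster_separation=6.0, marker_noise_sigma=0.5, seed=7)
    return generate_genomic_cohort(spec)


class TestArchitecture:
    def test_parameter_count_matches_closed_form(self):
        m, k = 50, 8
        ae = GenomicAutoencoder(m, latent_dim=k, seed=0)
        h = ae.hidden
        expected = (m * h + h) + (h * k + k) + (k * h + h) + (h * m + m)
        assert ae.parameter_count() == expected

    def test_smallest_valid_compression_accepted(self):
        GenomicAutoencoder(10, latent_dim=9)

    def test_no_compression_rejected(self):
        with pytest.raises(ValidationError):
            GenomicAutoencoder(10, latent_dim=10)


class TestTraining:
    def test_loss_decreases(self, cohort):
        frame, _ = cohort
        ae = GenomicAutoencoder(40, latent_dim=8, seed=0)
        res = ae.fit(frame, epochs=30, batch_size=32, seed=0)
        assert res.history[-1] < res.history[0]
        assert res.final_loss < res.initial_loss
        assert "GenomicAutoencoder" in res.summary()

    def test_same_seed_identical_history(self, cohort):
        frame, _ = cohort
        histories = []
        for _ in range(2):
            ae = GenomicAutoencoder(40, latent_dim=8, seed=3)
            histories.append(ae.fit(frame, epochs=5, seed=3).history)
        assert histories[0] == histories[1]

    def test_low_rank_cohort_reconstructed(self):
        """Noise-free rank-4 data with latent_dim >= rank trains to a small
        fraction of the initial loss."""
        spec = CohortSpec(n_samples=120, n_markers=30, latent_rank=4,
                          n_subtypes=6, cluster_separation=6.0,
                          marker_noise_sigma=0.0, seed=2)
        frame, _ = generate_genomic_cohort(spec)
        ae = GenomicAutoencoder(30, latent_dim=8, dropout=0.0, seed=0)
        res = ae.fit(frame, epochs=150, batch_size=32, lr=0.003, seed=0)
        assert res.final_loss < 0.05 * res.initial_loss

    def test_marker_count_mismatch_rejected(self, cohort):
        ae = GenomicAutoencoder(10, latent_dim=4)
        with pytest.raises(ValidationError):
            ae.fit(cohort[0])


class TestEncode:
    def test_duplicated_samples_share_codes(self, cohort):
        frame, _ = cohort
        ae = GenomicAutoencoder(40, latent_dim=8, seed=0)
        ae.fit(frame, epochs=3, seed=0)
        x = frame.to_numpy()[:5]
        z = ae.encode(np.vstack([x, x]))
        assert z.shape == (10, 8)
        assert np.allclose(z[:5], z[5:])

    def test_standardization_round_trip(self):
        """De-standardized reconstruction recovers the original column
        means and variances within 5% on noiseless low-rank data."""
        spec = CohortSpec(n_samples=150, n_markers=25, latent_rank=3,
                          n_subtypes=5, cluster_separation=6.0,
                          marker_noise_sigma=0.0, seed=4)
        frame, _ = generate_genomic_cohort(spec)
        ae = GenomicAutoencoder(25, latent_dim=6, dropout=0.0, seed=0)
        ae.fit(frame, epochs=200, batch_size=32, lr=0.003, seed=0)
        recon = ae.reconstruct(frame, original_scale=True)
        x = frame.to_numpy()
        assert np.allclose(recon.mean(axis=0), x.mean(axis=0),
                           atol=0.05 * np.abs(x.mean(axis=0)).mean() + 0.05)
        assert np.allclose(recon.std(axis=0), x.std(axis=0),
                           rtol=0.05, atol=0.05 * x.std(axis=0).mean())

    def test_near_pca_reconstruction(self):
        """The unregularized autoencoder reconstructs no worse than 1.5x
        the best rank-k linear (PCA) reconstruction on a linear cohort."""
        spec = CohortSpec(n_samples=300, n_markers=200, latent_rank=8,
                          n_subtypes=3, cluster_separation=6.0,
                          marker_noise_sigma=0.5, seed=11)
        frame, _ = generate_genomic_cohort(spec)
        xs = (frame.to_numpy() - frame.to_numpy().mean(0)) / frame.to_numpy().std(0)
        pca = PCA(n_components=16).fit(xs)
        pca_loss = ((xs - pca.inverse_transform(pca.transform(xs))) ** 2) \
            .sum(axis=1).mean()
        ae = GenomicAutoencoder(200, latent_dim=16, dropout=0.0, seed=0)
        res = ae.fit(frame, epochs=400, batch_size=32, lr=0.003, seed=0)
        assert res.final_loss <= 1.5 * pca_loss


class TestClustering:
    def test_two_samples_two_clusters(self):
        labels = cluster_latent(np.array([[0.0, 0.0], [5.0, 5.0]]), 2, seed=0)
        assert sorted(labels) == [0, 1]

    def test_noiseless_planted_clusters_recovered_exactly(self):
        spec = CohortSpec(n_samples=60, n_markers=30, latent_rank=4,
                          n_subtypes=3, cluster_separation=5.0,
                          marker_noise_sigma=0.0, seed=9)
        frame, truth = generate_genomic_cohort(spec)
        ae = GenomicAutoencoder(30, latent_dim=6, dropout=0.0, seed=0)
        ae.fit(frame, epochs=60, lr=0.003, seed=0)
        labels = cluster_latent(ae.encode(frame), 3, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_ari_non_decreasing_in_separation(self):
        aris = []
        for sep in (1.0, 2.5, 4.0):
            spec = CohortSpec(n_samples=90, n_markers=30, latent_rank=4,
                              n_subtypes=3, cluster_separation=sep,
                              marker_noise_sigma=1.0, seed=13)
            frame, truth = generate_genomic_cohort(spec)
            ae = GenomicAutoencoder(30, latent_dim=6, seed=0)
            ae.fit(frame, epochs=120, lr=0.003, seed=0)
            labels = cluster_latent(ae.encode(frame), 3, seed=0)
            aris.append(adjusted_rand_score(truth, labels))
        assert aris[0] <= aris[1] + 0.05 and aris[1] <= aris[2] + 0.05
        assert aris[2] > 0.9

    def test_single_cluster_rejected(self):
        with pytest.raises(ValidationError):
            cluster_latent(np.zeros((5, 2)), 1)


class TestMarkerRanking:
    def test_cluster_indicator_marker_ranks_first(self, cohort, rng):
        frame, truth = cohort
        x = frame.to_numpy().copy()
        x[:, 0] = (truth == 0).astype(float) * 10  # perfect separator
        ae = GenomicAutoencoder(40, latent_dim=8, seed=0)
        ae.fit(x, epochs=40, seed=0)
        z = ae.encode(x)
        ranking = rank_markers(x, z, truth,
                               marker_names=[f"m{j}" for j in range(40)])
        assert ranking.ranking[0][0] == "m0"

    def test_ranking_complete_and_sorted(self, cohort):
        frame, truth = cohort
        ae = GenomicAutoencoder(40, latent_dim=8, seed=0)
        ae.fit(frame, epochs=10, seed=0)
        ranking = rank_markers(frame, ae.encode(frame), truth)
        names = [n for n, _ in ranking.ranking]
        assert sorted(names) == sorted(frame.columns)
        scores = [s for _, s in ranking.ranking]
        assert scores == sorted(scores, reverse=True)

    def test_constant_marker_scored_zero_and_flagged(self, cohort):
        frame, truth = cohort
        x = frame.to_numpy().copy()
        x[:, 5] = 3.14
        ae = GenomicAutoencoder(40, latent_dim=8, seed=0)
        ae.fit(x, epochs=10, seed=0)
        names = [f"m{j}" for j in range(40)]
        ranking = rank_markers(x, ae.encode(x), truth, marker_names=names)
        assert "m5" in ranking.constant_markers
        assert dict(ranking.ranking)["m5"] == 0.0

    def test_noise_markers_consistent_with_permutation_null(self, rng):
        """Scores of pure-noise markers fall inside the null distribution
        obtained by permuting the sample order of a noise column."""
        spec = CohortSpec(n_samples=120, n_markers=20, latent_rank=3,
                          n_subtypes=2, cluster_separation=8.0,
                          marker_noise_sigma=0.2, seed=3)
        frame, truth = generate_genomic_cohort(spec)
        x = frame.to_numpy().copy()
        noise = rng.normal(size=120)
        x[:, -1] = noise  # a marker carrying no cluster signal
        ae = GenomicAutoencoder(20, latent_dim=4, seed=0)
        ae.fit(x, epochs=60, seed=0)
        z = ae.encode(x)
        ranking = rank_markers(x, z, truth)
        observed = dict(ranking.ranking)["marker_0020"]
        null = []
        for _ in range(200):
            x_perm = x.copy()
            x_perm[:, -1] = rng.permutation(noise)
            null.append(dict(rank_markers(x_perm, z, truth).ranking)
                        ["marker_0020"])
        # the unpermuted noise marker is not an outlier of its own null
        assert observed <= np.quantile(null, 0.99) + 1e-9
        # while a genuine signal marker sits far above that null
        top_score = ranking.ranking[0][1]
        assert top_score > np.quantile(null, 0.99) * 3


class TestIo:
    def test_read_genomic_csv_and_tsv(self, tmp_path, cohort):
        frame, _ = cohort
        frame.to_csv(tmp_path / "g.csv")
        frame.to_csv(tmp_path / "g.tsv", sep="\t")
        a = read_genomic_csv(tmp_path / "g.csv")
        b = read_genomic_csv(tmp_path / "g.tsv")
        assert np.allclose(a.to_numpy(), frame.to_numpy())
        assert list(b.columns) == list(frame.columns)
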