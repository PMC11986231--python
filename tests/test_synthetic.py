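"""Contracts of the phantom / cohort generators and the joint labeling rule."""

import dataclasses
import json

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from hepafuse.exceptions import ValidationError
from hepafuse.synthetic import (CohortSpec, PhantomSpec, JOINT_XOR_TABLE,
                                generate_genomic_cohort, generate_paired_cohort,
                                generate_phantom, modality_ceilings,
                                read_cohort, write_cohort)


class TestGeneratePhantom:
    def test_no_tumor_gives_empty_mask(self, tiny_phantom_spec):
        spec = dataclasses.replace(tiny_phantom_spec, n_tumors=0)
        image, mask = generate_phantom(spec)
        assert mask.sum() == 0
        assert image.min() >= 0 and image.max() <= 1

    def test_same_seed_bit_identical(self, tiny_phantom_spec):
        a = generate_phantom(tiny_phantom_spec)
        b = generate_phantom(tiny_phantom_spec)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_disk_area_matches_rasterizer_oracle(self):
        """A circular tumor of radius 10 on 64x64: the mask pixel count must
        match a brute-force rasterization of the analytic disk within 5%."""
        spec = PhantomSpec(height=64, width=64, n_tumors=1,
                           radius_range=(10, 10), eccentricity_range=(0, 0),
                           boundary_irregularity=0.0, seed=5)
        _, mask = generate_phantom(spec)
        # brute-force oracle: count lattice points strictly inside some
        # radius-10 circle (count is center-independent up to +-5%)
        oracle = sum(1 for y in range(64) for x in range(64)
                     if (y - 32) ** 2 + (x - 32) ** 2 < 100)
        assert oracle == pytest.approx(np.pi * 100, rel=0.05)
        assert int(mask.sum()) == pytest.approx(oracle, rel=0.05)
        assert int(mask.sum()) == pytest.approx(np.pi * 100, rel=0.05)

    def test_mask_binary_and_image_in_unit_range(self, tiny_phantom_spec):
        for seed in range(3):
            spec = dataclasses.replace(tiny_phantom_spec, seed=seed, n_tumors=2)
            image, mask = generate_phantom(spec)
            assert set(np.unique(mask)) <= {0, 1}
            assert image.min() >= 0.0 and image.max() <= 1.0

    def test_oversized_radius_rejected(self):
        with pytest.raises(ValidationError):
            generate_phantom(PhantomSpec(height=32, width=32,
                                         radius_range=(20, 30)))


class TestGenerateGenomicCohort:
    def test_noiseless_rows_identical_within_subtype(self, tiny_cohort_spec):
        spec = dataclasses.replace(tiny_cohort_spec, marker_noise_sigma=0.0)
        frame, labels = generate_genomic_cohort(spec)
        x = frame.to_numpy()
        for lab in np.unique(labels):
            rows = x[labels == lab]
            assert np.allclose(rows, rows[0])
        # distinct subtypes differ
        assert not np.allclose(x[labels == 0][0], x[labels == 1][0])

    def test_noiseless_rank_equals_latent_rank(self):
        """With more subtypes than latent factors the noiseless matrix has
        rank exactly latent_rank (checked by direct SVD)."""
        spec = CohortSpec(n_samples=30, n_markers=25, latent_rank=4,
                          n_subtypes=6, cluster_separation=5.0,
                          marker_noise_sigma=0.0, seed=3)
        frame, _ = generate_genomic_cohort(spec)
        sv = np.linalg.svd(frame.to_numpy(), compute_uv=False)
        assert int((sv > 1e-8 * sv[0]).sum()) == 4

    def test_same_seed_identical(self, tiny_cohort_spec):
        a, _ = generate_genomic_cohort(tiny_cohort_spec)
        b, _ = generate_genomic_cohort(tiny_cohort_spec)
        assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_labels_balanced(self, tiny_cohort_spec):
        _, labels = generate_genomic_cohort(tiny_cohort_spec)
        counts = np.bincount(labels)
        assert counts.max() - counts.min() <= 1

    def test_silhouette_monotone_in_separation(self):
        sils = []
        for sep in (1.0, 2.5, 4.0):
            spec = CohortSpec(n_samples=90, n_markers=30, latent_rank=4,
                              n_subtypes=3, cluster_separation=sep,
                              marker_noise_sigma=1.0, seed=21)
            frame, labels = generate_genomic_cohort(spec)
            sils.append(silhouette_score(frame.to_numpy(), labels))
        assert sils[0] <= sils[1] <= sils[2]

    def test_too_many_subtypes_rejected(self):
        with pytest.raises(ValidationError):
            CohortSpec(n_samples=2, n_subtypes=3).validate()


class TestPairedCohort:
    def test_image_only_label_is_size_stratum(self, tiny_phantom_spec,
                                              tiny_cohort_spec):
        cohort = dataclasses.replace(tiny_cohort_spec, n_samples=12,
                                     n_subtypes=2)
        samples = generate_paired_cohort(tiny_phantom_spec, cohort, "image_only")
        for s in samples:
            assert s.subtype_label == s.morphology_stratum

    def test_joint_rule_truth_table(self):
        """Enumerating the interaction table: both strata determine the label
        exactly; either stratum alone caps at the designed 0.75 ceiling."""
        t = JOINT_XOR_TABLE
        # full-information accuracy is 1.0 by construction (deterministic map)
        img_ceiling = np.mean([max(np.mean(r), 1 - np.mean(r)) for r in t])
        gen_ceiling = np.mean([max(np.mean(c), 1 - np.mean(c)) for c in t.T])
        assert img_ceiling == pytest.approx(0.75)
        assert gen_ceiling == pytest.approx(0.75)
        assert modality_ceilings("joint_xor") == (0.75, 0.75)
        assert t.sum() == t.size // 2  # balanced labels

    def test_joint_xor_labels_follow_table_and_balance(self, tiny_phantom_spec):
        cohort = CohortSpec(n_samples=32, n_markers=20, latent_rank=4,
                            n_subtypes=2, seed=5)
        samples = generate_paired_cohort(tiny_phantom_spec, cohort, "joint_xor")
        for s in samples:
            assert s.subtype_label == JOINT_XOR_TABLE[s.morphology_stratum,
                                                      s.genomic_cluster]
        labels = [s.subtype_label for s in samples]
        assert sorted(np.bincount(labels)) == [16, 16]

    def test_four_samples_two_subtypes_balanced(self, tiny_phantom_spec):
        cohort = CohortSpec(n_samples=4, n_markers=20, latent_rank=4,
                            n_subtypes=2, seed=5)
        samples = generate_paired_cohort(tiny_phantom_spec, cohort, "image_only")
        assert sorted(s.subtype_label for s in samples) == [0, 0, 1, 1]

    def test_morphology_strata_sized_disjointly(self, tiny_phantom_spec):
        cohort = CohortSpec(n_samples=32, n_markers=20, latent_rank=4,
                            n_subtypes=2, seed=5)
        samples = generate_paired_cohort(tiny_phantom_spec, cohort, "joint_xor")
        areas = {}
        for s in samples:
            areas.setdefault(s.morphology_stratum, []).append(s.mask.sum())
        means = [np.mean(areas[k]) for k in sorted(areas)]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_unknown_rule_rejected(self, tiny_phantom_spec, tiny_cohort_spec):
        with pytest.raises(ValidationError):
            generate_paired_cohort(tiny_phantom_spec, tiny_cohort_spec, "bogus")


class TestCohortIO:
    def test_round_trip(self, tmp_path, tiny_phantom_spec):
        cohort = CohortSpec(n_samples=6, n_markers=12, latent_rank=3,
                            n_subtypes=2, seed=5)
        samples = generate_paired_cohort(tiny_phantom_spec, cohort, "image_only")
        out = write_cohort(samples, tmp_path / "cohort",
                           phantom=tiny_phantom_spec, cohort=cohort,
                           joint_rule="image_only")
        loaded, manifest = read_cohort(out)
        assert manifest["joint_rule"] == "image_only"
        assert len(loaded) == 6
        for orig, back in zip(samples, loaded):
            assert back.subtype_label == orig.subtype_label
            assert np.array_equal(back.mask, orig.mask)
            # images round-trip through 8-bit PNG quantization
            assert np.abs(back.image - orig.image).max() <= 1 / 255 + 1e-12
            assert np.allclose(back.genomic_row, orig.genomic_row)

    def test_refuses_nonempty_dir(self, tmp_path, tiny_phantom_spec):
        cohort = CohortSpec(n_samples=2, n_markers=12, latent_rank=3,
                            n_subtypes=2, seed=5)
        samples = generate_paired_cohort(tiny_phantom_spec, cohort, "image_only")
        out = tmp_path / "cohort"
        write_cohort(samples, out, phantom=tiny_phantom_spec, cohort=cohort,
                     joint_rule="image_only")
        with pytest.raises(ValidationError):
            write_cohort(samples, out, phantom=tiny_phantom_spec, cohort=cohort,
                         joint_rule="image_only")

    def test_manifest_identical_for_same_seed(self, tmp_path, tiny_phantom_spec):
        cohort = CohortSpec(n_samples=4, n_markers=12, latent_rank=3,
                            n_subtypes=2, seed=5)
        manifests = []
        for name in ("a", "b"):
            samples = generate_paired_cohort(tiny_phantom_spec, cohort,
                                             "image_only")
            out = write_cohort(samples, tmp_path / name,
                               phantom=tiny_phantom_spec, cohort=cohort,
                               joint_rule="image_only")
            manifests.append((out / "manifest.json").read_text())
        assert manifests[0] == manifests[1]
        json.loads(manifests[0])  # valid JSON
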