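"""Fusion ops (projection, adaptive blend, gate, softmax head) and the
trainable classifier."""

import numpy as np
import pytest

from hepafuse.exceptions import ValidationError
from hepafuse.fusion import (FusionClassifier, GateParams, ProjectionParams,
                             attend_fused, classify, fuse, pool_image_features,
                             project, train_joint)
from hepafuse.segmentation import DepthFeatureSet


def _proj_params(d_img, d_gen, d_f, rng=None):
    if rng is None:
        w_img = np.zeros((d_img, d_f))
        w_gen = np.zeros((d_gen, d_f))
    else:
        w_img = rng.normal(size=(d_img, d_f))
        w_gen = rng.normal(size=(d_gen, d_f))
    return ProjectionParams(w_img, np.zeros(d_f), w_gen, np.zeros(d_f))


class TestPooling:
    def test_constant_feature_map_pools_to_constant(self):
        bottleneck = np.stack([np.full((3, 4, 4), c) for c in (1.0, -2.0)])
        ds = DepthFeatureSet(features=[], projections=[], bottleneck=bottleneck)
        pooled = pool_image_features(ds)
        assert pooled.shape == (2, 3)
        assert np.allclose(pooled[0], 1.0) and np.allclose(pooled[1], -2.0)

    def test_output_dim_is_channel_count(self, rng):
        ds = DepthFeatureSet(features=[], projections=[],
                             bottleneck=rng.normal(size=(5, 7, 2, 2)))
        assert pool_image_features(ds).shape == (5, 7)

    def test_pooling_commutes_with_spatial_flip(self, rng):
        fm = rng.normal(size=(2, 3, 4, 4))
        a = pool_image_features(DepthFeatureSet([], [], fm))
        b = pool_image_features(DepthFeatureSet([], [], fm[:, :, :, ::-1]))
        assert np.allclose(a, b)

    def test_missing_bottleneck_rejected(self):
        with pytest.raises(ValidationError):
            pool_image_features(DepthFeatureSet([], [], None))


class TestProject:
    def test_zero_params_annihilate(self, rng):
        params = _proj_params(3, 4, 2)
        out = project(rng.normal(size=(5, 3)), rng.normal(size=(5, 4)), params)
        assert np.allclose(out.f_img, 0) and np.allclose(out.f_gen, 0)

    def test_identity_projection_passes_through(self, rng):
        xi = rng.normal(size=(4, 3))
        xg = rng.normal(size=(4, 3))
        params = ProjectionParams(np.eye(3), np.zeros(3), np.eye(3), np.zeros(3))
        out = project(xi, xg, params)
        assert np.allclose(out.f_img, xi) and np.allclose(out.f_gen, xg)

    def test_matches_matrix_product_oracle(self, rng):
        params = _proj_params(3, 5, 4, rng)
        xi, xg = rng.normal(size=(6, 3)), rng.normal(size=(6, 5))
        out = project(xi, xg, params)
        assert np.allclose(out.f_img, xi @ params.w_img)
        assert np.allclose(out.f_gen, xg @ params.w_gen)

    def test_dim_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            project(rng.normal(size=(2, 7)), rng.normal(size=(2, 5)),
                    _proj_params(3, 5, 4, rng))


class TestFuse:
    def test_degenerate_alphas(self, rng):
        feats = project(rng.normal(size=(3, 2)), rng.normal(size=(3, 2)),
                        _proj_params(2, 2, 2, rng))
        assert np.allclose(fuse(feats, 1.0), feats.f_img)
        assert np.allclose(fuse(feats, 0.0), feats.f_gen)

    def test_midpoint(self):
        from hepafuse.fusion import ProjectedFeatures

        feats = ProjectedFeatures(np.array([[2.0, 2.0]]), np.array([[0.0, 0.0]]))
        assert np.allclose(fuse(feats, 0.5), [[1.0, 1.0]])

    def test_out_of_range_alpha_clamped_with_warning(self):
        from hepafuse.fusion import ProjectedFeatures

        feats = ProjectedFeatures(np.ones((1, 2)), np.zeros((1, 2)))
        with pytest.warns(RuntimeWarning):
            out = fuse(feats, 1.5)
        assert np.allclose(out, feats.f_img)


class TestAttendAndClassify:
    def test_saturated_gates(self, rng):
        f = rng.normal(size=(3, 4))
        open_gate = GateParams(np.zeros((4, 4)), np.full(4, 50.0))
        closed_gate = GateParams(np.zeros((4, 4)), np.full(4, -50.0))
        assert np.allclose(attend_fused(f, open_gate), f, atol=1e-12)
        assert np.allclose(attend_fused(f, closed_gate), 0.0, atol=1e-12)

    def test_gate_matches_elementwise_oracle(self):
        f = np.array([[1.0, -2.0]])
        gate = GateParams(np.array([[0.5, 0.0], [0.0, 0.25]]), np.array([0.1, -0.1]))
        pre = f @ gate.w + gate.b
        expected = f * (1 / (1 + np.exp(-pre)))
        assert np.allclose(attend_fused(f, gate), expected, atol=1e-12)

    def test_zero_weights_give_uniform_softmax(self):
        pred = classify(np.zeros((3, 5)), np.zeros((5, 4)), np.zeros(4))
        assert np.allclose(pred.probabilities, 0.25)

    def test_rows_sum_to_one(self, rng):
        pred = classify(rng.normal(size=(6, 3)) * 5, rng.normal(size=(3, 4)),
                        rng.normal(size=4))
        assert np.allclose(pred.probabilities.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(pred.probabilities > 0)

    def test_two_logit_softmax_value(self):
        pred = classify(np.array([[1.0]]), np.array([[1.0, 0.0]]), np.zeros(2))
        e = np.exp(1.0)
        assert pred.probabilities[0] == pytest.approx([e / (e + 1), 1 / (e + 1)],
                                                      abs=1e-9)


class TestFusionClassifier:
    @pytest.fixture
    def toy_data(self, rng):
        n = 60
        y = np.arange(n) % 2
        xi = rng.normal(size=(n, 6)) + 2.0 * y[:, None]
        xg = rng.normal(size=(n, 4)) - 1.5 * y[:, None]
        return xi, xg, y

    def test_learns_separable_task(self, toy_data):
        xi, xg, y = toy_data
        clf = FusionClassifier(6, 4, 2, shared_dim=8, seed=0)
        res = clf.fit(xi, xg, y, epochs=150, seed=0)
        assert res.history[-1]["accuracy"] > 0.9
        assert 0.0 < res.final_alpha < 1.0
        assert "FusionClassifier" in res.summary()

    def test_prediction_rows_stochastic_after_training(self, toy_data):
        xi, xg, y = toy_data
        clf = FusionClassifier(6, 4, 2, shared_dim=8, seed=0)
        clf.fit(xi, xg, y, epochs=5, seed=0)
        probs = clf.predict_proba(xi, xg)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_untrained_accuracy_near_chance(self, rng):
        n, s = 400, 4
        y = rng.integers(0, s, size=n)
        clf = FusionClassifier(5, 5, s, shared_dim=8, seed=1)
        clf._stats = None
        acc = float((clf.predict(rng.normal(size=(n, 5)),
                                 rng.normal(size=(n, 5))).labels == y).mean())
        assert abs(acc - 1 / s) < 0.15

    def test_frozen_alpha_one_ignores_genomics(self, toy_data, rng):
        xi, xg, y = toy_data
        clf = FusionClassifier(6, 4, 2, shared_dim=8, fixed_alpha=1.0, seed=0)
        clf.fit(xi, xg, y, epochs=10, seed=0)
        a = clf.predict_proba(xi, xg)
        b = clf.predict_proba(xi, rng.normal(size=xg.shape) * 100)
        assert np.allclose(a, b, atol=1e-10)

    def test_permutation_equivariance_over_samples(self, toy_data, rng):
        xi, xg, y = toy_data
        clf = FusionClassifier(6, 4, 2, shared_dim=8, seed=0)
        clf.fit(xi, xg, y, epochs=5, seed=0)
        perm = rng.permutation(len(y))
        probs = clf.predict_proba(xi, xg)
        probs_perm = clf.predict_proba(xi[perm], xg[perm])
        assert np.allclose(probs[perm], probs_perm, atol=1e-10)

    def test_label_range_validated(self, toy_data):
        xi, xg, _ = toy_data
        clf = FusionClassifier(6, 4, 2, shared_dim=8)
        with pytest.raises(ValidationError):
            clf.fit(xi, xg, np.full(len(xi), 5), epochs=1)


class TestTrainJoint:
    @pytest.fixture(scope="class")
    @staticmethod
    def tiny_cohort():
        from hepafuse.synthetic import (CohortSpec, PhantomSpec,
                                        generate_paired_cohort)

        phantom = PhantomSpec(height=32, width=32, n_tumors=1,
                              radius_range=(3, 9), eccentricity_range=(0, 0.3),
                              boundary_irregularity=0.1, tumor_contrast=0.4,
                              background_texture_scale=4.0, noise_sigma=0.03,
                              seed=3)
        cohort = CohortSpec(n_samples=16, n_markers=20, latent_rank=3,
                            n_subtypes=2, cluster_separation=6.0, seed=4)
        return generate_paired_cohort(phantom, cohort, "image_only")

    def test_two_stage_smoke(self, tiny_cohort):
        from hepafuse.genomics import GenomicAutoencoder
        from hepafuse.segmentation import AttentionSegmenter, SegmenterConfig

        seg = AttentionSegmenter(SegmenterConfig(n_levels=2, base_channels=4,
                                                 reduction_ratio=2, seed=0))
        images = np.stack([s.image for s in tiny_cohort])
        masks = np.stack([s.mask for s in tiny_cohort])
        seg.fit(images, masks, epochs=1, batch_size=8, validation_split=0.0,
                early_stopping=False, seed=0)
        ae = GenomicAutoencoder(20, latent_dim=4, seed=0)
        ae.fit(np.stack([s.genomic_row for s in tiny_cohort]), epochs=5, seed=0)
        res = train_joint(tiny_cohort, seg, ae, shared_dim=8, epochs=10, seed=0)
        assert len(res.history) == 10
        assert 0.0 < res.final_alpha < 1.0

    def test_end_to_end_smoke(self, tiny_cohort):
        from hepafuse.genomics import GenomicAutoencoder
        from hepafuse.segmentation import AttentionSegmenter, SegmenterConfig

        seg = AttentionSegmenter(SegmenterConfig(n_levels=2, base_channels=4,
                                                 reduction_ratio=2, seed=0))
        ae = GenomicAutoencoder(20, latent_dim=4, seed=0)
        ae.fit(np.stack([s.genomic_row for s in tiny_cohort]), epochs=2, seed=0)
        res = train_joint(tiny_cohort, seg, ae, shared_dim=8, epochs=2,
                          end_to_end=True, seg_loss_weight=0.1, seed=0)
        assert len(res.history) == 2
        assert np.isfinite(res.history[-1]["loss"])
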