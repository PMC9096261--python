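"""Dual-branch model: wiring contracts, losses, trainability."""

import math

import numpy as np
import pytest

import roifuse as rf
from roifuse.network import autodiff as ad
from roifuse.network.layers import Adam
from roifuse.network.model import synthetic_inputs
from roifuse.network.train import (ModelDataset, TrainConfig, prepare_dataset,
                                   train_step)

TINY = rf.BranchConfig(input_shape=(8, 8, 8), conv_channels=(2, 3, 4),
                       latent_dim=8, dropout_rate=0.3)


def tiny_inputs(rng, n=2, modalities=("MRI", "PET")):
    return {m: (rng.normal(size=(n, 8, 8, 8)), rng.normal(size=(n, 8, 8, 8)))
            for m in modalities}


@pytest.fixture
def rng():
    return np.random.default_rng(11)


class TestModelContracts:
    def test_probabilities_normalized(self, rng):
        model = rf.build_model({"MRI": TINY, "PET": TINY}, seed=1)
        probs, _, _ = model.forward(tiny_inputs(rng), training=False)
        assert probs.shape == (2, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_reconstruction_shape_mirrors_input(self, rng):
        model = rf.build_model({"MRI": TINY, "PET": TINY}, seed=1)
        _, _, recons = model.forward(tiny_inputs(rng), training=False)
        for m in ("MRI", "PET"):
            assert recons[m].data.shape == (2, 1, 8, 8, 8)

    def test_eval_mode_deterministic(self, rng):
        model = rf.build_model({"MRI": TINY}, seed=2)
        inputs = tiny_inputs(rng, modalities=("MRI",))
        p1, _, r1 = model.forward(inputs, training=False)
        p2, _, r2 = model.forward(inputs, training=False)
        np.testing.assert_array_equal(p1, p2)
        np.testing.assert_array_equal(r1["MRI"].data, r2["MRI"].data)

    def test_latent_dimension_and_determinism(self, rng):
        model = rf.build_model({"MRI": TINY}, seed=3)
        x = rng.normal(size=(4, 8, 8, 8))
        z1 = model.encode("MRI", x)
        z2 = model.encode("MRI", x)
        assert z1.shape == (4, TINY.latent_dim)
        np.testing.assert_array_equal(z1, z2)

    def test_single_modality_keeps_dual_branch(self, rng):
        model = rf.build_model({"PET": TINY}, seed=4)
        probs, _, recons = model.forward(tiny_inputs(rng, modalities=("PET",)),
                                         training=False)
        assert probs.shape == (2, 2) and "PET" in recons

    def test_no_modality_rejected(self):
        with pytest.raises(ValueError):
            rf.build_model({})

    def test_incompatible_shapes_rejected(self):
        other = rf.BranchConfig(input_shape=(16, 16, 16))
        with pytest.raises(ValueError, match="incompatible"):
            rf.build_model({"MRI": TINY, "PET": other})

    def test_severed_cross_concat_ignores_synthetic(self, rng):
        """With cross_mode='none' the classifier only sees the CNN path."""
        model = rf.build_model({"MRI": TINY}, seed=5, cross_mode="none")
        x = rng.normal(size=(2, 8, 8, 8))
        p1, _, _ = model.forward({"MRI": (x, rng.normal(size=(2, 8, 8, 8)))},
                                 training=False)
        p2, _, _ = model.forward({"MRI": (x, rng.normal(size=(2, 8, 8, 8)))},
                                 training=False)
        np.testing.assert_array_equal(p1, p2)

    def test_bidirectional_cross_concat_sees_synthetic(self, rng):
        model = rf.build_model({"MRI": TINY}, seed=5, cross_mode="bidirectional")
        x = rng.normal(size=(2, 8, 8, 8))
        p1, _, _ = model.forward({"MRI": (x, rng.normal(size=(2, 8, 8, 8)))},
                                 training=False)
        p2, _, _ = model.forward({"MRI": (x, rng.normal(size=(2, 8, 8, 8)))},
                                 training=False)
        assert not np.array_equal(p1, p2)

    def test_cnn_only_ablation_has_no_reconstruction(self, rng):
        model = rf.build_model({"MRI": TINY}, seed=6, use_cae=False)
        x = rng.normal(size=(2, 8, 8, 8))
        probs, _, recons = model.forward({"MRI": (x, None)}, training=False)
        assert recons == {} and probs.shape == (2, 2)


class TestLosses:
    def test_reconstruction_loss_identity(self, rng):
        x = rng.normal(size=(4, 4, 4))
        assert rf.reconstruction_loss(x, x) == 0.0

    def test_reconstruction_loss_unit_difference(self):
        assert rf.reconstruction_loss(np.ones((3, 5, 2)),
                                      np.zeros((3, 5, 2))) == pytest.approx(1.0)

    def test_reconstruction_loss_brute_force(self, rng):
        a = rng.normal(size=(3, 4, 5))
        b = rng.normal(size=(3, 4, 5))
        acc, n = 0.0, 0
        for i in range(3):
            for j in range(4):
                for k in range(5):
                    acc += (a[i, j, k] - b[i, j, k]) ** 2
                    n += 1
        assert rf.reconstruction_loss(a, b) == pytest.approx(acc / n, rel=1e-12)

    def test_reconstruction_loss_shape_mismatch(self):
        with pytest.raises(ValueError):
            rf.reconstruction_loss(np.zeros((2, 2, 2)), np.zeros((2, 2, 3)))

    def test_classification_loss_closed_forms(self):
        assert rf.classification_loss([0.0, 1.0], 1) == pytest.approx(0.0)
        assert rf.classification_loss([0.5, 0.5], 0) == pytest.approx(math.log(2))

    def test_classification_loss_batch_mean_oracle(self, rng):
        probs = [[0.9, 0.1], [0.2, 0.8], [0.5, 0.5], [0.3, 0.7]]
        labels = [0, 1, 1, 0]
        per_item = [-math.log(p[y]) for p, y in zip(probs, labels)]
        batch = np.mean([rf.classification_loss(p, y)
                         for p, y in zip(probs, labels)])
        assert batch == pytest.approx(np.mean(per_item), rel=1e-12)

    def test_classification_loss_invalid_inputs(self):
        with pytest.raises(ValueError):
            rf.classification_loss([0.7, 0.6], 0)
        with pytest.raises(ValueError):
            rf.classification_loss([0.5, 0.5], 2)

    def test_total_loss_arithmetic(self):
        w = rf.LossWeights(lambda_recon=1.0, lambda_cls=1.0)
        assert rf.total_loss(0.5, {"MRI": 0.2, "PET": 0.3}, w) == pytest.approx(1.0)
        w0 = rf.LossWeights(lambda_recon=0.0, lambda_cls=2.0)
        assert rf.total_loss(0.5, {"MRI": 9.9}, w0) == pytest.approx(1.0)
        w2 = rf.LossWeights(lambda_recon=2.0, lambda_cls=2.0)
        assert rf.total_loss(0.5, {"MRI": 0.2, "PET": 0.3}, w2) == pytest.approx(2.0)

    def test_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            rf.LossWeights(lambda_recon=0.0, lambda_cls=0.0)


class TestReconstructionTarget:
    def test_masked_outside_affected(self, small_atlas, small_effects):
        s = rf.simulate_subject(small_atlas, "AD", small_effects, seed=1)
        target = rf.reconstruction_target(s, small_atlas, "PET",
                                          roi_subset=[1, 2, 3])
        outside = ~np.isin(small_atlas.labels, [1, 2, 3])
        assert np.all(target[outside] == 0.0)

    def test_equals_full_synthetic_on_members(self, small_atlas, small_effects):
        s = rf.simulate_subject(small_atlas, "AD", small_effects, seed=1)
        target = rf.reconstruction_target(s, small_atlas, "MRI",
                                          roi_subset=[1, 2, 3])
        full = synthetic_inputs(s, small_atlas, "MRI")
        inside = np.isin(small_atlas.labels, [1, 2, 3])
        np.testing.assert_array_equal(target[inside], full[inside])

    def test_two_region_voxel_census(self):
        atlas = rf.make_toy_atlas((8, 8, 8), 2, seed=2)
        eff = rf.EffectSpec(affected_rois=frozenset({1}), noise_sd=0.0)
        s = rf.simulate_subject(atlas, "AD", eff, seed=0)
        target = rf.reconstruction_target(s, atlas, "PET", roi_subset=[1])
        nonzero = np.argwhere(target != 0)
        region1 = np.argwhere(atlas.labels == 1)
        assert {tuple(v) for v in nonzero} == {tuple(v) for v in region1}


class TestTrainability:
    def test_one_adam_step_decreases_loss(self, small_atlas, small_effects):
        """One lr-1e-4 step lowers the joint loss in >= 19/20 seeded trials."""
        subs, _ = rf.simulate_cohort(small_atlas, {"NC": 4, "AD": 4},
                                     small_effects, seed=5)
        labels = [1 if s.class_label == "AD" else 0 for s in subs]
        ds = prepare_dataset(subs, small_atlas, labels, modalities=("MRI",),
                             downsample=2)
        cfg = rf.BranchConfig(input_shape=(8, 8, 8), conv_channels=(2, 3, 4),
                              latent_dim=8, dropout_rate=0.0)
        w = rf.LossWeights()
        idx = np.arange(8)
        wins = 0
        for seed in range(20):
            model = rf.build_model({"MRI": cfg}, seed=seed)
            opt = Adam(model.parameters(), lr=1e-4)
            l0 = train_step(model, ds, idx, opt, w)
            l1 = train_step(model, ds, idx, opt, w)
            wins += l1 < l0
        assert wins >= 19

    def test_unit_normal_init_option(self, rng):
        model = rf.build_model({"MRI": TINY}, seed=0, init="unit_normal")
        w = model.branches["MRI"].cnn_convs[0].w.data
        assert 0.5 < w.std() < 1.5  # unit-SD draw, not fan-in scaled
        he = rf.build_model({"MRI": TINY}, seed=0).branches["MRI"].cnn_convs[0].w.data
        assert he.std() < w.std()
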