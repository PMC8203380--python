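"""Loss functions: analytic values, oracle agreement, invariants."""

import numpy as np
import pytest

from cascadegan import nn
from cascadegan import losses as L
from cascadegan import reference as R
from cascadegan.checks import ORACLE_TOL, run_oracle_suite
from cascadegan.networks import (ConfigurationError, DiscriminatorSpec,
                                 build_patch_discriminator)
from cascadegan.nn import Tensor


def const_map(v, shape=(1, 3, 3)):
    return Tensor(np.full(shape, v, dtype=np.float64))


class TestGanLoss:
    def test_vanilla_at_even_odds_is_ln2(self):
        # pre-sigmoid score 0 -> sigmoid 0.5 -> BCE = ln 2
        assert L.gan_loss("vanilla", const_map(0.0), True).item() == \
            pytest.approx(np.log(2), abs=1e-12)
        assert L.gan_loss("vanilla", const_map(0.0), False).item() == \
            pytest.approx(np.log(2), abs=1e-12)

    def test_lsgan_at_half_score(self):
        assert L.gan_loss("lsgan", const_map(0.5), True).item() == \
            pytest.approx(0.25)
        assert L.gan_loss("lsgan", const_map(0.5), False).item() == \
            pytest.approx(0.25)

    def test_wgangp_is_signed_mean(self):
        assert L.gan_loss("wgangp", const_map(1.0), True).item() == -1.0
        assert L.gan_loss("wgangp", const_map(1.0), False).item() == 1.0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigurationError):
            L.gan_loss("hinge", const_map(0.0), True)

    def test_nan_scores_rejected(self):
        with pytest.raises(L.NumericError):
            L.gan_loss("lsgan", const_map(np.nan), True)


class TestCycleLoss:
    def test_perfect_round_trip_is_zero(self):
        x = Tensor(np.random.default_rng(0).normal(0, 1, (1, 1, 4, 4)))
        assert L.cycle_loss(x, x, x, x).item() == 0.0

    def test_constant_offset_gives_mean_abs(self):
        x = const_map(0.2, (1, 1, 4, 4))
        xr = const_map(0.7, (1, 1, 4, 4))
        assert L.cycle_loss(x, xr, x, x).item() == pytest.approx(0.5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            L.cycle_loss(const_map(0, (1, 1, 4, 4)), const_map(0, (1, 1, 2, 2)),
                         const_map(0, (1, 1, 4, 4)), const_map(0, (1, 1, 4, 4)))


class TestCascadeL1:
    def test_exact_predictions_give_zero(self):
        t = const_map(0.3, (1, 1, 2, 2))
        assert L.cascade_l1_loss([t, t], t, (0.5, 0.5)).item() == 0.0

    def test_published_weight_example(self):
        # per-cascade mean errors (0.3, 0.2, 0.6) under ω=(1/3,1/2,1/6)
        t = const_map(0.0, (1, 1, 2, 2))
        preds = [const_map(v, (1, 1, 2, 2)) for v in (0.3, 0.2, 0.6)]
        got = L.cascade_l1_loss(preds, t, (1 / 3, 1 / 2, 1 / 6)).item()
        assert got == pytest.approx(0.3, abs=1e-12)

    def test_weight_length_mismatch_rejected(self):
        t = const_map(0.0, (1, 1, 2, 2))
        with pytest.raises(ConfigurationError):
            L.cascade_l1_loss([t], t, (0.5, 0.5))

    def test_homogeneity_in_weights(self):
        rng = np.random.default_rng(3)
        t = Tensor(rng.normal(0, 1, (1, 1, 4, 4)))
        preds = [Tensor(rng.normal(0, 1, (1, 1, 4, 4))) for _ in range(3)]
        w = rng.uniform(0.1, 1, 3)
        base = L.cascade_l1_loss(preds, t, w).item()
        scaled = L.cascade_l1_loss(preds, t, 3.0 * w).item()
        assert scaled == pytest.approx(3.0 * base, rel=1e-9)


class TestCascadeAdversarial:
    @pytest.fixture()
    def disc(self):
        d = build_patch_discriminator(
            DiscriminatorSpec(base_channels=4), seed=0)
        for p in d.parameters():
            p.data = p.data.astype(np.float64)
        return d

    def test_zero_weight_cascades_do_not_contribute(self, disc):
        rng = np.random.default_rng(1)
        cond = Tensor(rng.normal(0, 1, (1, 1, 64, 64)))
        tgt = Tensor(rng.normal(0, 1, (1, 1, 64, 64)))
        preds = [Tensor(rng.normal(0, 1, (1, 1, 64, 64))) for _ in range(3)]
        d1, g1 = L.cascade_adversarial_losses(disc, cond, tgt, preds,
                                              (1, 0, 0), "lsgan")
        preds2 = [preds[0]] + [Tensor(rng.normal(0, 1, (1, 1, 64, 64)))
                               for _ in range(2)]
        d2, g2 = L.cascade_adversarial_losses(disc, cond, tgt, preds2,
                                              (1, 0, 0), "lsgan")
        assert d1.item() == d2.item() and g1.item() == g2.item()

    def test_constant_half_critic_analytic_values(self):
        class Half(nn.Module):
            def forward(self, x):
                return Tensor(np.full((x.shape[0], 3, 3), 0.5))

        cond = const_map(0.0, (1, 1, 8, 8))
        d_loss, g_loss = L.cascade_adversarial_losses(
            Half(), cond, cond, [cond], (1.0,), "lsgan")
        assert d_loss.item() == pytest.approx(0.5)   # 0.25 real + 0.25 fake
        assert g_loss.item() == pytest.approx(0.25)

    def test_discriminator_update_cannot_reach_generators(self, disc):
        """d_loss must be built on detached predictions."""
        rng = np.random.default_rng(5)
        cond = Tensor(rng.normal(0, 1, (1, 1, 64, 64)))
        tgt = Tensor(rng.normal(0, 1, (1, 1, 64, 64)))
        pred_leaf = Tensor(rng.normal(0, 1, (1, 1, 64, 64)),
                           requires_grad=True)
        d_loss, g_loss = L.cascade_adversarial_losses(
            disc, cond, tgt, [pred_leaf], (1.0,), "lsgan")
        d_loss.backward()
        assert pred_leaf.grad is None
        g_loss.backward()
        assert pred_leaf.grad is not None


class TestGradientPenalty:
    def test_sum_critic_on_2x2(self):
        # D = sum of pixels: gradient is 1 per pixel, ||grad|| = 2
        def d(cond, img):
            return nn.sum_(img)

        z = Tensor(np.zeros((1, 1, 2, 2)))
        pen = L.gradient_penalty(d, z, Tensor(np.ones((1, 1, 2, 2))),
                                 Tensor(np.zeros((1, 1, 2, 2))),
                                 np.random.default_rng(0))
        assert pen.item() == pytest.approx(1.0, abs=1e-9)

    def test_constant_critic_penalty_is_one(self):
        def d(cond, img):
            return nn.sum_(img * 0.0)

        z = Tensor(np.zeros((1, 1, 2, 2)))
        pen = L.gradient_penalty(d, z, Tensor(np.ones((1, 1, 2, 2))), z,
                                 np.random.default_rng(0))
        assert pen.item() == pytest.approx(1.0, abs=1e-5)

    def test_penalty_nonnegative_for_random_critics(self):
        d = build_patch_discriminator(
            DiscriminatorSpec(in_channels=1, base_channels=4), seed=2,
            norm="none")

        def apply(cond, img):
            return d(img)

        rng = np.random.default_rng(0)
        for i in range(5):
            pen = L.gradient_penalty(
                apply, Tensor(np.zeros((1, 1, 64, 64))),
                Tensor(rng.normal(0, 1, (1, 1, 64, 64)).astype(np.float32)),
                Tensor(rng.normal(0, 1, (1, 1, 64, 64)).astype(np.float32)),
                np.random.default_rng(i))
            assert pen.item() >= 0.0

    def test_penalty_is_trainable(self):
        """The penalty must backpropagate into critic parameters."""
        d = build_patch_discriminator(
            DiscriminatorSpec(in_channels=1, base_channels=4), seed=2,
            norm="none")

        def apply(cond, img):
            return d(img)

        rng = np.random.default_rng(0)
        pen = L.gradient_penalty(
            apply, Tensor(np.zeros((1, 1, 32, 32))),
            Tensor(rng.normal(0, 1, (1, 1, 32, 32)).astype(np.float32)),
            Tensor(rng.normal(0, 1, (1, 1, 32, 32)).astype(np.float32)),
            np.random.default_rng(0))
        pen.backward()
        norms = [np.abs(p.grad.data).max() for p in d.parameters()
                 if p.grad is not None]
        assert norms and max(norms) > 0


class TestPerceptual:
    def test_identical_prediction_gives_zero_both_modes(self):
        ext = L.RandomFeatureExtractor(seed=1)
        t = Tensor(np.random.default_rng(0).normal(0, 1, (1, 1, 8, 8)).astype(np.float32))
        for mode in ("manh", "cosine"):
            assert L.perceptual_loss(ext, [t], t, mode).item() == \
                pytest.approx(0.0, abs=1e-6)

    def test_manh_identity_extractor_mean_abs(self):
        class Ident(nn.Module):
            def forward(self, x):
                return [x]

        t = const_map(1.0, (1, 1, 2, 2))
        p = const_map(0.0, (1, 1, 2, 2))
        assert L.perceptual_loss(Ident(), [p], t, "manh").item() == \
            pytest.approx(1.0)

    def test_cosine_orthogonal_maps(self):
        class Flat(nn.Module):
            def forward(self, x):
                return [nn.reshape(x, (1, 1, 1, 2))]

        t = Tensor(np.array([[[[1.0, 0.0]]]]))
        p = Tensor(np.array([[[[0.0, 1.0]]]]))
        got = L.perceptual_loss(Flat(), [p], t, "cosine").item()
        assert got == pytest.approx(1.0, abs=1e-6)

    def test_empty_predictions_rejected(self):
        with pytest.raises(ConfigurationError):
            L.perceptual_loss(L.RandomFeatureExtractor(), [],
                              const_map(0, (1, 1, 8, 8)), "manh")

    def test_extractor_is_deterministic_and_frozen(self):
        e1 = L.RandomFeatureExtractor(seed=4)
        e2 = L.RandomFeatureExtractor(seed=4)
        x = Tensor(np.random.default_rng(0).normal(0, 1, (1, 1, 16, 16)).astype(np.float32))
        f1, f2 = e1(x), e2(x)
        for a, b in zip(f1, f2):
            assert np.array_equal(a.data, b.data)
        assert all(not p.requires_grad for p in e1.parameters())


class TestTotals:
    def test_translation_total_example(self):
        got = L.translation_total_loss(Tensor(np.float64(0.2)),
                                       Tensor(np.float64(0.5)),
                                       Tensor(np.float64(0.5)), 10.0)
        assert got.item() == pytest.approx(3.0)

    def test_segmentation_total_example(self):
        got = L.segmentation_total_loss(Tensor(np.float64(0.01)),
                                        Tensor(np.float64(0.3)),
                                        Tensor(np.float64(0.2)))
        assert got.item() == pytest.approx(1.5)

    def test_all_zero_parts_give_zero(self):
        z = Tensor(np.float64(0.0))
        assert L.translation_total_loss(z, z, z).item() == 0.0
        assert L.segmentation_total_loss(z, z, z).item() == 0.0


class TestLossConfig:
    def test_defaults_match_published_protocol(self):
        cfg = L.LossConfig()
        assert cfg.lambda_1 == 10.0
        assert cfg.lambda_l == 100.0
        assert cfg.lambda_vgg == 1.0
        assert cfg.omega_g == cfg.omega_1

    def test_negative_weights_rejected(self):
        with pytest.raises(ConfigurationError):
            L.LossConfig(omega_g=(-0.5, 1.0), omega_1=(0.5, 0.5))

    def test_mismatched_weight_lengths_rejected(self):
        with pytest.raises(ConfigurationError):
            L.LossConfig(omega_g=(1.0,), omega_1=(0.5, 0.5))


def test_oracle_suite_within_tolerance():
    """Every vectorised loss agrees with its nested-loop reference on 50
    seeded random tiny instances."""
    dev = run_oracle_suite(seed=0, n_instances=50)
    assert len(dev) >= 15
    worst = max(dev, key=dev.get)
    assert dev[worst] <= ORACLE_TOL, (worst, dev[worst])


def test_oracle_suite_detects_a_broken_loss():
    dev = run_oracle_suite(seed=0, n_instances=2, perturb=1e-4)
    assert any(v > ORACLE_TOL for v in dev.values())
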