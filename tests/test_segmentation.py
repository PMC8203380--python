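"""Stage II segmentation: codec, training contracts, inference paths."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cascadegan import nn
from cascadegan.config import TrainConfig
from cascadegan.losses import (LossConfig, cascade_l1_loss,
                               cascade_adversarial_losses,
                               segmentation_total_loss)
from cascadegan.networks import ConfigurationError, cascade_forward
from cascadegan.phantom import make_dataset
from cascadegan.segmentation import (DataError, MaskCodec, build_seg_model,
                                     evaluate_segmentation, load_seg_model,
                                     mixed_training_set, segment,
                                     segment_lge_indirect, train_segmentation)
from cascadegan.translation import TranslationModel, _as_batch


@pytest.fixture(scope="module")
def tiny_pairs(tiny_params):
    ds = make_dataset(tiny_params, 6, seed=8, paired=True)
    return [(s.image_B, s.mask) for s in ds.samples_a]


def _tiny_loss_config(**kw):
    base = dict(gan_mode="lsgan", perceptual_mode="off",
                omega_g=(0.5, 0.5), omega_1=(0.5, 0.5))
    base.update(kw)
    return LossConfig(**base)


def _tiny_train(tiny_pairs, seed=0, epochs=1, **kw):
    return train_segmentation(tiny_pairs, _tiny_loss_config(),
                              TrainConfig(epochs=epochs, lr=2e-4, seed=seed),
                              base_channels=4, first_depth=3, **kw)


class TestMaskCodec:
    def test_levels_equally_spaced_and_symmetric(self):
        codec = MaskCodec()
        lv = np.asarray(codec.levels)
        assert np.allclose(lv + lv[::-1], 0.0)
        assert np.allclose(np.diff(lv), 2.0 / 3.0)

    def test_all_background_encodes_to_constant(self):
        codec = MaskCodec()
        img = codec.encode(np.zeros((8, 8), dtype=np.int16))
        assert np.all(img == -1.0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_round_trip_identity(self, seed):
        codec = MaskCodec()
        mask = np.random.default_rng(seed).integers(0, 4, (16, 16)).astype(np.int16)
        assert np.array_equal(codec.decode(codec.encode(mask)), mask)

    def test_injective_on_distinct_masks(self):
        codec = MaskCodec()
        a = np.zeros((4, 4), dtype=np.int16)
        b = a.copy()
        b[0, 0] = 3
        assert not np.array_equal(codec.encode(a), codec.encode(b))

    def test_noise_below_half_gap_decodes_exactly(self):
        codec = MaskCodec()
        mask = np.random.default_rng(0).integers(0, 4, (16, 16)).astype(np.int16)
        enc = codec.encode(mask)
        noise = np.random.default_rng(1).uniform(-0.3, 0.3, enc.shape)
        # half the minimum level gap is 1/3
        assert np.array_equal(codec.decode(enc + noise * (1 / 3) / 0.3 * 0.99),
                              mask)

    def test_midpoint_ties_go_to_lower_class(self):
        codec = MaskCodec()
        mid = (codec.levels[0] + codec.levels[1]) / 2.0
        assert codec.decode(np.full((2, 2), mid))[0, 0] == 0

    def test_unknown_label_rejected(self):
        with pytest.raises(DataError):
            MaskCodec().encode(np.full((2, 2), 9, dtype=np.int16))

    def test_duplicate_levels_rejected(self):
        with pytest.raises(ConfigurationError):
            MaskCodec(levels=(-1.0, 0.0, 0.0, 1.0))


class TestTraining:
    def test_seed_determinism(self, tiny_pairs):
        m1 = _tiny_train(tiny_pairs)
        m2 = _tiny_train(tiny_pairs)
        assert m1.digest() == m2.digest()
        assert m1.digest() != _tiny_train(tiny_pairs, seed=3).digest()

    def test_history_schema(self, tiny_pairs):
        m = _tiny_train(tiny_pairs, epochs=2)
        assert len(m.history) == 2
        assert {"L1", "L_gan", "L_vgg", "L_D", "total"} <= set(m.history[0])

    def test_empty_dataset_rejected(self):
        with pytest.raises(DataError):
            train_segmentation([], _tiny_loss_config(), TrainConfig(epochs=1))

    def test_weight_length_mismatch_rejected(self, tiny_pairs):
        model = build_seg_model(3, 32, base_channels=4, first_depth=3)
        with pytest.raises(ConfigurationError):
            train_segmentation(tiny_pairs, _tiny_loss_config(),
                               TrainConfig(epochs=1), model=model)

    def test_zero_weight_cascade_receives_zero_generation_gradient(self, tiny_pairs):
        """With ω = (1, 0) the generation loss must not move G_2."""
        model = build_seg_model(2, 32, base_channels=4, seed=0, first_depth=3)
        lc = _tiny_loss_config(omega_g=(1.0, 0.0), omega_1=(1.0, 0.0))
        img, mask = tiny_pairs[0]
        cond = _as_batch(img)
        target = _as_batch(model.codec.encode(mask))
        preds = cascade_forward(model.generators, cond, condition=cond)
        _, g_gan = cascade_adversarial_losses(
            model.discriminator, cond, target, preds, lc.omega_g, "lsgan")
        l1 = cascade_l1_loss(preds, target, lc.omega_1)
        total = segmentation_total_loss(l1, g_gan, nn.Tensor(np.float32(0.0)))
        model.generators[0].zero_grad()
        model.generators[1].zero_grad()
        total.backward()
        g2_norms = [0.0 if p.grad is None else float(np.abs(p.grad.data).max())
                    for p in model.generators[1].parameters()]
        assert max(g2_norms) == 0.0
        g1_norms = [0.0 if p.grad is None else float(np.abs(p.grad.data).max())
                    for p in model.generators[0].parameters()]
        assert max(g1_norms) > 0.0

    def test_freeze_prior_flag_trains(self, tiny_pairs):
        m = _tiny_train(tiny_pairs, freeze_prior=True)
        assert len(m.history) == 1


class TestInference:
    def test_cascade_output_length_and_labels(self, tiny_pairs):
        m = _tiny_train(tiny_pairs)
        mask, cascade = segment(m, tiny_pairs[0][0])
        assert len(cascade) == m.n_cascades
        assert set(np.unique(mask)) <= {0, 1, 2, 3}
        assert mask.shape == tiny_pairs[0][0].shape

    def test_deterministic(self, tiny_pairs):
        m = _tiny_train(tiny_pairs)
        m1, c1 = segment(m, tiny_pairs[0][0])
        m2, c2 = segment(m, tiny_pairs[0][0])
        assert np.array_equal(m1, m2)
        for a, b in zip(c1, c2):
            assert np.array_equal(a, b)

    def test_size_mismatch_rejected(self, tiny_pairs):
        m = _tiny_train(tiny_pairs)
        with pytest.raises(DataError):
            segment(m, np.zeros((64, 64), dtype=np.float32))


class _IdentityGen(nn.Module):
    def forward(self, x):
        return x


class TestIndirectPath:
    def _identity_tmodel(self, size=32):
        return TranslationModel(g_a=_IdentityGen(), g_b=_IdentityGen(),
                                d_a=_IdentityGen(), d_b=_IdentityGen(),
                                image_size=size)

    def test_equals_manual_composition(self, tiny_pairs, tiny_params):
        from cascadegan.translation import translate
        sm = _tiny_train(tiny_pairs)
        tm = self._identity_tmodel()
        ds = make_dataset(tiny_params, 2, seed=33, paired=True)
        img = ds.samples_a[0].image_A
        via_op = segment_lge_indirect(tm, sm, img)
        manual, _ = segment(sm, translate(tm, img, "A2B"))
        assert np.array_equal(via_op, manual)

    def test_identity_translation_equals_direct(self, tiny_pairs):
        sm = _tiny_train(tiny_pairs)
        tm = self._identity_tmodel()
        img = tiny_pairs[0][0]
        assert np.array_equal(segment_lge_indirect(tm, sm, img),
                              segment(sm, img)[0])

    def test_size_mismatch_between_stages_rejected(self, tiny_pairs):
        sm = _tiny_train(tiny_pairs)
        tm = self._identity_tmodel(size=64)
        with pytest.raises(ConfigurationError):
            segment_lge_indirect(tm, sm, tiny_pairs[0][0])


class TestEvaluate:
    def test_perfect_predictions_score_one(self, tiny_pairs):
        lookup = {im.tobytes(): m for im, m in tiny_pairs}
        table = evaluate_segmentation(
            lambda img: lookup[img.tobytes()], tiny_pairs)
        for rep in table.values():
            assert rep.mean == 1.0 and rep.sd == 0.0

    def test_all_background_scores_zero_per_foreground_class(self, tiny_pairs):
        table = evaluate_segmentation(
            lambda img: np.zeros_like(tiny_pairs[0][1]), tiny_pairs)
        assert list(table) == ["LV", "MYO", "RV"]
        for rep in table.values():
            assert rep.mean == 0.0

    def test_empty_dataset_rejected(self):
        with pytest.raises(ConfigurationError):
            evaluate_segmentation(lambda img: img, [])


class TestPersistence:
    def test_save_load_round_trip(self, tiny_pairs, tmp_path):
        m = _tiny_train(tiny_pairs)
        m.save(str(tmp_path / "sm"))
        r = load_seg_model(str(tmp_path / "sm"))
        assert r.digest() == m.digest()
        a, _ = segment(m, tiny_pairs[0][0])
        b, _ = segment(r, tiny_pairs[0][0])
        assert np.array_equal(a, b)


def test_mixed_training_set_fake_fraction(tiny_params, tiny_pairs):
    ds = make_dataset(tiny_params, 6, seed=8, paired=True)

    class _Ident(nn.Module):
        def forward(self, x):
            return x

    tm = TranslationModel(g_a=_Ident(), g_b=_Ident(), d_a=_Ident(),
                          d_b=_Ident(), image_size=32)
    pairs = mixed_training_set(ds.samples_a, tm, fake_fraction=0.5,
                               rng=np.random.default_rng(0))
    assert len(pairs) == 6 + 3
    none = mixed_training_set(ds.samples_a, None)
    assert len(none) == 6
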