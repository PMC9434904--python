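"""Pix2pix translator: architecture contracts, loss law, determinism."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retfusion import (Pix2PixModel, TrainConfig, build_discriminator,
                       build_generator, composite_generator_loss, train,
                       translate)
from retfusion.errors import ParameterError
from retfusion.translator import (PatchDiscriminator, UNetGenerator,
                                  coerce_pairs)


def tiny_config(**kw):
    base = dict(image_size=32, epochs=2, checkpoint_interval_epochs=1,
                base_channels=4, disc_channels=4, seed=7)
    base.update(kw)
    return TrainConfig(**base)


@pytest.fixture(scope="module")
def tiny_pairs(samples32=None):
    rng = np.random.default_rng(5)
    return [(rng.integers(0, 256, (32, 32, 3), dtype=np.uint8),
             rng.integers(0, 256, (32, 32, 3), dtype=np.uint8))
            for _ in range(3)]


class TestConfig:
    def test_non_power_of_two_rejected(self):
        with pytest.raises(ParameterError):
            TrainConfig(image_size=48)

    def test_too_small_rejected(self):
        with pytest.raises(ParameterError):
            TrainConfig(image_size=16)

    def test_epochs_below_interval_rejected(self):
        with pytest.raises(ParameterError):
            TrainConfig(image_size=32, epochs=5, checkpoint_interval_epochs=10)

    @given(st.integers(1, 400), st.integers(1, 50))
    @settings(max_examples=60, deadline=None)
    def test_checkpoint_count_floor_law(self, epochs, interval):
        if epochs < interval:
            return
        cfg = TrainConfig(image_size=32, epochs=epochs,
                          checkpoint_interval_epochs=interval)
        assert cfg.n_checkpoints == epochs // interval

    def test_paper_scale_defaults_give_twenty_checkpoints(self):
        cfg = TrainConfig()
        assert cfg.epochs == 200 and cfg.checkpoint_interval_epochs == 10
        assert cfg.n_checkpoints == 20
        assert cfg.lambda_l1 == 100.0 and cfg.image_size == 512


class TestGenerator:
    def test_output_shape_matches_input(self):
        gen = build_generator(tiny_config(image_size=64))
        x = np.zeros((1, 3, 64, 64), dtype=np.float32)
        assert gen.forward(x).shape == (1, 3, 64, 64)

    def test_output_bounded_by_tanh(self):
        gen = build_generator(tiny_config())
        x = np.random.default_rng(0).standard_normal((1, 3, 32, 32)).astype(np.float32)
        y = gen.forward(x)
        assert np.all(y >= -1.0) and np.all(y <= 1.0)

    def test_depth_scales_with_size(self):
        assert UNetGenerator(32, ngf=4).levels == 5
        assert UNetGenerator(128, ngf=4).levels == 7

    def test_invalid_size_rejected(self):
        with pytest.raises(ParameterError):
            UNetGenerator(48, ngf=4)


class TestDiscriminator:
    def test_emits_spatial_score_grid(self):
        disc = build_discriminator(tiny_config())
        s = np.zeros((1, 3, 32, 32), dtype=np.float32)
        z = disc.forward(s, s)
        assert z.ndim == 4 and z.shape[2] > 1 and z.shape[3] > 1

    def test_grid_is_30x30_at_256(self):
        disc = PatchDiscriminator(ndf=2)
        s = np.zeros((1, 3, 256, 256), dtype=np.float32)
        assert disc.forward(s, s).shape == (1, 1, 30, 30)

    def test_candidate_swap_changes_scores_not_shape(self):
        rng = np.random.default_rng(1)
        disc = build_discriminator(tiny_config())
        s = rng.standard_normal((1, 3, 32, 32)).astype(np.float32)
        a = rng.standard_normal((1, 3, 32, 32)).astype(np.float32)
        b = rng.standard_normal((1, 3, 32, 32)).astype(np.float32)
        za, zb = disc.forward(s, a), disc.forward(s, b)
        assert za.shape == zb.shape and not np.array_equal(za, zb)

    def test_mismatched_dims_rejected(self):
        disc = build_discriminator(tiny_config())
        with pytest.raises(ParameterError):
            disc.forward(np.zeros((1, 3, 32, 32), np.float32),
                         np.zeros((1, 3, 16, 16), np.float32))


class TestCompositeLoss:
    def test_printed_formula(self):
        assert composite_generator_loss(1.0, 1.0, 100.0).generator_loss == 101.0

    def test_zero_l1_degenerates_to_adversarial(self):
        assert composite_generator_loss(0.7, 0.0, 100.0).generator_loss == 0.7

    def test_lambda_zero_is_pure_adversarial(self):
        bd = composite_generator_loss(0.7, 0.9, 0.0)
        assert bd.generator_loss == 0.7

    def test_negative_inputs_rejected(self):
        with pytest.raises(ParameterError):
            composite_generator_loss(-1.0, 0.0, 100.0)


class TestTraining:
    def test_checkpoint_schedule_and_epochs(self, tiny_pairs):
        cks, hist = train(tiny_pairs, tiny_config(epochs=5,
                                                  checkpoint_interval_epochs=2))
        assert len(cks) == 2 and cks.epochs == [2, 4]
        assert len(hist) == 5

    def test_single_checkpoint_floor(self, tiny_pairs):
        cks, _ = train(tiny_pairs[:1], tiny_config(
            epochs=3, checkpoint_interval_epochs=2))
        assert len(cks) == 1 and cks.epochs == [2]

    def test_seeded_reruns_identical(self, tiny_pairs):
        cfg = tiny_config(epochs=2)
        _, h1 = train(tiny_pairs, cfg)
        _, h2 = train(tiny_pairs, cfg)
        assert h1.equals(h2)

    def test_loss_identity_every_epoch(self, tiny_pairs):
        cfg = tiny_config(epochs=3)
        _, hist = train(tiny_pairs, cfg)
        np.testing.assert_allclose(
            hist["generator_loss"],
            hist["adversarial_loss"] + cfg.lambda_l1 * hist["l1_loss"],
            rtol=1e-6)
        assert (hist[["adversarial_loss", "l1_loss",
                      "discriminator_loss"]] >= 0).all().all()

    def test_empty_dataset_rejected(self):
        with pytest.raises(ParameterError):
            train([], tiny_config())

    def test_checkpoint_save_load_roundtrip(self, tiny_pairs, tmp_path):
        from retfusion.translator import CheckpointSet

        cks, _ = train(tiny_pairs, tiny_config(epochs=2))
        cks.save(tmp_path)
        loaded = CheckpointSet.load(tmp_path, cks.direction)
        src = tiny_pairs[0][0]
        out_a = translate(cks.generator_at(0), src)
        out_b = translate(loaded.generator_at(0), src)
        np.testing.assert_array_equal(out_a.pixels, out_b.pixels)


class TestTranslate:
    def test_output_dims_and_determinism(self, tiny_pairs):
        cks, _ = train(tiny_pairs, tiny_config(epochs=1,
                                               checkpoint_interval_epochs=1))
        gen = cks.generator_at(0)
        src = tiny_pairs[0][0]
        a = translate(gen, src)
        b = translate(gen, src)
        assert a.pixels.shape == (32, 32, 3)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_wrong_dims_rejected(self, tiny_pairs):
        cks, _ = train(tiny_pairs, tiny_config(epochs=1,
                                               checkpoint_interval_epochs=1))
        with pytest.raises(ParameterError):
            translate(cks.generator_at(0),
                      np.zeros((16, 16, 3), dtype=np.uint8))


class TestDirectionPlumbing:
    def test_direction_selects_composite_half(self, rng):
        fa = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
        oc = rng.integers(0, 256, (32, 32, 3), dtype=np.uint8)
        comp = np.concatenate([fa, oc], axis=1)
        fwd = coerce_pairs([comp], tiny_config(direction="fa_to_oct"))
        rev = coerce_pairs([comp], tiny_config(direction="oct_to_fa"))
        np.testing.assert_array_equal(fwd[0][0], rev[0][1])
        np.testing.assert_array_equal(fwd[0][1], rev[0][0])


class TestModelResults:
    def test_fit_returns_results_with_summary(self, tiny_pairs):
        res = Pix2PixModel(tiny_pairs, tiny_config(epochs=2)).fit()
        text = res.summary()
        assert "lambda" in text and "checkpoints saved:    2" in text
        assert res.history.shape[0] == 2
        out = res.translate(tiny_pairs[0][0])
        assert out.pixels.shape == (32, 32, 3)

    def test_lambda_weighting_lowers_reconstruction_error(self, samples32):
        """Dropping the L1 term (lambda=0) must not beat the lambda=100 run
        in mean absolute reconstruction error, averaged over 3 seeds."""
        from retfusion.translator import tensor_to_image

        train_set, test_set = samples32[:9], samples32[9:]
        err = {0.0: [], 100.0: []}
        for lam in err:
            for seed in (1, 2, 3):
                cfg = tiny_config(epochs=4, checkpoint_interval_epochs=4,
                                  base_channels=8, disc_channels=8,
                                  lambda_l1=lam, seed=seed)
                cks, _ = train(train_set, cfg)
                gen = cks.generator_at(0)
                l1s = [np.mean(np.abs(
                    translate(gen, s.fa_crop).pixels.astype(float) -
                    s.oct_crop.pixels.astype(float))) for s in test_set]
                err[lam].append(np.mean(l1s))
        assert np.mean(err[0.0]) >= np.mean(err[100.0])
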