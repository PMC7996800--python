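"""DCGAN plans, losses, latent sampling and adversarial training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cystaug.convmath import ConvSpec, tconv_output_size
from cystaug.gan import (
    DiscriminatorPlan,
    GanTrainConfig,
    GeneratorPlan,
    build_discriminator,
    build_generator,
    discriminator_loss,
    generate_images,
    generator_loss,
    sample_latent,
    train_gan,
)


class TestLatentSampling:
    def test_shape_and_range(self):
        z = sample_latent(5, seed=0)
        assert z.shape == (5, 100)
        assert z.min() >= 0.0 and z.max() <= 1.0

    def test_seed_determinism(self):
        assert np.array_equal(sample_latent(3, 7), sample_latent(3, 7))

    def test_uniform_moments(self):
        z = sample_latent(1000, seed=1).ravel()
        se = (1 / np.sqrt(12)) / np.sqrt(z.size)
        assert abs(z.mean() - 0.5) < 3 * se

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            sample_latent(0, seed=0)


class TestPlans:
    def test_generator_plan_28(self):
        plan = GeneratorPlan(28, 28)
        assert plan.dense_units == 12544
        assert plan.shape_chain() == [
            (1, 100), (12544,), (7, 7, 256), (7, 7, 128), (14, 14, 64), (28, 28, 1),
        ]

    def test_generator_plan_smallest(self):
        plan = GeneratorPlan(4, 4)
        assert plan.dense_units == 256
        assert plan.shape_chain()[-1] == (4, 4, 1)

    def test_every_stage_obeys_tconv_formula(self):
        plan = GeneratorPlan(28, 28)
        chain = plan.shape_chain()
        sizes = [c[0] for c in chain[2:]]  # spatial sizes from reshape onward
        for s_in, s_out, stride in zip(sizes, sizes[1:], plan.strides):
            assert s_out == tconv_output_size(
                ConvSpec(L=s_in, F=plan.kernel, S=stride, P="same")
            )

    def test_discriminator_plan_28(self):
        plan = DiscriminatorPlan(28, 28)
        assert plan.flatten_width == 6272
        assert plan.shape_chain() == [
            (28, 28, 1), (14, 14, 64), (7, 7, 128), (6272,), (1,),
        ]
        assert plan.dropout == 0.3

    def test_discriminator_plan_smallest(self):
        assert DiscriminatorPlan(4, 4).flatten_width == 128

    def test_non_divisible_sizes_rejected(self):
        with pytest.raises(ValueError):
            GeneratorPlan(30, 28)
        with pytest.raises(ValueError):
            DiscriminatorPlan(28, 30)

    def test_generator_output_matches_discriminator_input(self):
        for size in (4, 8, 16, 28):
            g = GeneratorPlan(size, size)
            d = DiscriminatorPlan(size, size)
            assert g.shape_chain()[-1] == d.shape_chain()[0]


class TestRealizedNetworks:
    def test_generator_forward_shape(self):
        gen = build_generator(8, 8, channels=(16, 8, 4), seed=0)
        out = gen.forward(sample_latent(3, 0))
        assert out.shape == (3, 8, 8, 1)
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_discriminator_forward_shape(self):
        disc = build_discriminator(8, 8, channels=(4, 8), seed=0)
        p = disc.forward(np.random.default_rng(0).random((3, 8, 8)))
        assert p.shape == (3,)
        assert np.all((p > 0) & (p < 1))


class TestLosses:
    def test_generator_loss_limits(self):
        assert generator_loss(np.full(4, 1.0 - 1e-9)) < 1e-6
        assert generator_loss(np.full(4, 0.5)) == pytest.approx(np.log(2), rel=1e-9)
        assert generator_loss(np.array([0.9, 0.1])) == pytest.approx(
            np.mean([-np.log(0.9), -np.log(0.1)]), rel=1e-9
        )

    def test_discriminator_loss_limits(self):
        terms = discriminator_loss(np.full(4, 1.0 - 1e-9), np.full(4, 1e-9))
        assert terms.h_d < 1e-6
        terms = discriminator_loss(np.full(4, 0.5), np.full(4, 0.5))
        assert terms.h_d == pytest.approx(2 * np.log(2), rel=1e-9)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            generator_loss(np.array([]))
        with pytest.raises(ValueError):
            discriminator_loss(np.array([]), np.array([0.5]))

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        real=st.lists(st.floats(1e-6, 1 - 1e-6), min_size=1, max_size=8),
        fake=st.lists(st.floats(1e-6, 1 - 1e-6), min_size=1, max_size=8),
    )
    def test_additivity_and_positivity(self, real, fake):
        terms = discriminator_loss(np.array(real), np.array(fake))
        assert terms.h_d == terms.h_d_real + terms.h_d_fake
        assert terms.h_d_real >= 0 and terms.h_d_fake >= 0
        assert generator_loss(np.array(fake)) >= 0


class TestTraining:
    def test_smoke_one_epoch(self, small_dataset):
        sub = small_dataset.subset(np.arange(8))
        cfg = GanTrainConfig(epochs=1, batch_size=4, channels=(8, 4, 4), seed=0)
        gen, hist = train_gan(sub, cfg)
        assert len(hist) == 1
        assert np.isfinite(hist[["h_g", "h_d_real", "h_d_fake", "h_d"]].to_numpy()).all()

    def test_seeded_determinism(self, small_dataset):
        sub = small_dataset.subset(np.arange(12))
        cfg = GanTrainConfig(epochs=2, batch_size=4, channels=(8, 4, 4), seed=5)
        _, h1 = train_gan(sub, cfg)
        _, h2 = train_gan(sub, cfg)
        assert np.array_equal(h1.to_numpy(), h2.to_numpy())

    def test_converges_on_constant_images(self):
        """On a degenerate dataset of identical flat images the generator's
        mean pixel must approach the constant (stochastic probe, fixed seed)."""
        imgs = np.full((8, 4, 4), 0.75, dtype=np.float32)
        cfg = GanTrainConfig(
            epochs=400, batch_size=8, learning_rate=0.01, channels=(16, 8, 4), seed=3
        )
        gen, _ = train_gan(imgs, cfg)
        assert abs(gen.generate(32, 1).mean() - 0.75) < 0.1

    def test_milestone_dumps_and_history_csv(self, small_dataset, tmp_path):
        sub = small_dataset.subset(np.arange(8))
        cfg = GanTrainConfig(
            epochs=2, batch_size=4, channels=(8, 4, 4), seed=0, milestones=(1, 2)
        )
        train_gan(sub, cfg, out_dir=tmp_path)
        assert (tmp_path / "milestone_epoch_0001.png").exists()
        assert (tmp_path / "milestone_epoch_0002.png").exists()
        assert (tmp_path / "loss_history.csv").exists()

    def test_mixed_sizes_rejected(self):
        with pytest.raises(ValueError):
            train_gan(np.zeros((2, 8, 6)), GanTrainConfig(epochs=1))


class TestGenerateImages:
    @pytest.fixture(scope="class")
    def tiny_generator(self):
        return build_generator(8, 8, channels=(8, 4, 4), seed=1)

    def test_zero_images(self, tiny_generator):
        out = generate_images(tiny_generator, 0, seed=0)
        assert len(out) == 0

    def test_count_shape_and_provenance(self, tiny_generator):
        out = generate_images(tiny_generator, 5, seed=0)
        assert out.images.shape == (5, 8, 8)
        assert np.all(out.provenance == "generated")

    def test_seed_determinism(self, tiny_generator):
        a = generate_images(tiny_generator, 3, seed=9)
        b = generate_images(tiny_generator, 3, seed=9)
        assert np.array_equal(a.images, b.images)

    def test_negative_n_rejected(self, tiny_generator):
        with pytest.raises(ValueError):
            generate_images(tiny_generator, -1, seed=0)
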