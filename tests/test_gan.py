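"""Restore-CycleGAN: architectures, losses, image pool, training behavior."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from galofrec import (DiscriminatorSpec, GeneratorSpec, ImagePool, LossWeights,
                      TrainConfig, build_discriminator, build_generator,
                      discriminator_loss, generate_objects, generator_loss,
                      pool_sample, train, translate, ObjectSpec)
from galofrec.gan import reduced_specs
from galofrec.nn import Tensor


@pytest.fixture(scope="module")
def easy_task_checkpoint():
    """Tiny training run on an easy task: fuzzy domain = blurred references."""
    refs = generate_objects(ObjectSpec(image_size=32, seed=5), 20)
    fuzzy = np.stack([
        np.stack([gaussian_filter(r[..., c].astype(float), 1.5)
                  for c in range(3)], axis=-1).astype(np.uint8)
        for r in refs])
    config = TrainConfig(epochs=4, seed=0, reduced_scale=True)
    return fuzzy, refs, config, train(fuzzy, refs, config, LossWeights())


class TestArchitectures:
    def test_default_generator_ends_in_three_filters(self):
        gen = build_generator()
        assert gen.spec.filter_schedule == (64, 128, 256, 512, 512, 512, 512,
                                            512, 512, 512, 512, 512, 256, 128,
                                            64, 3)
        assert gen.output_channels == 3

    def test_default_discriminator_ends_in_one_filter(self):
        disc = build_discriminator()
        assert disc.spec.filter_schedule == (64, 128, 256, 512, 512, 1)
        assert disc.output_channels == 1

    def test_reduced_generator_preserves_spatial_size(self):
        spec, _ = reduced_specs(64, width_divisor=8)
        gen = build_generator(spec, np.random.default_rng(0))
        out = gen(Tensor(np.zeros((1, 3, 64, 64), np.float32)))
        assert out.shape == (1, 3, 64, 64)

    def test_generator_pads_incompatible_sizes(self):
        spec, _ = reduced_specs(32, depth=3)
        gen = build_generator(spec, np.random.default_rng(0))
        out = gen(Tensor(np.zeros((1, 3, 30, 30), np.float32)))
        assert out.shape == (1, 3, 30, 30)

    def test_discriminator_output_is_patch_map(self):
        _, spec = reduced_specs(32)
        disc = build_discriminator(spec, np.random.default_rng(0))
        out = disc(Tensor(np.zeros((1, 3, 32, 32), np.float32)))
        assert out.shape[1] == 1
        assert out.shape[2] < 32 and out.shape[3] < 32

    def test_forward_pass_deterministic_with_fixed_weights(self):
        spec, _ = reduced_specs(32)
        gen = build_generator(spec, np.random.default_rng(3))
        x = np.random.default_rng(4).standard_normal((1, 3, 32, 32)).astype(np.float32)
        a = gen(Tensor(x)).data
        b = gen(Tensor(x)).data
        assert np.array_equal(a, b)

    def test_unmirrorable_schedule_rejected(self):
        with pytest.raises(ValueError):
            build_generator(GeneratorSpec(filter_schedule=(8, 16, 32, 3)))
        with pytest.raises(ValueError):
            build_generator(GeneratorSpec(filter_schedule=(8, 16, 16, 4)))
        with pytest.raises(ValueError):
            build_discriminator(DiscriminatorSpec(filter_schedule=(8, 2)))


class TestLosses:
    def test_identity_generators_and_unit_discriminator_give_zero(self, rng):
        x = rng.random((2, 3, 4, 4))
        y = rng.random((2, 3, 4, 4))
        identity = lambda t: t
        d_one = lambda t: Tensor(np.ones((2, 1, 1, 1)))
        loss = generator_loss(x, y, identity, identity, d_one, LossWeights())
        assert loss.item() == pytest.approx(0.0)

    def test_scalar_stub_arithmetic(self):
        # additive stubs G_xy: t+0.2, G_yx: t-0.1 give cycle residuals
        # |0.2-0.1| = 0.1 in both directions and identity residual 0.2;
        # with D(G(x)) = 0.5: (0.5-1)^2 + 10*0.1 + 10*0.1 + 5*0.2 = 3.25
        x = np.zeros((1, 1, 1, 1))
        y = np.zeros((1, 1, 1, 1))
        g_xy = lambda t: t + 0.2
        g_yx = lambda t: t + (-0.1)
        d_y = lambda t: 0.5
        loss = generator_loss(x, y, g_xy, g_yx, d_y, LossWeights(10.0, 5.0))
        assert loss.item() == pytest.approx(3.25)

    def test_doubling_alpha1_adds_exactly_the_cycle_total(self):
        x = np.zeros((1, 1, 1, 1))
        y = np.zeros((1, 1, 1, 1))
        g_xy = lambda t: t + 0.2
        g_yx = lambda t: t + (-0.1)
        d_y = lambda t: 0.5
        base = generator_loss(x, y, g_xy, g_yx, d_y, LossWeights(10.0, 5.0)).item()
        doubled = generator_loss(x, y, g_xy, g_yx, d_y, LossWeights(20.0, 5.0)).item()
        assert doubled - base == pytest.approx(10.0 * 0.1 + 10.0 * 0.1)

    def test_perfect_discriminator_loss_zero(self, rng):
        y = rng.random((2, 3, 4, 4))
        fake = rng.random((2, 3, 4, 4))
        d = _LabelStub(real=y)
        assert discriminator_loss(y, fake, d).item() == pytest.approx(0.0)

    def test_half_scores_give_quarter(self, rng):
        y = rng.random((1, 3, 2, 2))
        d_half = lambda t: Tensor(np.full((1, 1, 1, 1), 0.5))
        assert discriminator_loss(y, y, d_half).item() == pytest.approx(0.25)

    def test_always_one_gives_half(self, rng):
        y = rng.random((1, 3, 2, 2))
        d_one = lambda t: Tensor(np.ones((1, 1, 1, 1)))
        assert discriminator_loss(y, y, d_one).item() == pytest.approx(0.5)


class _LabelStub:
    def __init__(self, real):
        self.real = np.asarray(real)

    def __call__(self, t):
        data = t.data if hasattr(t, "data") else np.asarray(t)
        value = 1.0 if data.shape == self.real.shape and np.allclose(data, self.real) else 0.0
        return Tensor(np.full((1, 1, 1, 1), value))


class TestImagePool:
    def test_first_call_stores_and_returns(self, rng):
        pool = ImagePool(50)
        img = rng.random((3, 4, 4))
        out = pool_sample(pool, img, rng)
        assert np.array_equal(out, img)
        assert len(pool.store) == 1

    def test_capacity_never_exceeded(self, rng):
        pool = ImagePool(50)
        for i in range(120):
            pool_sample(pool, np.full((2, 2), i), rng)
        assert len(pool.store) == 50

    def test_returned_is_new_about_half_the_time_at_capacity(self):
        rng = np.random.default_rng(42)
        pool = ImagePool(50)
        for i in range(50):
            pool_sample(pool, np.full((1,), i), rng)
        hits = 0
        n = 10_000
        for i in range(n):
            new = np.full((1,), 1000 + i)
            out = pool_sample(pool, new, rng)
            hits += int(out[0] == new[0])
        assert abs(hits / n - 0.5) < 0.02

    def test_every_stored_image_was_a_generated_fake(self):
        rng = np.random.default_rng(0)
        pool = ImagePool(10)
        seen = set()
        for i in range(100):
            seen.add(float(i))
            pool_sample(pool, np.full((1,), float(i)), rng)
        assert {float(s[0]) for s in pool.store} <= seen


class TestTraining:
    def test_smoke_all_losses_finite(self, easy_task_checkpoint):
        _, _, _, checkpoint = easy_task_checkpoint
        for record in checkpoint.history:
            for key in ("g_xy", "g_yx", "d_y", "d_x"):
                assert np.isfinite(record[key])

    def test_seeded_rerun_reproduces_loss_sequence(self, easy_task_checkpoint):
        fuzzy, refs, config, checkpoint = easy_task_checkpoint
        again = train(fuzzy, refs, config, LossWeights())
        assert again.history == checkpoint.history

    def test_generator_loss_decreases_on_easy_task(self, easy_task_checkpoint):
        _, _, _, checkpoint = easy_task_checkpoint
        g = [rec["g_xy"] for rec in checkpoint.history]
        assert np.mean(g[-2:]) < np.mean(g[:2])

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            train(np.zeros((0, 8, 8, 3), np.uint8),
                  np.zeros((2, 8, 8, 3), np.uint8))


class TestTranslate:
    def test_identity_stub_generator(self, rng):
        img = rng.integers(0, 256, (16, 16, 3)).astype(np.uint8)

        class Identity:
            def __call__(self, t):
                return t

        assert np.array_equal(translate(img, Identity()), img)

    def test_repeated_calls_bit_identical(self, easy_task_checkpoint):
        fuzzy, _, _, checkpoint = easy_task_checkpoint
        a = translate(fuzzy[0], checkpoint.g_xy)
        b = translate(fuzzy[0], checkpoint.g_xy)
        assert np.array_equal(a, b)
        assert a.shape == fuzzy[0].shape
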