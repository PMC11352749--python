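"""Conditional-GAN construction, training contracts and sampling."""

import numpy as np
import pytest

from fcgan import (CganSpec, build_discriminator, build_generator,
                   generate_synthetic, train_cgan)
from fcgan.augment_cgan import CganBundle, load_bundle, save_bundle
from fcgan.simulate import FixtureConfig, make_feature_fixture


def table(n=80, seed=0):
    cfg = FixtureConfig(regions=10, sites=(("A", n // 2, n // 2),),
                        planted_edges=((0, 1), (2, 3), (4, 5)), seed=seed)
    return make_feature_fixture(cfg)


def small_spec(d, **kw):
    kw.setdefault("scale", 0.02)
    kw.setdefault("epochs", 40)
    kw.setdefault("seed", 1)
    return CganSpec(feature_dim=d, **kw)


class TestArchitecture:
    def test_generator_output_shape_and_range(self, rng):
        spec = small_spec(45)
        gen = build_generator(spec)
        out = gen(rng.standard_normal((7, spec.noise_dim_scaled)),
                  np.zeros(7, dtype=int), train=False)
        assert out.data.shape == (7, 45)
        assert (np.abs(out.data) < 1.0).all()

    def test_generator_deterministic_given_inputs(self, rng):
        spec = small_spec(45)
        z = rng.standard_normal((4, spec.noise_dim_scaled))
        y = np.array([0, 1, 0, 1])
        a = build_generator(spec)(z, y, train=False).data
        b = build_generator(spec)(z, y, train=False).data
        assert np.array_equal(a, b)

    def test_full_scale_discriminator_input_width(self):
        spec = CganSpec(feature_dim=6670)
        disc = build_discriminator(spec)
        assert disc.linears[0].weight.data.shape == (6670 + 500, 4000)

    def test_full_scale_generator_widths(self):
        spec = CganSpec(feature_dim=6670)
        gen = build_generator(spec)
        widths = [lin.weight.data.shape for lin in gen.linears]
        assert widths == [(1000, 2000), (2000, 3000), (3000, 4000),
                          (4000, 5000)]
        assert gen.out.weight.data.shape == (5000, 6670)

    def test_discriminator_scores_batch(self, rng):
        spec = small_spec(45)
        disc = build_discriminator(spec)
        out = disc(rng.standard_normal((5, 45)), np.ones(5, dtype=int),
                   train=False)
        assert out.data.shape == (5, 1)

    def test_feature_length_mismatch_rejected(self, rng):
        spec = small_spec(45)
        disc = build_discriminator(spec)
        with pytest.raises(ValueError):
            disc(rng.standard_normal((5, 44)), np.ones(5, dtype=int))

    def test_invalid_class_rejected(self, rng):
        spec = small_spec(45)
        gen = build_generator(spec)
        with pytest.raises(ValueError):
            gen(rng.standard_normal((2, spec.noise_dim_scaled)),
                np.array([0, 2]))

    def test_scaled_output_dim_follows_feature_dim(self, rng):
        spec = CganSpec(feature_dim=190, scale=0.01)
        gen = build_generator(spec)
        out = gen(rng.standard_normal((3, spec.noise_dim_scaled)),
                  np.zeros(3, dtype=int), train=False)
        assert out.data.shape == (3, 190)

    def test_spectral_norm_property_after_training(self):
        t = table()
        bundle = train_cgan(t, small_spec(t.dim, epochs=20))
        for model in (bundle.generator, bundle.discriminator):
            for lin in model.linears:
                w = lin.normalized_weight().data
                assert np.linalg.svd(w, compute_uv=False)[0] <= 1 + 1e-3


class TestTraining:
    def test_zero_epochs_is_initialization(self):
        t = table()
        spec = small_spec(t.dim, epochs=0)
        bundle = train_cgan(t, spec)
        assert bundle.d_loss_trace == [] and bundle.g_loss_trace == []
        init = build_generator(spec)
        for a, b in zip(bundle.generator.parameters(), init.parameters()):
            assert np.array_equal(a.data, b.data)

    def test_training_deterministic_under_seed(self):
        t = table(n=40)
        spec = small_spec(t.dim, epochs=10)
        b1 = train_cgan(t, spec)
        b2 = train_cgan(t, spec)
        for a, b in zip(b1.generator.parameters(), b2.generator.parameters()):
            assert np.array_equal(a.data, b.data)
        assert b1.d_loss_trace == b2.d_loss_trace

    def test_losses_finite_and_traced(self):
        t = table(n=40)
        bundle = train_cgan(t, small_spec(t.dim, epochs=15))
        assert len(bundle.d_loss_trace) == 15 == len(bundle.g_loss_trace)
        assert np.isfinite(bundle.d_loss_trace).all()
        assert np.isfinite(bundle.g_loss_trace).all()

    def test_fidelity_trace_recorded_with_ae(self):
        from fcgan import AeSpec, train_autoencoder

        t = table(n=40)
        ae = train_autoencoder(t, AeSpec(feature_dim=t.dim, scale=0.02,
                                         epochs=30, seed=2))
        bundle = train_cgan(t, small_spec(t.dim, epochs=12), ae=ae)
        assert len(bundle.fidelity_trace) == 12
        assert all(v >= 0 for v in bundle.fidelity_trace)

    def test_minimax_flag_changes_generator_loss(self):
        t = table(n=40)
        ns = train_cgan(t, small_spec(t.dim, epochs=5))
        mm = train_cgan(t, small_spec(t.dim, epochs=5, non_saturating=False))
        assert ns.g_loss_trace != mm.g_loss_trace

    def test_generator_fools_frozen_discriminator(self):
        # with D frozen at init, G's objective is smooth: smoothed loss
        # over 20-epoch windows must not increase
        t = table(n=60)
        spec = small_spec(t.dim, epochs=120, seed=3)
        from fcgan import nn
        from fcgan.autodiff import Tensor
        from fcgan.augment_cgan import build_discriminator, build_generator

        gen = build_generator(spec)
        disc = build_discriminator(spec)
        rng = np.random.default_rng(0)
        opt = nn.Adam(gen.parameters(), lr=spec.effective_lr)
        losses = []
        for _ in range(spec.epochs):
            z = rng.standard_normal((32, spec.noise_dim_scaled))
            y = rng.integers(0, 2, size=32)
            loss = nn.bce_with_logits(
                disc(gen(z, y, train=True), y, train=False), np.ones(32))
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        smoothed = np.convolve(losses, np.ones(20) / 20, mode="valid")
        assert smoothed[-1] <= smoothed[0] + 1e-6


class TestGenerateSynthetic:
    def trained(self):
        t = table(n=40)
        return train_cgan(t, small_spec(t.dim, epochs=10))

    def test_counts_and_labels(self):
        bundle = self.trained()
        synth = generate_synthetic(bundle, 25, seed=0)
        assert len(synth) == 50
        assert synth.labels.count("ASD") == 25 == synth.labels.count("HC")
        assert set(synth.sites) == {"SYNTH"}
        assert (np.abs(synth.values) <= 1.0).all()

    def test_single_per_class(self):
        synth = generate_synthetic(self.trained(), 1, seed=5)
        assert len(synth) == 2 and set(synth.labels) == {"ASD", "HC"}

    def test_seed_changes_values_not_shape(self):
        bundle = self.trained()
        a = generate_synthetic(bundle, 10, seed=1)
        b = generate_synthetic(bundle, 10, seed=2)
        assert a.values.shape == b.values.shape
        assert not np.array_equal(a.values, b.values)

    def test_deterministic_given_seed(self):
        bundle = self.trained()
        a = generate_synthetic(bundle, 10, seed=7)
        b = generate_synthetic(bundle, 10, seed=7)
        assert np.array_equal(a.values, b.values)

    def test_nonpositive_count_rejected(self):
        with pytest.raises(ValueError):
            generate_synthetic(self.trained(), 0, seed=0)


def test_bundle_roundtrip(tmp_path):
    t = table(n=40)
    bundle = train_cgan(t, small_spec(t.dim, epochs=8))
    save_bundle(bundle, tmp_path / "cgan.bundle")
    loaded = load_bundle(tmp_path / "cgan.bundle")
    a = generate_synthetic(bundle, 5, seed=3)
    b = generate_synthetic(loaded, 5, seed=3)
    assert np.array_equal(a.values, b.values)
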