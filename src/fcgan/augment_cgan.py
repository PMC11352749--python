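"""Class-conditional GAN for connectivity-feature augmentation.

Connectivity classification is a small-n / large-D problem (hundreds of
subjects, thousands of correlation features), so the classifier overfits
badly on real data alone. The augmenter trains a conditional GAN on the
*training* feature vectors and samples class-labelled synthetic vectors to
enlarge the training set.

Architecture at full scale: the generator embeds the class into a 500-dim
condition vector, concatenates it with a 500-dim standard-normal noise
vector (1000 inputs), passes hidden layers of widths 2000→3000→4000→5000
(each spectrally normalized, batch-normalized, leaky-ReLU 0.1) and maps to
the feature dimension through a tanh, keeping outputs inside the valid
correlation range (−1, 1). The discriminator embeds the class to 500 dims,
concatenates it with the feature vector, and scores it through spectrally
normalized leaky-ReLU layers 4000→2000→1000→500→1 (one unbounded logit).

Training alternates one discriminator and one generator update per batch
under the binary-cross-entropy realization of the minimax objective
min_G max_D E[log D(x|y)] + E[log(1 − D(G(z|y)))]; the generator uses the
non-saturating variant by default (strict minimax behind a flag). If a
trained denoising autoencoder is supplied, its reconstruction error on a
generated batch is recorded each epoch as a distribution-fidelity trace.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .ae_fidelity import AeBundle, fidelity_score, scale_widths
from .autodiff import Tensor, concat
from .io_formats import LABELS, SYNTH_SITE, FeatureTable

N_CLASSES = 2


@dataclass(frozen=True)
class CganSpec:
    feature_dim: int
    noise_dim: int = 500
    condition_dim: int = 500
    generator_widths: tuple[int, ...] = (2000, 3000, 4000, 5000)
    discriminator_widths: tuple[int, ...] = (4000, 2000, 1000, 500)
    leaky_slope: float = 0.1
    learning_rate: float = 1e-5
    batch_size: int = 64
    epochs: int = 5000
    seed: int = 0
    scale: float = 1.0
    non_saturating: bool = True  # False → literal minimax generator loss

    def scaled(self, widths) -> list[int]:
        return scale_widths(widths, self.scale)

    @property
    def effective_lr(self) -> float:
        """Optimizer step scaled inversely with width scale (= learning_rate
        at full scale)."""
        return self.learning_rate / min(self.scale, 1.0)

    @property
    def noise_dim_scaled(self) -> int:
        return max(1, round(self.noise_dim * self.scale))

    @property
    def condition_dim_scaled(self) -> int:
        return max(1, round(self.condition_dim * self.scale))


class Generator(nn.Module):
    def __init__(self, spec: CganSpec, rng: np.random.Generator):
        self.spec = spec
        self.embed = nn.Embedding(N_CLASSES, spec.condition_dim_scaled, rng)
        dims = ([spec.noise_dim_scaled + spec.condition_dim_scaled]
                + spec.scaled(spec.generator_widths))
        self.linears = [nn.Linear(a, b, rng, spectral_norm=True)
                        for a, b in zip(dims, dims[1:])]
        self.norms = [nn.BatchNorm1d(b) for b in dims[1:]]
        self.out = nn.Linear(dims[-1], spec.feature_dim, rng)

    def __call__(self, z: np.ndarray, y: np.ndarray, train: bool = True) -> Tensor:
        h = concat([self.embed(y), Tensor(z)], axis=-1)
        for lin, norm in zip(self.linears, self.norms):
            h = norm(lin(h, train), train).leaky_relu(self.spec.leaky_slope)
        return self.out(h, train).tanh()


class Discriminator(nn.Module):
    def __init__(self, spec: CganSpec, rng: np.random.Generator):
        self.spec = spec
        self.embed = nn.Embedding(N_CLASSES, spec.condition_dim_scaled, rng)
        dims = ([spec.feature_dim + spec.condition_dim_scaled]
                + spec.scaled(spec.discriminator_widths))
        self.linears = [nn.Linear(a, b, rng, spectral_norm=True)
                        for a, b in zip(dims, dims[1:])]
        self.out = nn.Linear(dims[-1], 1, rng)

    def __call__(self, x: Tensor | np.ndarray, y: np.ndarray,
                 train: bool = True) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.shape[-1] != self.spec.feature_dim:
            raise ValueError(f"feature length {x.shape[-1]} != "
                             f"{self.spec.feature_dim}")
        h = concat([x, self.embed(y)], axis=-1)
        for lin in self.linears:
            h = lin(h, train).leaky_relu(self.spec.leaky_slope)
        return self.out(h, train)


@dataclass
class CganBundle:
    generator: Generator
    discriminator: Discriminator
    spec: CganSpec
    d_loss_trace: list[float] = field(default_factory=list)
    g_loss_trace: list[float] = field(default_factory=list)
    fidelity_trace: list[float] = field(default_factory=list)


def build_generator(spec: CganSpec) -> Generator:
    return Generator(spec, np.random.default_rng(np.random.SeedSequence(
        [spec.seed, 11])))


def build_discriminator(spec: CganSpec) -> Discriminator:
    return Discriminator(spec, np.random.default_rng(np.random.SeedSequence(
        [spec.seed, 12])))


def train_cgan(train_features: FeatureTable, spec: CganSpec,
               ae: AeBundle | None = None) -> CganBundle:
    """Adversarial training on labelled training-set feature vectors.

    One discriminator update then one generator update per minibatch;
    class conditions for fake batches reuse the real batch's labels so the
    conditional distribution of classes is preserved. Returns the trained
    bundle with per-epoch discriminator/generator loss traces and, when an
    autoencoder is given, the per-epoch fidelity trace of generated batches.
    """
    if train_features.dim != spec.feature_dim:
        raise ValueError(f"feature dim {train_features.dim} != spec.feature_dim "
                         f"{spec.feature_dim}")
    gen = build_generator(spec)
    disc = build_discriminator(spec)
    bundle = CganBundle(generator=gen, discriminator=disc, spec=spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 13]))
    opt_g = nn.Adam(gen.parameters(), lr=spec.effective_lr)
    opt_d = nn.Adam(disc.parameters(), lr=spec.effective_lr)

    x_all = train_features.values
    y_all = train_features.label_ints()
    n, zdim = x_all.shape[0], spec.noise_dim_scaled

    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        d_losses, g_losses = [], []
        for start in range(0, n, spec.batch_size):
            idx = order[start:start + spec.batch_size]
            x_real, y = x_all[idx], y_all[idx]
            b = len(idx)

            # discriminator step: real → 1, generated (detached) → 0
            z = rng.standard_normal((b, zdim))
            fake = gen(z, y, train=True).detach()
            loss_d = (nn.bce_with_logits(disc(x_real, y, train=True), np.ones(b))
                      + nn.bce_with_logits(disc(fake, y, train=True), np.zeros(b)))
            opt_d.zero_grad()
            loss_d.backward()
            opt_d.step()

            # generator step
            z = rng.standard_normal((b, zdim))
            logits = disc(gen(z, y, train=True), y, train=False)
            if spec.non_saturating:
                loss_g = nn.bce_with_logits(logits, np.ones(b))
            else:  # literal minimax: maximize log(1 - D(G(z)))... minimized
                loss_g = -nn.bce_with_logits(logits, np.zeros(b))
            opt_g.zero_grad()
            loss_g.backward()
            opt_g.step()

            if not (np.isfinite(loss_d.data) and np.isfinite(loss_g.data)):
                raise FloatingPointError(
                    f"cGAN loss became non-finite at epoch {epoch}")
            d_losses.append(float(loss_d.data))
            g_losses.append(float(loss_g.data))
        bundle.d_loss_trace.append(float(np.mean(d_losses)))
        bundle.g_loss_trace.append(float(np.mean(g_losses)))

        if ae is not None:
            # probe a batch generated exactly as during training (batch
            # statistics), so the trace reflects the generator itself and
            # not stale normalization state
            z = rng.standard_normal((spec.batch_size, zdim))
            y_probe = np.arange(spec.batch_size) % N_CLASSES
            probe = gen(z, y_probe, train=True)
            bundle.fidelity_trace.append(fidelity_score(ae, probe.data))
    return bundle


def generate_synthetic(bundle: CganBundle, n_per_class: int,
                       seed: int) -> FeatureTable:
    """Sample n_per_class labelled synthetic feature vectors per class.

    Deterministic given the seed; rows carry site label "SYNTH" and values
    lie in (−1, 1) by the generator's output activation.
    """
    if n_per_class <= 0:
        raise ValueError("n_per_class must be positive")
    spec = bundle.spec
    rng = np.random.default_rng(seed)
    y = np.repeat(np.arange(N_CLASSES), n_per_class)
    z = rng.standard_normal((len(y), spec.noise_dim_scaled))
    x = bundle.generator(z, y, train=False).data
    labels = [LABELS[c] for c in y]
    sids = [f"synth_{LABELS[c]}_{i:05d}" for i, c in enumerate(y)]
    return FeatureTable(subject_ids=sids, sites=[SYNTH_SITE] * len(y),
                        labels=labels, values=np.clip(x, -1.0, 1.0))


def save_bundle(bundle: CganBundle, path) -> None:
    payload = {"kind": "cgan", "spec": bundle.spec,
               "gen_arrays": [a.copy() for a in bundle.generator.state_arrays()],
               "disc_arrays": [a.copy() for a in bundle.discriminator.state_arrays()],
               "d_loss_trace": list(bundle.d_loss_trace),
               "g_loss_trace": list(bundle.g_loss_trace),
               "fidelity_trace": list(bundle.fidelity_trace)}
    Path(path).write_bytes(pickle.dumps(payload, protocol=4))


def load_bundle(path) -> CganBundle:
    payload = pickle.loads(Path(path).read_bytes())
    if payload.get("kind") != "cgan":
        raise ValueError(f"{path} is not a cGAN bundle")
    spec = payload["spec"]
    bundle = CganBundle(generator=build_generator(spec),
                        discriminator=build_discriminator(spec), spec=spec,
                        d_loss_trace=payload["d_loss_trace"],
                        g_loss_trace=payload["g_loss_trace"],
                        fidelity_trace=payload["fidelity_trace"])
    bundle.generator.load_state(payload["gen_arrays"])
    bundle.discriminator.load_state(payload["disc_arrays"])
    return bundle
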