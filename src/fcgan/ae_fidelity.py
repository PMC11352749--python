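"""Denoising autoencoder used as a distribution-fidelity oracle.

A GAN's own losses say little about whether generated feature vectors lie
on the manifold of real connectivity profiles. The workaround implemented
here: train a denoising autoencoder on a small subset of real training
features (encoder widths 4000→3000→2000→1000→500, decoder
1000→2000→3000→4000→D at full scale; Gaussian input corruption, MSE
against the clean input), then score any sample set by its mean squared
reconstruction error through the frozen autoencoder. Real-like samples
reconstruct well; off-manifold samples do not. The score is attached to
cGAN training as a per-epoch trace of generated-batch fidelity.

No numeric pass/fail threshold is imposed — fidelity is exposed as a score.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .autodiff import Tensor
from .io_formats import FeatureTable


def scale_widths(widths, scale: float) -> list[int]:
    """Multiply layer widths by a scale factor, keeping every width ≥ 1."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    return [max(1, round(w * scale)) for w in widths]


@dataclass(frozen=True)
class AeSpec:
    feature_dim: int
    encoder_widths: tuple[int, ...] = (4000, 3000, 2000, 1000, 500)
    decoder_widths: tuple[int, ...] = (1000, 2000, 3000, 4000)
    noise_sigma: float = 0.1
    learning_rate: float = 1e-5
    epochs: int = 5000
    batch_size: int = 64
    seed: int = 0
    scale: float = 1.0

    @property
    def effective_lr(self) -> float:
        """Optimizer step, scaled inversely with the width scale.

        Narrow desk-scale networks trained for a small epoch budget need a
        proportionally larger step; at full scale this is exactly
        ``learning_rate``.
        """
        return self.learning_rate / min(self.scale, 1.0)

    def scaled_encoder(self) -> list[int]:
        return scale_widths(self.encoder_widths, self.scale)

    def scaled_decoder(self) -> list[int]:
        return scale_widths(self.decoder_widths, self.scale)

    @property
    def latent_dim(self) -> int:
        return self.scaled_encoder()[-1]


class DenoisingAutoencoder(nn.Module):
    """Encoder/decoder stacks of (linear, batch-norm, ReLU); tanh output."""

    def __init__(self, spec: AeSpec, rng: np.random.Generator):
        self.spec = spec
        dims_enc = [spec.feature_dim] + spec.scaled_encoder()
        dims_dec = [spec.latent_dim] + spec.scaled_decoder()
        self.enc_linears = [nn.Linear(a, b, rng) for a, b in zip(dims_enc, dims_enc[1:])]
        self.enc_norms = [nn.BatchNorm1d(b) for b in dims_enc[1:]]
        self.dec_linears = [nn.Linear(a, b, rng) for a, b in zip(dims_dec, dims_dec[1:])]
        self.dec_norms = [nn.BatchNorm1d(b) for b in dims_dec[1:]]
        self.out = nn.Linear(dims_dec[-1], spec.feature_dim, rng)

    def encode(self, x: Tensor, train: bool) -> Tensor:
        h = x
        for lin, norm in zip(self.enc_linears, self.enc_norms):
            h = norm(lin(h, train), train).relu()
        return h

    def decode(self, z: Tensor, train: bool) -> Tensor:
        h = z
        for lin, norm in zip(self.dec_linears, self.dec_norms):
            h = norm(lin(h, train), train).relu()
        return self.out(h, train).tanh()

    def __call__(self, x: Tensor, train: bool = True) -> Tensor:
        return self.decode(self.encode(x, train), train)


@dataclass
class AeBundle:
    model: DenoisingAutoencoder
    spec: AeSpec
    loss_trace: list[float] = field(default_factory=list)


def build_autoencoder(spec: AeSpec) -> AeBundle:
    rng = np.random.default_rng(spec.seed)
    return AeBundle(model=DenoisingAutoencoder(spec, rng), spec=spec)


def train_autoencoder(subset: FeatureTable, spec: AeSpec) -> AeBundle:
    """Fit the denoising autoencoder on (a subset of) real feature vectors.

    Each minibatch is corrupted with zero-mean Gaussian noise of standard
    deviation ``spec.noise_sigma`` before encoding; the loss is the mean
    squared reconstruction error against the *clean* input. The per-epoch
    mean loss trace is recorded on the returned bundle.
    """
    if len(subset) == 0:
        raise ValueError("training subset is empty")
    if subset.dim != spec.feature_dim:
        raise ValueError(f"feature dim {subset.dim} != spec.feature_dim "
                         f"{spec.feature_dim}")
    bundle = build_autoencoder(spec)
    model = bundle.model
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    opt = nn.Adam(model.parameters(), lr=spec.effective_lr)
    x_all = subset.values
    n = x_all.shape[0]
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, spec.batch_size):
            batch = x_all[order[start:start + spec.batch_size]]
            noisy = batch + rng.normal(0.0, spec.noise_sigma, size=batch.shape) \
                if spec.noise_sigma > 0 else batch
            recon = model(Tensor(noisy), train=True)
            loss = nn.mse_loss(recon, batch)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"autoencoder loss became non-finite at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        bundle.loss_trace.append(float(np.mean(losses)))
    return bundle


def fidelity_score(ae: AeBundle, samples: FeatureTable | np.ndarray) -> float:
    """Mean squared reconstruction error of samples through the autoencoder.

    Evaluated deterministically: no input corruption, normalization layers
    frozen at their running statistics. Lower = closer to the training
    distribution.
    """
    x = samples.values if isinstance(samples, FeatureTable) else np.atleast_2d(samples)
    if x.shape[0] == 0:
        raise ValueError("cannot score an empty sample set")
    if x.shape[1] != ae.spec.feature_dim:
        raise ValueError(f"sample dim {x.shape[1]} != autoencoder dim "
                         f"{ae.spec.feature_dim}")
    recon = ae.model(Tensor(x), train=False)
    return float(np.mean((recon.data - x) ** 2))


def save_bundle(bundle: AeBundle, path) -> None:
    payload = {"kind": "ae", "spec": bundle.spec,
               "arrays": [a.copy() for a in bundle.model.state_arrays()],
               "loss_trace": list(bundle.loss_trace)}
    Path(path).write_bytes(pickle.dumps(payload, protocol=4))


def load_bundle(path) -> AeBundle:
    payload = pickle.loads(Path(path).read_bytes())
    if payload.get("kind") != "ae":
        raise ValueError(f"{path} is not an autoencoder bundle")
    bundle = build_autoencoder(payload["spec"])
    bundle.model.load_state(payload["arrays"])
    bundle.loss_trace = payload["loss_trace"]
    return bundle
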