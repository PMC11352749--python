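"""Multi-head-attention classifier and the plain feed-forward ablation.

The main classifier treats each subject's connectivity vector as a single
token of width D and applies scaled dot-product attention over h learned
subspaces (heads): per-head projections produce query, key and value of
width D/h, attention weights are softmax(QKᵀ/√d_k), heads are concatenated
and passed through an output projection, followed by a residual connection
from the input and layer normalization. With a single token the softmax is
over one key and every attention weight is exactly 1 — the block reduces to
a learned value/output projection with residual — which is the faithful
consequence of feeding one vector per subject; an optional ``tokens=k``
mode reshapes the vector into k tokens of width D/k for genuinely
non-degenerate attention. The attention block is followed by a
feed-forward reduction (widths 3000→2000→1000→1 at full scale) where each
width-changing layer carries a learned linear projection on its skip
connection and per-layer normalization, ending in a single logit
(positive class = ASD).

The ablation classifier ("cGAN only" configuration) is a plain multilayer
perceptron of widths 4000→3000→2000→1000→500→50→1 with batch
normalization, ReLU and 10% dropout after each hidden layer.

Both are trained with binary cross-entropy on the logit over the
concatenation of real and (optionally) synthetic feature tables.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .ae_fidelity import scale_widths
from .autodiff import Tensor
from .io_formats import ASD, HC, FeatureTable


@dataclass(frozen=True)
class MhaSpec:
    input_dim: int = 6670
    heads: int = 10
    ff_widths: tuple[int, ...] = (3000, 2000, 1000, 1)
    tokens: int = 1
    learning_rate: float = 1e-4
    batch_size: int = 64
    epochs: int = 5000
    seed: int = 0
    scale: float = 1.0

    def __post_init__(self):
        if self.input_dim % self.tokens != 0:
            raise ValueError(f"input_dim {self.input_dim} not divisible by "
                             f"tokens {self.tokens}")
        token_dim = self.input_dim // self.tokens
        if token_dim % self.heads != 0:
            raise ValueError(f"token width {token_dim} not divisible by "
                             f"{self.heads} heads")
        if self.ff_widths[-1] != 1:
            raise ValueError("last feed-forward width must be 1")

    @property
    def effective_lr(self) -> float:
        return self.learning_rate / min(self.scale, 1.0)

    def scaled_ff(self) -> list[int]:
        return scale_widths(self.ff_widths[:-1], self.scale) + [1]


@dataclass(frozen=True)
class MlpSpec:
    input_dim: int = 6670
    widths: tuple[int, ...] = (4000, 3000, 2000, 1000, 500, 50, 1)
    dropout: float = 0.10
    learning_rate: float = 1e-4
    batch_size: int = 64
    epochs: int = 5000
    seed: int = 0
    scale: float = 1.0

    def __post_init__(self):
        if self.widths[-1] != 1:
            raise ValueError("last width must be 1")

    @property
    def effective_lr(self) -> float:
        return self.learning_rate / min(self.scale, 1.0)

    def scaled_widths(self) -> list[int]:
        return scale_widths(self.widths[:-1], self.scale) + [1]


class MhaClassifier(nn.Module):
    def __init__(self, spec: MhaSpec, rng: np.random.Generator):
        self.spec = spec
        t = spec.input_dim // spec.tokens
        self.token_dim = t
        self.wq = nn.Linear(t, t, rng)
        self.wk = nn.Linear(t, t, rng)
        self.wv = nn.Linear(t, t, rng)
        self.wo = nn.Linear(t, t, rng)
        self.ln_attn = nn.LayerNorm(t)
        dims = [spec.input_dim] + spec.scaled_ff()
        self.ff_linears = [nn.Linear(a, b, rng) for a, b in zip(dims, dims[1:-1])]
        self.ff_skips = [nn.Linear(a, b, rng) for a, b in zip(dims, dims[1:-1])]
        self.ff_norms = [nn.LayerNorm(b) for b in dims[1:-1]]
        self.head = nn.Linear(dims[-2], 1, rng)

    def attention_block(self, x: Tensor, train: bool = True) -> Tensor:
        """softmax(QKᵀ/√d_k)V over heads, + residual, + layer norm.

        Input and output have shape (batch, input_dim).
        """
        spec = self.spec
        b = x.shape[0]
        k_tokens, t, h = spec.tokens, self.token_dim, spec.heads
        d_head = t // h
        x3 = x.reshape(b, k_tokens, t)

        def split_heads(m: Tensor) -> Tensor:
            # (b, k, t) -> (b, h, k, d_head)
            return m.reshape(b, k_tokens, h, d_head).transpose(0, 2, 1, 3)

        q = split_heads(self.wq(x3, train))
        key = split_heads(self.wk(x3, train))
        v = split_heads(self.wv(x3, train))
        scores = (q @ key.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(d_head))
        attn = scores.softmax(axis=-1)
        ctx = attn @ v  # (b, h, k, d_head)
        merged = ctx.transpose(0, 2, 1, 3).reshape(b, k_tokens, t)
        out = self.wo(merged, train)
        return self.ln_attn(x3 + out, train).reshape(b, spec.input_dim)

    def __call__(self, x: Tensor, train: bool = True,
                 rng: np.random.Generator | None = None) -> Tensor:
        h = self.attention_block(x, train)
        for lin, skip, norm in zip(self.ff_linears, self.ff_skips, self.ff_norms):
            h = norm(lin(h, train).relu() + skip(h, train), train)
        return self.head(h, train)


class MlpClassifier(nn.Module):
    def __init__(self, spec: MlpSpec, rng: np.random.Generator):
        self.spec = spec
        dims = [spec.input_dim] + spec.scaled_widths()
        self.linears = [nn.Linear(a, b, rng) for a, b in zip(dims, dims[1:-1])]
        self.norms = [nn.BatchNorm1d(b) for b in dims[1:-1]]
        self.drop = nn.Dropout(spec.dropout)
        self.head = nn.Linear(dims[-2], 1, rng)

    def __call__(self, x: Tensor, train: bool = True,
                 rng: np.random.Generator | None = None) -> Tensor:
        h = x
        for lin, norm in zip(self.linears, self.norms):
            h = self.drop(norm(lin(h, train), train).relu(), train, rng)
        return self.head(h, train)


@dataclass
class ClassifierBundle:
    arch: str  # "mha" | "mlp"
    model: MhaClassifier | MlpClassifier
    spec: MhaSpec | MlpSpec
    loss_trace: list[float] = field(default_factory=list)


def build_classifier(spec: MhaSpec | MlpSpec) -> ClassifierBundle:
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 21]))
    if isinstance(spec, MhaSpec):
        return ClassifierBundle("mha", MhaClassifier(spec, rng), spec)
    if isinstance(spec, MlpSpec):
        return ClassifierBundle("mlp", MlpClassifier(spec, rng), spec)
    raise TypeError(f"unknown classifier spec type {type(spec)!r}")


def mha_forward(model: MhaClassifier, x: np.ndarray) -> np.ndarray:
    """Evaluation-mode attention block output for a batch of vectors."""
    return model.attention_block(Tensor(np.atleast_2d(x)), train=False).data


def train_classifier(bundle: ClassifierBundle, train: FeatureTable,
                     synth: FeatureTable | None = None) -> ClassifierBundle:
    """Fit on real (plus optional synthetic) labelled feature vectors.

    The two tables are concatenated and reshuffled every epoch under the
    spec seed; loss is binary cross-entropy on the single logit with
    ASD = 1. Omitting `synth` is the real-data-only configuration.
    """
    spec = bundle.spec
    tables = [train] if synth is None else [train, synth]
    full = FeatureTable.concatenate(tables)
    if full.dim != spec.input_dim:
        raise ValueError(f"feature dim {full.dim} != spec input_dim "
                         f"{spec.input_dim}")
    x_all = full.values
    y_all = full.label_ints().astype(np.float64)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 22]))
    opt = nn.Adam(bundle.model.parameters(), lr=spec.effective_lr)
    n = x_all.shape[0]
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, spec.batch_size):
            idx = order[start:start + spec.batch_size]
            logits = bundle.model(Tensor(x_all[idx]), train=True, rng=rng)
            loss = nn.bce_with_logits(logits.reshape(-1), y_all[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"classifier loss became non-finite at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        bundle.loss_trace.append(float(np.mean(losses)))
    return bundle


def predict(bundle: ClassifierBundle,
            features: FeatureTable) -> tuple[np.ndarray, list[str]]:
    """Per-subject probability of the positive (ASD) class and hard labels.

    Deterministic: dropout off, normalization frozen. Label is ASD iff
    p ≥ 0.5.
    """
    if len(features) == 0:
        return np.empty(0), []
    if features.dim != bundle.spec.input_dim:
        raise ValueError(f"feature dim {features.dim} != spec input_dim "
                         f"{bundle.spec.input_dim}")
    logits = bundle.model(Tensor(features.values), train=False).data.reshape(-1)
    probs = 1.0 / (1.0 + np.exp(-logits))
    labels = [ASD if p >= 0.5 else HC for p in probs]
    return probs, labels


def save_bundle(bundle: ClassifierBundle, path) -> None:
    payload = {"kind": "classifier", "arch": bundle.arch, "spec": bundle.spec,
               "arrays": [a.copy() for a in bundle.model.state_arrays()],
               "loss_trace": list(bundle.loss_trace)}
    Path(path).write_bytes(pickle.dumps(payload, protocol=4))


def load_bundle(path) -> ClassifierBundle:
    payload = pickle.loads(Path(path).read_bytes())
    if payload.get("kind") != "classifier":
        raise ValueError(f"{path} is not a classifier bundle")
    bundle = build_classifier(payload["spec"])
    bundle.model.load_state(payload["arrays"])
    bundle.loss_trace = payload["loss_trace"]
    return bundle
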