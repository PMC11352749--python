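"""Attention block against a step-by-step oracle; classifier training behavior."""

import numpy as np
import pytest

from fcgan import (FeatureTable, MhaSpec, MlpSpec, build_classifier,
                   mha_forward, predict, train_classifier)
from fcgan.autodiff import Tensor
from fcgan.simulate import FixtureConfig, make_feature_fixture


def attention_oracle(model, x):
    """Independent step-by-step evaluation of scaled dot-product attention
    with residual and layer normalization, in plain numpy."""
    spec = model.spec
    t = spec.input_dim // spec.tokens
    h = spec.heads
    d = t // h
    out_rows = []
    for row in np.atleast_2d(x):
        tokens = row.reshape(spec.tokens, t)
        q = tokens @ model.wq.weight.data + model.wq.bias.data
        k = tokens @ model.wk.weight.data + model.wk.bias.data
        v = tokens @ model.wv.weight.data + model.wv.bias.data
        merged = np.zeros_like(tokens)
        for head in range(h):
            sl = slice(head * d, (head + 1) * d)
            scores = q[:, sl] @ k[:, sl].T / np.sqrt(d)
            e = np.exp(scores - scores.max(axis=-1, keepdims=True))
            attn = e / e.sum(axis=-1, keepdims=True)
            merged[:, sl] = attn @ v[:, sl]
        out = merged @ model.wo.weight.data + model.wo.bias.data
        res = tokens + out
        mu = res.mean(axis=-1, keepdims=True)
        var = ((res - mu) ** 2).mean(axis=-1, keepdims=True)
        normed = ((res - mu) / np.sqrt(var + model.ln_attn.eps)
                  * model.ln_attn.gamma.data + model.ln_attn.beta.data)
        out_rows.append(normed.reshape(-1))
    return np.array(out_rows)


def small_table(n=40, seed=0, regions=10):
    cfg = FixtureConfig(regions=regions, sites=(("A", n // 2, n // 2),),
                        planted_edges=((0, 1), (2, 3), (4, 5)), seed=seed)
    return make_feature_fixture(cfg)


class TestAttentionBlock:
    @pytest.mark.parametrize("tokens,heads", [(1, 5), (3, 3), (9, 1)])
    def test_matches_oracle(self, tokens, heads, rng):
        spec = MhaSpec(input_dim=45, heads=heads, tokens=tokens,
                       ff_widths=(8, 1), seed=2)
        model = build_classifier(spec).model
        x = rng.standard_normal((6, 45))
        assert np.abs(mha_forward(model, x) - attention_oracle(model, x)).max() \
            < 1e-6

    def test_single_token_closed_form(self, rng):
        # one key => softmax weight exactly 1, so pre-residual output is
        # wo(wv(x)) regardless of the query/key projections
        spec = MhaSpec(input_dim=20, heads=4, ff_widths=(8, 1), seed=0)
        model = build_classifier(spec).model
        x = rng.standard_normal((3, 20))
        v = x @ model.wv.weight.data + model.wv.bias.data
        closed = v @ model.wo.weight.data + model.wo.bias.data
        # reconstruct pre-residual output from the block by inverting the
        # residual + layernorm is awkward; instead set gamma/beta to pass
        # through after removing the residual
        model.wq.weight.data *= 100  # irrelevant under a single token
        assert np.abs(mha_forward(model, x)
                      - attention_oracle(model, x)).max() < 1e-10
        # direct check on the attention weights path: context == value
        pre = attention_oracle(model, x)
        mu = (x + closed).mean(-1, keepdims=True)
        var = ((x + closed - mu) ** 2).mean(-1, keepdims=True)
        expected = (x + closed - mu) / np.sqrt(var + model.ln_attn.eps)
        assert np.abs(pre - expected).max() < 1e-10

    def test_identity_projections_give_normalized_2x(self, rng):
        spec = MhaSpec(input_dim=12, heads=3, ff_widths=(4, 1), seed=0)
        model = build_classifier(spec).model
        for lin in (model.wq, model.wk, model.wv, model.wo):
            lin.weight.data = np.eye(12)
            lin.bias.data[:] = 0
        x = rng.standard_normal((4, 12))
        out = mha_forward(model, x)
        two_x = 2 * x
        mu = two_x.mean(-1, keepdims=True)
        var = two_x.var(-1, keepdims=True)
        assert np.abs(out - (two_x - mu) / np.sqrt(var + model.ln_attn.eps)
                      ).max() < 1e-10

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            MhaSpec(input_dim=6670, heads=7)


class TestBuildAndSpecs:
    def test_mlp_shapes_end_to_end(self, rng):
        spec = MlpSpec(input_dim=45, scale=0.01, seed=1)
        bundle = build_classifier(spec)
        dims = spec.scaled_widths()
        assert dims[-1] == 1
        assert bundle.model.linears[0].weight.data.shape[0] == 45
        out = bundle.model(Tensor(rng.standard_normal((5, 45))), train=False)
        assert out.data.shape == (5, 1)

    def test_reproducible_build(self):
        spec = MhaSpec(input_dim=20, heads=4, ff_widths=(8, 1), seed=7)
        a = build_classifier(spec).model
        b = build_classifier(spec).model
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data)

    def test_full_scale_mlp_widths(self):
        spec = MlpSpec()
        assert spec.scaled_widths() == [4000, 3000, 2000, 1000, 500, 50, 1]


class TestTrainPredict:
    def test_training_reduces_loss_and_separates(self):
        table = small_table(n=60, seed=3)
        spec = MhaSpec(input_dim=table.dim, heads=5, ff_widths=(30, 20, 1),
                       epochs=150, seed=1, scale=1.0, learning_rate=1e-3)
        bundle = train_classifier(build_classifier(spec), table)
        assert bundle.loss_trace[-1] < bundle.loss_trace[0]
        probs, labels = predict(bundle, table)
        acc = np.mean([l == t for l, t in zip(labels, table.labels)])
        assert acc >= 0.9

    def test_untrained_predicts_near_chance(self):
        accs = []
        for seed in range(5):
            table = small_table(n=100, seed=seed + 10)
            spec = MhaSpec(input_dim=table.dim, heads=5, ff_widths=(10, 1),
                           epochs=0, seed=seed)
            bundle = build_classifier(spec)
            _, labels = predict(bundle, table)
            accs.append(np.mean([l == t for l, t in zip(labels, table.labels)]))
        assert 0.4 <= np.mean(accs) <= 0.6

    def test_prediction_deterministic(self):
        table = small_table(n=30, seed=5)
        spec = MlpSpec(input_dim=table.dim, widths=(20, 10, 1), epochs=20,
                       seed=2, learning_rate=1e-3)
        bundle = train_classifier(build_classifier(spec), table)
        p1, l1 = predict(bundle, table)
        p2, l2 = predict(bundle, table)
        assert np.array_equal(p1, p2) and l1 == l2

    def test_threshold_convention(self):
        table = small_table(n=30, seed=5)
        spec = MlpSpec(input_dim=table.dim, widths=(10, 1), epochs=5, seed=2)
        bundle = train_classifier(build_classifier(spec), table)
        probs, labels = predict(bundle, table)
        for p, lab in zip(probs, labels):
            assert lab == ("ASD" if p >= 0.5 else "HC")

    def test_empty_table_empty_predictions(self):
        spec = MlpSpec(input_dim=5, widths=(4, 1), seed=0)
        bundle = build_classifier(spec)
        empty = FeatureTable([], [], [], np.empty((0, 5)))
        probs, labels = predict(bundle, empty)
        assert len(probs) == 0 and labels == []

    def test_width_mismatch_rejected(self, rng):
        table = small_table(n=20, seed=0)
        spec = MlpSpec(input_dim=table.dim + 1, widths=(4, 1), seed=0)
        bundle = build_classifier(spec)
        with pytest.raises(ValueError):
            train_classifier(bundle, table)
        with pytest.raises(ValueError):
            predict(bundle, table)

    def test_synth_concatenated_into_training(self):
        table = small_table(n=30, seed=1)
        synth = small_table(n=30, seed=99)
        spec = MlpSpec(input_dim=table.dim, widths=(10, 1), epochs=3, seed=0)
        b1 = train_classifier(build_classifier(spec), table, synth)
        b2 = train_classifier(build_classifier(spec), table, None)
        # with extra data the loss trajectory must differ
        assert b1.loss_trace != b2.loss_trace

    def test_bundle_roundtrip(self, tmp_path):
        from fcgan.classifier_mha import load_bundle, save_bundle

        table = small_table(n=24, seed=4)
        spec = MhaSpec(input_dim=table.dim, heads=5, ff_widths=(10, 1),
                       epochs=10, seed=3, learning_rate=1e-3)
        bundle = train_classifier(build_classifier(spec), table)
        save_bundle(bundle, tmp_path / "clf.bundle")
        loaded = load_bundle(tmp_path / "clf.bundle")
        p1, _ = predict(bundle, table)
        p2, _ = predict(loaded, table)
        assert np.array_equal(p1, p2)
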