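"""Attention encoders and integration architectures.

The multi-head block is checked against an independent brute-force oracle
that materializes every head separately with explicit numpy softmax.
"""

import numpy as np
import pytest

from dmoit._autograd import Tensor
from dmoit.models import (
    EncoderConfig,
    IntegrationModel,
    ModelSpec,
    MultiHeadSelfAttention,
    TokenEmbed,
    build_model,
    scaled_dot_attention,
)
from dmoit.nn import cross_entropy


def brute_force_mhsa(tokens, attn: MultiHeadSelfAttention):
    """Reference multi-head attention: each head materialized separately."""
    cfg = attn.cfg
    W = {k: getattr(attn, k).W.data for k in ("Wq", "Wk", "Wv", "Wo")}
    b = {k: getattr(attn, k).b.data for k in ("Wq", "Wk", "Wv", "Wo")}
    out = np.zeros_like(tokens)
    for s in range(tokens.shape[0]):  # per sample
        x = tokens[s]
        q_full = x @ W["Wq"] + b["Wq"]
        k_full = x @ W["Wk"] + b["Wk"]
        v_full = x @ W["Wv"] + b["Wv"]
        heads = []
        for h in range(cfg.num_heads):
            sl = slice(h * cfg.d_k, (h + 1) * cfg.d_k)
            q, k, v = q_full[:, sl], k_full[:, sl], v_full[:, sl]
            scores = q @ k.T / np.sqrt(cfg.d_k)
            e = np.exp(scores - scores.max(axis=1, keepdims=True))
            p = e / e.sum(axis=1, keepdims=True)
            heads.append(p @ v)
        out[s] = np.concatenate(heads, axis=1) @ W["Wo"] + b["Wo"]
    return out


class TestScaledDotAttention:
    def test_single_token_returns_value(self):
        q = np.array([[[1.0, 2.0]]])
        v = np.array([[[3.0, 4.0]]])
        out = scaled_dot_attention(q, q, v, d_k=2)
        assert np.allclose(out.data, v)

    def test_two_token_identity_projection_worked_example(self):
        x = np.array([[[1.0, 0.0], [0.0, 1.0]]])
        out = scaled_dot_attention(x, x, x, d_k=2)
        assert np.allclose(out.data[0, 0], [0.6698, 0.3302], atol=1e-4)

    def test_zero_values_give_zero_output(self):
        rng = np.random.default_rng(0)
        q = rng.standard_normal((1, 3, 4))
        out = scaled_dot_attention(q, q, np.zeros_like(q), d_k=4)
        assert np.allclose(out.data, 0)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        q = rng.standard_normal((2, 5, 4))
        _, w = scaled_dot_attention(q, q, q, d_k=4, return_weights=True)
        assert np.allclose(w.data.sum(axis=-1), 1.0, atol=1e-6)

    def test_invalid_dk_rejected(self):
        with pytest.raises(ValueError):
            scaled_dot_attention(np.zeros((1, 2, 2)), np.zeros((1, 2, 2)), np.zeros((1, 2, 2)), d_k=0)


class TestMhsaBlock:
    def test_matches_brute_force_per_head_oracle(self):
        rng = np.random.default_rng(2)
        cfg = EncoderConfig(num_heads=2, d_model=4, n_tokens=3, dropout_rate=0.0)
        attn = MultiHeadSelfAttention(cfg, np.random.default_rng(3))
        tokens = rng.standard_normal((5, 3, 4))
        out = attn(Tensor(tokens)).data
        ref = brute_force_mhsa(tokens, attn)
        assert np.abs(out - ref).max() < 1e-5

    def test_single_head_equals_plain_attention_plus_projection(self):
        rng = np.random.default_rng(4)
        cfg = EncoderConfig(num_heads=1, d_model=4, n_tokens=3, dropout_rate=0.0)
        attn = MultiHeadSelfAttention(cfg, np.random.default_rng(5))
        tokens = rng.standard_normal((2, 3, 4))
        out = attn(Tensor(tokens)).data
        q = tokens @ attn.Wq.W.data + attn.Wq.b.data
        k = tokens @ attn.Wk.W.data + attn.Wk.b.data
        v = tokens @ attn.Wv.W.data + attn.Wv.b.data
        plain = scaled_dot_attention(q, k, v, d_k=4).data
        assert np.allclose(out, plain @ attn.Wo.W.data + attn.Wo.b.data, atol=1e-10)

    def test_attention_rows_sum_to_one_in_every_head(self):
        cfg = EncoderConfig(num_heads=4, d_model=8, n_tokens=5)
        attn = MultiHeadSelfAttention(cfg, np.random.default_rng(6))
        attn(Tensor(np.random.default_rng(7).standard_normal((3, 5, 8))))
        assert attn.last_attention.shape == (3, 4, 5, 5)
        assert np.allclose(attn.last_attention.sum(axis=-1), 1.0, atol=1e-6)


class TestTokenEmbed:
    def test_output_shape(self):
        cfg = EncoderConfig(d_model=8, n_tokens=3, input_dropout=0.0)
        emb = TokenEmbed(11, cfg, np.random.default_rng(0))
        out = emb(Tensor(np.random.default_rng(1).uniform(0, 1, (7, 11))))
        assert out.shape == (7, 3, 8)

    def test_width_mismatch_rejected(self):
        cfg = EncoderConfig(d_model=8, n_tokens=3)
        emb = TokenEmbed(11, cfg, np.random.default_rng(0))
        with pytest.raises(ValueError):
            emb(Tensor(np.zeros((2, 12))))


class TestArchitectures:
    WIDTHS = [10, 8, 5]

    def _batch(self, n=6, seed=0):
        rng = np.random.default_rng(seed)
        return [rng.uniform(0, 1, (n, w)) for w in self.WIDTHS]

    @pytest.mark.parametrize(
        "arch,n_enc", [("m1", 3), ("m2", 1), ("m3", 4), ("dmoit", 4)]
    )
    def test_encoder_stack_count_and_logit_shape(self, arch, n_enc):
        model = build_model(ModelSpec(arch, self.WIDTHS, EncoderConfig()), seed=0)
        assert model.n_encoders == n_enc
        logits = model.forward(self._batch())
        assert logits.shape == (6, 2) and np.isfinite(logits.data).all()

    def test_duplicate_sample_gives_identical_logits(self):
        model = build_model(ModelSpec("dmoit", self.WIDTHS, EncoderConfig()), seed=1)
        model.eval()
        xs = self._batch()
        xs_dup = [np.vstack([x[:1], x[:1]]) for x in xs]
        logits = model.forward(xs_dup).data
        assert np.allclose(logits[0], logits[1])

    def test_eval_mode_repeatable(self):
        model = build_model(ModelSpec("m3", self.WIDTHS, EncoderConfig()), seed=2)
        model.eval()
        xs = self._batch()
        assert np.array_equal(model.forward(xs).data, model.forward(xs).data)

    def test_extreme_inputs_finite(self):
        model = build_model(ModelSpec("m2", self.WIDTHS, EncoderConfig()), seed=3)
        model.eval()
        xs = [np.ones((4, w)) for w in self.WIDTHS]
        assert np.isfinite(model.forward(xs).data).all()

    def test_missing_values_rejected(self):
        model = build_model(ModelSpec("m1", self.WIDTHS, EncoderConfig()), seed=4)
        xs = self._batch()
        xs[0][0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            model.forward(xs)

    def test_parameter_count_structural_accounting(self):
        """dmoit = m1 + m2 up to the width of the combined MLP head."""
        cfg = EncoderConfig(d_model=16, num_heads=2)
        counts = {
            arch: build_model(ModelSpec(arch, self.WIDTHS, cfg), seed=0).n_parameters()
            for arch in ("m1", "m2", "dmoit")
        }
        d, L = cfg.d_model, len(self.WIDTHS)

        def head_params(w_in):
            return (w_in * d + d) + (d * 2 + 2)

        expected = (
            counts["m1"]
            + counts["m2"]
            - head_params(L * d)
            - head_params(d)
            + head_params((L + 1) * d)
        )
        assert counts["dmoit"] == expected

    def test_gradient_reaches_every_parameter(self):
        for arch in ("m1", "m2", "m3", "dmoit"):
            model = build_model(ModelSpec(arch, self.WIDTHS, EncoderConfig(input_dropout=0.0)), seed=5)
            xs = self._batch(n=8, seed=6)
            y = np.array([0, 1] * 4)
            loss = cross_entropy(model.forward(xs), y)
            loss.backward()
            dead = [p for p in model.parameters() if p.grad is None or not np.any(p.grad)]
            assert not dead, f"{arch}: {len(dead)} parameters with zero gradient"

    def test_unknown_tag_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("m4", self.WIDTHS)

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError):
            EncoderConfig(num_heads=3, d_model=32)
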