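"""Multi-head self-attention encoders and the four integration architectures.

Each omics layer is a flat feature vector per sample. A linear layer maps
it to ``n_tokens`` tokens of width ``d_model`` (plus learned position
embeddings), which feed a stack of pre-norm transformer encoder blocks;
token outputs are mean-pooled back to one vector per sample.

Architectures (L = number of omics layers):

* ``m1`` — one encoder per layer; pooled outputs concatenated into an MLP.
  Captures intra-omics structure only.
* ``m2`` — layers concatenated feature-wise, one shared encoder, MLP.
  Captures inter-omics structure but must attend across heterogeneous
  layers at once.
* ``m3`` — per-layer encoders, token sequences concatenated, a second
  encoder over the combined sequence, pool, MLP.
* ``dmoit`` — the dual design: M1's per-layer paths AND M2's shared path in
  parallel; all pooled outputs concatenated into the MLP head.

Encoders within one model share hyperparameters (not weights).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autograd import Tensor, concat
from .nn import Dropout, LayerNorm, Linear, Module

ARCH_TAGS = ("m1", "m2", "m3", "dmoit")


@dataclass
class EncoderConfig:
    """Hyperparameters shared by every encoder stack in a model."""

    num_heads: int = 2
    num_blocks: int = 1
    d_model: int = 32
    dropout_rate: float = 0.1
    n_tokens: int = 4
    #: denoising-style dropout on the flat feature vector before embedding;
    #: the main regularizer against memorizing noise features when p >> n
    input_dropout: float = 0.3

    def __post_init__(self) -> None:
        if self.d_model % self.num_heads != 0:
            raise ValueError(
                f"d_model={self.d_model} not divisible by num_heads={self.num_heads}"
            )
        if self.n_tokens < 2:
            raise ValueError("n_tokens must be >= 2")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if not 0 <= self.input_dropout < 1:
            raise ValueError("input_dropout must lie in [0, 1)")

    @property
    def d_k(self) -> int:
        return self.d_model // self.num_heads


@dataclass
class ModelSpec:
    """Architecture wiring: tag, per-layer input widths, encoder config."""

    arch: str
    layer_widths: list[int]
    encoder: EncoderConfig = field(default_factory=EncoderConfig)

    def __post_init__(self) -> None:
        if self.arch not in ARCH_TAGS:
            raise ValueError(f"unknown architecture tag {self.arch!r}")
        if not self.layer_widths or any(w < 1 for w in self.layer_widths):
            raise ValueError("layer_widths must be positive")


def scaled_dot_attention(Q, K, V, d_k: int, return_weights: bool = False):
    """softmax(Q K^T / sqrt(d_k)) V on the trailing two axes.

    Accepts numpy arrays or Tensors; every softmax row sums to one.
    """
    if d_k <= 0:
        raise ValueError("d_k must be positive")
    Q = Q if isinstance(Q, Tensor) else Tensor(Q)
    K = K if isinstance(K, Tensor) else Tensor(K)
    V = V if isinstance(V, Tensor) else Tensor(V)
    scores = (Q @ K.swapaxes(-1, -2)) / float(np.sqrt(d_k))
    weights = scores.softmax(axis=-1)
    out = weights @ V
    if return_weights:
        return out, weights
    return out


class TokenEmbed(Module):
    """Affine map from a flat omics vector to a token sequence.

    ``(batch, p) -> (batch, n_tokens, d_model)`` with learned per-token
    position embeddings added.
    """

    def __init__(self, p_in: int, cfg: EncoderConfig, rng: np.random.Generator):
        self.p_in = p_in
        self.cfg = cfg
        self.proj = Linear(p_in, cfg.n_tokens * cfg.d_model, rng)
        self.in_drop = Dropout(cfg.input_dropout, rng)
        self.pos = Tensor(
            0.02 * rng.standard_normal((cfg.n_tokens, cfg.d_model)), requires_grad=True
        )

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.p_in:
            raise ValueError(f"expected input width {self.p_in}, got {x.shape[-1]}")
        x = self.in_drop(x)
        tokens = self.proj(x).reshape(x.shape[0], self.cfg.n_tokens, self.cfg.d_model)
        return tokens + self.pos


class MultiHeadSelfAttention(Module):
    """h parallel scaled-dot-product heads, concatenated, projected by W_o."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.cfg = cfg
        d = cfg.d_model
        self.Wq = Linear(d, d, rng)
        self.Wk = Linear(d, d, rng)
        self.Wv = Linear(d, d, rng)
        self.Wo = Linear(d, d, rng)
        self.last_attention: np.ndarray | None = None  # (batch, h, T, T)

    def _split_heads(self, x: Tensor, batch: int, T: int) -> Tensor:
        cfg = self.cfg
        return x.reshape(batch, T, cfg.num_heads, cfg.d_k).transpose(0, 2, 1, 3)

    def __call__(self, tokens: Tensor) -> Tensor:
        batch, T, d = tokens.shape
        q = self._split_heads(self.Wq(tokens), batch, T)
        k = self._split_heads(self.Wk(tokens), batch, T)
        v = self._split_heads(self.Wv(tokens), batch, T)
        out, weights = scaled_dot_attention(q, k, v, self.cfg.d_k, return_weights=True)
        self.last_attention = weights.data
        merged = out.transpose(0, 2, 1, 3).reshape(batch, T, d)
        return self.Wo(merged)


class EncoderBlock(Module):
    """Pre-norm transformer block: MHSA and position-wise feed-forward."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        d = cfg.d_model
        self.ln1 = LayerNorm(d)
        self.attn = MultiHeadSelfAttention(cfg, rng)
        self.drop1 = Dropout(cfg.dropout_rate, rng)
        self.ln2 = LayerNorm(d)
        self.ff1 = Linear(d, 4 * d, rng)
        self.ff2 = Linear(4 * d, d, rng)
        self.drop2 = Dropout(cfg.dropout_rate, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.drop1(self.attn(self.ln1(x)))
        x = x + self.drop2(self.ff2(self.ff1(self.ln2(x)).relu()))
        return x


class Encoder(Module):
    """Stack of encoder blocks with a final layer norm."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.blocks = [EncoderBlock(cfg, rng) for _ in range(cfg.num_blocks)]
        self.ln_out = LayerNorm(cfg.d_model)

    def __call__(self, x: Tensor) -> Tensor:
        for block in self.blocks:
            x = block(x)
        return self.ln_out(x)

    def attention_maps(self) -> list[np.ndarray]:
        return [b.attn.last_attention for b in self.blocks]


def _pool(tokens: Tensor) -> Tensor:
    """Mean over the token axis: (batch, T, d) -> (batch, d)."""
    return tokens.mean(axis=1)


class MLPHead(Module):
    """One hidden layer of width d_model, dropout, two output logits."""

    def __init__(self, d_in: int, cfg: EncoderConfig, rng: np.random.Generator):
        self.fc1 = Linear(d_in, cfg.d_model, rng)
        self.drop = Dropout(cfg.dropout_rate, rng)
        self.fc2 = Linear(cfg.d_model, 2, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.drop(self.fc1(x).relu()))


class IntegrationModel(Module):
    """Common forward interface over a list of per-layer sample batches."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        self.spec = spec
        cfg = spec.encoder
        rng = np.random.default_rng(seed)
        widths = spec.layer_widths
        L = len(widths)
        arch = spec.arch

        self.layer_embeds: list[TokenEmbed] = []
        self.layer_encoders: list[Encoder] = []
        self.shared_embed: TokenEmbed | None = None
        self.shared_encoder: Encoder | None = None

        if arch in ("m1", "m3", "dmoit"):
            self.layer_embeds = [TokenEmbed(w, cfg, rng) for w in widths]
            self.layer_encoders = [Encoder(cfg, rng) for _ in widths]
        if arch in ("m2", "dmoit"):
            self.shared_embed = TokenEmbed(sum(widths), cfg, rng)
            self.shared_encoder = Encoder(cfg, rng)
        if arch == "m3":
            self.shared_encoder = Encoder(cfg, rng)  # over concatenated tokens

        head_width = {
            "m1": L * cfg.d_model,
            "m2": cfg.d_model,
            "m3": cfg.d_model,
            "dmoit": (L + 1) * cfg.d_model,
        }[arch]
        self.head = MLPHead(head_width, cfg, rng)

    # number of encoder stacks, for structural checks
    @property
    def n_encoders(self) -> int:
        n = len(self.layer_encoders)
        if self.shared_encoder is not None:
            n += 1
        return n

    def __call__(self, xs: list[np.ndarray]) -> Tensor:
        return self.forward(xs)

    def forward(self, xs: list[np.ndarray]) -> Tensor:
        """Class logits (batch, 2) from per-layer batches (batch, p_l)."""
        if len(xs) != len(self.spec.layer_widths):
            raise ValueError("wrong number of omics layers")
        arrays = []
        for x, w in zip(xs, self.spec.layer_widths):
            a = np.asarray(x, dtype=float)
            if a.ndim != 2 or a.shape[1] != w:
                raise ValueError(f"layer batch must be (batch, {w})")
            if np.isnan(a).any():
                raise ValueError("inputs contain missing values; impute first")
            arrays.append(Tensor(a))
        arch = self.spec.arch

        pooled: list[Tensor] = []
        if arch == "m1":
            for x, emb, enc in zip(arrays, self.layer_embeds, self.layer_encoders):
                pooled.append(_pool(enc(emb(x))))
            feat = concat(pooled, axis=-1)
        elif arch == "m2":
            x = concat(arrays, axis=-1)
            feat = _pool(self.shared_encoder(self.shared_embed(x)))
        elif arch == "m3":
            token_seqs = [
                enc(emb(x))
                for x, emb, enc in zip(arrays, self.layer_embeds, self.layer_encoders)
            ]
            combined = concat(token_seqs, axis=1)  # (batch, L*T, d)
            feat = _pool(self.shared_encoder(combined))
        else:  # dmoit
            for x, emb, enc in zip(arrays, self.layer_embeds, self.layer_encoders):
                pooled.append(_pool(enc(emb(x))))
            shared_in = concat(arrays, axis=-1)
            pooled.append(_pool(self.shared_encoder(self.shared_embed(shared_in))))
            feat = concat(pooled, axis=-1)
        return self.head(feat)

    def predict(self, xs: list[np.ndarray]) -> np.ndarray:
        was_training = self.training
        self.eval()
        logits = self.forward(xs)
        if was_training:
            self.train()
        return np.argmax(logits.data, axis=1)

    def attention_maps(self) -> list[np.ndarray]:
        maps = []
        for enc in self.layer_encoders:
            maps.extend(enc.attention_maps())
        if self.shared_encoder is not None:
            maps.extend(self.shared_encoder.attention_maps())
        return [m for m in maps if m is not None]


def build_model(spec: ModelSpec, seed: int = 0) -> IntegrationModel:
    """Initialize an integration model from its spec; reproducible per seed."""
    return IntegrationModel(spec, seed=seed)


def embed_tokens(x: np.ndarray, embed: TokenEmbed) -> np.ndarray:
    """Functional view of a token embedding (evaluation mode)."""
    return embed(Tensor(np.asarray(x, dtype=float))).data
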