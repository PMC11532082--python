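"""Fusion building blocks: FCN blocks, channel-attention feature enhancement
(FEM), cross-attention feature interaction (FIM), and the multi-level fusion
module (MLFM) that combines them.

Shapes follow one convention throughout: the FCN branch carries per-sample
vectors (N, C); the CNN branch carries NCHW maps whose channel count at each
fusion point equals the FCN vector length, so the two branches can exchange
information channel-wise.
"""

from __future__ import annotations

import math

import numpy as np

from ..nn import (
    BatchNorm1d,
    Conv2d,
    GlobalAvgPool2d,
    Linear,
    Module,
    ModuleList,
    ReLU,
    Sequential,
)
from ..nn.tensor import Tensor, concat, softmax

__all__ = [
    "FCNBlock",
    "FEM",
    "FEMSpatial",
    "CrossAttention",
    "cross_attention",
    "FIM",
    "MLFM",
    "group_sizes",
]


def _identity_concat_init(linear: Linear, channels: int, rng: np.random.Generator) -> None:
    """Initialize a (2C -> C) concat-reduction as identity on the first C
    inputs and zero on the second C, plus small noise.

    The reduction then starts as a pass-through of the enhanced feature and
    learns to blend in the second (interacted/grouped) feature gradually —
    the same idea as zero-initializing residual branches.
    """
    w = 0.01 * rng.normal(size=linear.weight.shape)
    w[:channels, :] += np.eye(channels)
    linear.weight.data[...] = w


def _identity_concat_conv_init(conv, channels: int, rng: np.random.Generator) -> None:
    """1x1-conv analogue of :func:`_identity_concat_init` for NCHW maps."""
    w = 0.01 * rng.normal(size=conv.weight.shape)
    for c in range(channels):
        w[c, c, 0, 0] += 1.0
    conv.weight.data[...] = w


class FCNBlock(Module):
    """One FCN stage: three FC layers with BN+ReLU after the first two.

    Hidden widths are half then a quarter of the input width (floored, with
    a minimum of 4); the output width must equal the channel count of the
    paired CNN stage.
    """

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        if in_dim < 4:
            raise ValueError(f"FCN block needs in_dim >= 4, got {in_dim}")
        h1 = max(4, in_dim // 2)
        h2 = max(4, in_dim // 4)
        self.hidden_dims = (h1, h2)
        self.net = Sequential(
            Linear(in_dim, h1, rng), BatchNorm1d(h1), ReLU(),
            Linear(h1, h2, rng), BatchNorm1d(h2), ReLU(),
            Linear(h2, out_dim, rng),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


def group_sizes(channels: int, n_groups: int) -> list[int]:
    """Split ``channels`` into ``n_groups`` near-equal parts; the first
    ``channels % n_groups`` groups get one extra channel."""
    n_groups = min(n_groups, channels)
    base, extra = divmod(channels, n_groups)
    return [base + (1 if i < extra else 0) for i in range(n_groups)]


class FEM(Module):
    """Channel-attention feature enhancement for a (N, C) feature vector.

    Attention weights: ``W_f = sigmoid(fc2(relu(BN(fc1(F)))))`` with hidden
    width ``C // 2``; the enhanced feature is ``F_e = W_f * BN(F)``.  In
    parallel, F is split into channel groups, each refined by a two-FC-layer
    module with a BN between; the concatenation ``[F_e, F_s1]`` is reduced
    back to width C by a final FC layer.
    """

    def __init__(self, channels: int, n_groups: int, rng: np.random.Generator):
        super().__init__()
        hidden = max(1, channels // 2)
        self.fc1 = Linear(channels, hidden, rng)
        self.bn_h = BatchNorm1d(hidden)
        self.fc2 = Linear(hidden, channels, rng)
        self.bn_in = BatchNorm1d(channels)
        self.group_sizes = group_sizes(channels, n_groups)
        self.group_modules = ModuleList(
            [
                Sequential(Linear(g, g, rng), BatchNorm1d(g), Linear(g, g, rng))
                for g in self.group_sizes
            ]
        )
        self.reduce = Linear(2 * channels, channels, rng)
        _identity_concat_init(self.reduce, channels, rng)

    def weights(self, f: Tensor) -> Tensor:
        """The channel-attention weight vector ``W_f``, entries in (0, 1)."""
        return self.fc2(self.bn_h(self.fc1(f)).relu()).sigmoid()

    def forward(self, f: Tensor, return_state: bool = False):
        w = self.weights(f)
        f_e = w * self.bn_in(f)
        parts = []
        start = 0
        for g, mod in zip(self.group_sizes, self.group_modules):
            parts.append(mod(f[:, start : start + g]))
            start += g
        f_s1 = concat(parts, axis=1)
        out = self.reduce(concat([f_e, f_s1], axis=1))
        if return_state:
            return out, {"W_f": w, "F_e": f_e, "F_s1": f_s1}
        return out


class FEMSpatial(Module):
    """FEM for an NCHW map: global-average-pool to a channel vector, run the
    vector FEM, modulate the map channel-wise with the result, and restore
    the channel count with a 1x1 convolution."""

    def __init__(self, channels: int, n_groups: int, rng: np.random.Generator):
        super().__init__()
        self.fem = FEM(channels, n_groups, rng)
        self.pool = GlobalAvgPool2d()
        self.conv = Conv2d(channels, channels, 1, rng)
        w = 0.01 * rng.normal(size=self.conv.weight.shape)
        for c in range(channels):
            w[c, c, 0, 0] += 1.0
        self.conv.weight.data[...] = w

    def channel_scale(self, x: Tensor) -> Tensor:
        """The per-channel modulation vector: the vector FEM applied to the
        pooled channel descriptor."""
        return self.fem(self.pool(x))

    def forward(self, x: Tensor) -> Tensor:
        s = self.channel_scale(x)
        n, c = s.shape
        y = x * s.reshape(n, c, 1, 1)
        return self.conv(y)


def cross_attention(query: Tensor, context: Tensor, tokens: int):
    """Scaled dot-product cross attention between two (N, C) vectors.

    Both vectors are reshaped into ``tokens`` tokens of width ``C / tokens``;
    the query branch supplies Q and the context branch supplies K and V:
    ``Q_e = softmax(Q K^T / sqrt(d)) V``.  Returns the attended output
    flattened back to (N, C) and the attention matrix (N, T, T), each row a
    probability vector.
    """
    n, c = query.shape
    if c % tokens != 0:
        raise ValueError(f"feature width {c} not divisible by token count {tokens}")
    d = c // tokens
    q = query.reshape(n, tokens, d)
    k = context.reshape(n, tokens, d)
    v = context.reshape(n, tokens, d)
    logits = (q @ k.transpose(0, 2, 1)) * (1.0 / math.sqrt(d))
    attn = softmax(logits, axis=-1)
    out = (attn @ v).reshape(n, c)
    return out, attn


class CrossAttention(Module):
    """Cross attention, optionally with learned Q/K/V projections.

    The default uses the features directly as Q, K and V; ``learned=True``
    inserts one linear projection per role."""

    def __init__(self, channels: int, tokens: int, rng: np.random.Generator, learned: bool = False):
        super().__init__()
        if channels % tokens != 0:
            raise ValueError(
                f"channel count {channels} must be divisible by fim_tokens={tokens}"
            )
        self.tokens = tokens
        self.learned = learned
        if learned:
            self.proj_q = Linear(channels, channels, rng)
            self.proj_k = Linear(channels, channels, rng)
            self.proj_v = Linear(channels, channels, rng)

    def forward(self, query: Tensor, context: Tensor):
        if self.learned:
            n, c = query.shape
            d = c // self.tokens
            q = self.proj_q(query).reshape(n, self.tokens, d)
            k = self.proj_k(context).reshape(n, self.tokens, d)
            v = self.proj_v(context).reshape(n, self.tokens, d)
            logits = (q @ k.transpose(0, 2, 1)) * (1.0 / math.sqrt(d))
            attn = softmax(logits, axis=-1)
            return (attn @ v).reshape(n, c), attn
        return cross_attention(query, context, self.tokens)


class FIM(Module):
    """Cross-attention feature interaction with a residual path:

    ``F'' = BN(fc(BN(F') + Q_e)) + F'`` where ``Q_e`` attends from this
    branch's feature (query) over the other branch's feature (key/value).
    With fc and both BN affine terms zeroed the module reduces to the
    identity on F'.
    """

    def __init__(self, channels: int, tokens: int, rng: np.random.Generator, learned: bool = False):
        super().__init__()
        self.attn = CrossAttention(channels, tokens, rng, learned=learned)
        self.bn_pre = BatchNorm1d(channels)
        self.fc = Linear(channels, channels, rng)
        self.bn_post = BatchNorm1d(channels)

    def forward(self, own: Tensor, other: Tensor) -> Tensor:
        q_e, _ = self.attn(own, other)
        return self.bn_post(self.fc(self.bn_pre(own) + q_e)) + own


class MLFM(Module):
    """Multi-level fusion module bridging the two branches at one depth.

    Input: the FCN stage output ``F`` (N, C) and the CNN stage output ``C``
    (N, C, H, W).  FEMs enhance each branch (``F'``, ``C'``), FIMs exchange
    information between them (``F''``, ``C''``), and each branch
    concatenates its enhanced and interacted features and reduces back to
    the input shape (FC layer on the vector side, 1x1 convolution on the
    spatial side, with ``C''`` broadcast over space).  Disabled modules pass
    their inputs through, so ablations keep the wiring intact.
    """

    def __init__(
        self,
        channels: int,
        n_groups: int,
        tokens: int,
        rng: np.random.Generator,
        use_fem: bool = True,
        use_fim: bool = True,
        learned_qkv: bool = False,
    ):
        super().__init__()
        self.channels = channels
        self.use_fem = use_fem
        self.use_fim = use_fim
        self.fem_f = FEM(channels, n_groups, rng) if use_fem else None
        self.fem_c = FEMSpatial(channels, n_groups, rng) if use_fem else None
        self.fim_f = FIM(channels, tokens, rng, learned=learned_qkv) if use_fim else None
        self.fim_c = FIM(channels, tokens, rng, learned=learned_qkv) if use_fim else None
        self.pool = GlobalAvgPool2d()
        self.reduce_l = Linear(2 * channels, channels, rng)
        _identity_concat_init(self.reduce_l, channels, rng)
        self.reduce_c = Conv2d(2 * channels, channels, 1, rng)
        _identity_concat_conv_init(self.reduce_c, channels, rng)
        self.n_calls = 0  # forward-invocation counter (instrumentation hook)

    def forward(self, f: Tensor, cmap: Tensor) -> tuple[Tensor, Tensor]:
        self.n_calls += 1
        f_p = self.fem_f(f) if self.use_fem else f
        c_map_p = self.fem_c(cmap) if self.use_fem else cmap
        c_vec_p = self.pool(c_map_p)
        if self.use_fim:
            f_pp = self.fim_f(f_p, c_vec_p)
            c_pp = self.fim_c(c_vec_p, f_p)
        else:
            f_pp, c_pp = f_p, c_vec_p
        f_l = self.reduce_l(concat([f_p, f_pp], axis=1))
        n, c = c_pp.shape
        h, w = c_map_p.shape[2], c_map_p.shape[3]
        c_b = c_pp.reshape(n, c, 1, 1) * Tensor(np.ones((1, 1, h, w)))
        f_c = self.reduce_c(concat([c_map_p, c_b], axis=1))
        return f_l, f_c
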