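"""The decoder-only translation model.

The fused input sequence is [mut_1 .. mut_K, start, e_1 .. e_K]: K
mutation-context embeddings, a learned start token, then the coalescence
token embeddings, for a fixed latent length of 2K+1 (1,001 at the default
K=500). A translation-aware fused-causal mask lets every
coalescence-stream slot attend to all K mutation slots plus the earlier
coalescence stream, while mutation slots are causal among themselves.
Next-coalescence prediction reads logits at the coalescence-stream slots:
the logits at the start token predict e_1 and the logits at the slot
carrying e_i predict e_{i+1}, exactly as in GPT-style next-token
prediction. Rotary phases encode the base-window index, shared between a
mutation slot and its paired coalescence slot so the two streams align
spatially (the start token sits at phase -1).

Tokens index a 324-bin log grid over the dimensionless ratio
t / T-bar (see `coaltrace.timescale`); the intercept T-bar is restored at
decode time from the Poisson-Gamma clock posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator

from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import (Block, Dropout, Embedding, LayerNorm, Linear, Module,
                        rotary_cos_sin)
from .timescale import N_BINS_DEFAULT, TimeDiscretization


@dataclass(frozen=True)
class ModelConfig:
    n_windows: int = 500  # K
    n_bins: int = N_BINS_DEFAULT
    embed_dim: int = 512
    n_layers: int = 6
    n_heads: int = 8
    dropout: float = 0.1
    n_scales: int = 7
    n_freq: int = 49

    def __post_init__(self):
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.n_windows < 1:
            raise ValueError("need at least one window")

    @property
    def latent_len(self) -> int:
        return 2 * self.n_windows + 1

    @property
    def d_in(self) -> int:
        # flattened (Z, WS, N) per window plus the WS accessibility fractions
        return 2 * self.n_scales * self.n_freq + self.n_scales

    def to_dict(self) -> dict:
        return asdict(self)


def tiny_config(**kw) -> ModelConfig:
    """2-layer / E=64 / K=50 configuration for CPU tests (<1M parameters)."""
    base = dict(n_windows=50, embed_dim=64, n_layers=2, n_heads=4)
    base.update(kw)
    return ModelConfig(**base)


def translation_mask(K: int, n_tokens: int | None = None) -> np.ndarray:
    """Boolean attention-permission matrix for the fused sequence.

    Rows are queries, columns keys, True = may attend. Mutation slot j
    attends to mutation slots <= j. Every coalescence-stream slot (start
    included) attends to all K mutation slots and to coalescence-stream
    slots up to and including itself; no slot sees future coalescence
    tokens.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    T = K if n_tokens is None else n_tokens
    if T > K:
        raise ValueError("token count exceeds K")
    L = K + 1 + T
    allowed = np.zeros((L, L), dtype=bool)
    tri = np.tril(np.ones((K, K), dtype=bool))
    allowed[:K, :K] = tri
    allowed[K:, :K] = True
    allowed[K:, K:] = np.tril(np.ones((T + 1, T + 1), dtype=bool))
    return allowed


def fused_positions(K: int, n_tokens: int | None = None) -> np.ndarray:
    """Rotary phase (base-window index) per fused-sequence slot."""
    T = K if n_tokens is None else n_tokens
    return np.concatenate([np.arange(K), [-1], np.arange(T)]).astype(np.float64)


_NEG = np.float32(-1e9)


def mask_bias(K: int, n_tokens: int | None = None) -> np.ndarray:
    return np.where(translation_mask(K, n_tokens), np.float32(0.0), _NEG)


class CoalescenceTransformer(Module):
    """GPT-2-style decoder over the fused mutation/coalescence sequence."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        E = config.embed_dim
        self.embed_fc = Linear(config.d_in, E, rng)
        self.embed_proj = Linear(E, E, rng)
        self.coal_embed = Embedding(config.n_bins, E, rng)
        self.start_token = Tensor(rng.normal(0.0, 0.02, size=(E,)), requires_grad=True)
        self.drop = Dropout(config.dropout)
        self.blocks = [Block(E, config.n_heads, config.dropout, rng)
                       for _ in range(config.n_layers)]
        self.ln_f = LayerNorm(E)
        self.head = Linear(E, config.n_bins, rng)
        # feature standardization constants, set from training data
        self.feat_mean = np.zeros(config.d_in, dtype=np.float32)
        self.feat_std = np.ones(config.d_in, dtype=np.float32)

    # -- input plumbing ---------------------------------------------------
    def set_feature_norm(self, mean: np.ndarray, std: np.ndarray) -> None:
        self.feat_mean = np.asarray(mean, dtype=np.float32).reshape(self.config.d_in)
        self.feat_std = np.maximum(np.asarray(std, dtype=np.float32), 1e-6) \
            .reshape(self.config.d_in)

    def input_features(self, mc_density, access) -> Tensor:
        """(B, Z, WS, K, N) density + (B, WS, K) access -> (B, K, d_in)."""
        cfg = self.config
        if isinstance(mc_density, Tensor):
            B = mc_density.shape[0]
            x = mc_density.transpose(0, 3, 1, 2, 4).reshape(
                B, cfg.n_windows, 2 * cfg.n_scales * cfg.n_freq)
            acc = Tensor(np.ascontiguousarray(
                np.swapaxes(np.asarray(access, dtype=np.float32), 1, 2)))
            x = ag.concat([x, acc], axis=-1)
        else:
            arr = np.asarray(mc_density, dtype=np.float32)
            B = arr.shape[0]
            flat = np.transpose(arr, (0, 3, 1, 2, 4)).reshape(
                B, cfg.n_windows, 2 * cfg.n_scales * cfg.n_freq)
            acc = np.swapaxes(np.asarray(access, dtype=np.float32), 1, 2)
            x = Tensor(np.concatenate([flat, acc], axis=-1))
        return (x - Tensor(self.feat_mean)) * Tensor(1.0 / self.feat_std)

    def embed_mutation_context(self, mc_density, access) -> Tensor:
        """Pointwise projection of each window's features into the latent
        space: (B, ...) -> (B, K, E), windows independent of one another."""
        x = self.input_features(mc_density, access)
        return self.embed_proj(ag.gelu(self.embed_fc(x)))

    def fused_sequence(self, mut_emb: Tensor, coal_tokens: np.ndarray) -> Tensor:
        """[mut_1..K, start, e_1..e_T] -> (B, K+1+T, E)."""
        B, K, E = mut_emb.shape
        T = coal_tokens.shape[1] if coal_tokens.size else 0
        if T > K:
            raise ValueError("more coalescence tokens than windows")
        start = ag.reshape(self.start_token, (1, 1, E))
        start = start + Tensor(np.zeros((B, 1, E), dtype=np.float32))
        parts = [mut_emb, start]
        if T:
            parts.append(self.coal_embed(coal_tokens.astype(np.int64)))
        return ag.concat(parts, axis=1)

    # -- forward ----------------------------------------------------------
    def forward(self, mc_density, access, coal_tokens: np.ndarray) -> Tensor:
        """Logits over bins at every fused slot: (B, K+1+T, n_bins).

        Prediction logits live at slots [K, K+T]: slot K (start) predicts
        e_1 and slot K+i predicts e_{i+1}.
        """
        cfg = self.config
        mut = self.embed_mutation_context(mc_density, access)
        B, K, E = mut.shape
        coal_tokens = np.asarray(coal_tokens, dtype=np.int64)
        if coal_tokens.size == 0:
            coal_tokens = np.zeros((B, 0), dtype=np.int64)
        if coal_tokens.ndim != 2 or coal_tokens.shape[0] != B:
            raise ValueError("coal_tokens must be (B, T)")
        if coal_tokens.size and (coal_tokens.min() < 0 or coal_tokens.max() >= cfg.n_bins):
            raise ValueError("coalescence token outside bin range")
        T = coal_tokens.shape[1]
        x = self.drop(self.fused_sequence(mut, coal_tokens))
        bias = mask_bias(K, T)
        cos, sin = rotary_cos_sin(fused_positions(K, T), E // cfg.n_heads)
        for blk in self.blocks:
            x = blk(x, bias, cos, sin)
        logits = self.head(self.ln_f(x))
        if not np.all(np.isfinite(logits.data)):
            raise FloatingPointError("non-finite logits; aborting forward")
        return logits

    def prediction_logits(self, logits: Tensor, n_pred: int) -> Tensor:
        """Slice the slots that predict e_1 .. e_{n_pred}."""
        K = self.config.n_windows
        return logits[:, K:K + n_pred, :]

    __call__ = forward


# ---------------------------------------------------------------------------
# pure-numpy incremental decoding (KV cache); correctness asserted in tests


def _ln_np(x, g, b, eps=1e-5):
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return g * xc / np.sqrt(var + eps) + b


def _gelu_np(x):
    c = np.sqrt(2.0 / np.pi)
    return 0.5 * x * (1.0 + np.tanh(c * (x + 0.044715 * x ** 3)))


def _softmax_np(x):
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _rot_np(x, cos, sin):
    half = x.shape[-1] // 2
    xr = np.concatenate([-x[..., half:], x[..., :half]], axis=-1)
    return x * cos + xr * sin


class IncrementalDecoder:
    """Token-by-token decoding with cached keys/values (eval mode only).

    Numerically equivalent to `CoalescenceTransformer.forward` with the
    full fused mask; exists because autoregressive sampling would
    otherwise cost K full forward passes per trajectory.
    """

    def __init__(self, net: CoalescenceTransformer, mc_density: np.ndarray,
                 access: np.ndarray):
        self.net = net
        cfg = net.config
        self.cfg = cfg
        E, H = cfg.embed_dim, cfg.n_heads
        self.hd = E // H
        with ag.no_grad():
            mut = net.embed_mutation_context(
                np.asarray(mc_density, dtype=np.float32),
                np.asarray(access, dtype=np.float32)).data
        B, K, _ = mut.shape
        self.B, self.K = B, K
        start = np.broadcast_to(net.start_token.data, (B, 1, E))
        x = np.concatenate([mut, start], axis=1)  # prefix: mut + start
        pos = fused_positions(K, 0)
        cos, sin = rotary_cos_sin(pos, self.hd)
        bias = mask_bias(K, 0)
        self.k_cache: list[np.ndarray] = []
        self.v_cache: list[np.ndarray] = []
        for blk in net.blocks:
            h = _ln_np(x, blk.ln1.gamma.data, blk.ln1.beta.data)
            q, k, v = self._qkv(blk, h)
            q = _rot_np(q, cos, sin)
            k = _rot_np(k, cos, sin)
            scores = q @ np.swapaxes(k, -1, -2) / np.sqrt(self.hd) + bias
            att = _softmax_np(scores) @ v  # (B, H, L, hd)
            x = x + self._proj(blk, att)
            x = x + self._mlp(blk, x)
            self.k_cache.append(k)
            self.v_cache.append(v)
        self.n_tokens = 0
        self._last_hidden = x[:, -1]  # start slot
        self._rot_base = 1.0 / 10000.0 ** (np.arange(self.hd // 2) / (self.hd // 2))

    def _qkv(self, blk, h):
        B, L, E = h.shape
        H, hd = self.cfg.n_heads, self.hd
        qkv = h @ blk.attn.qkv.W.data + blk.attn.qkv.b.data
        qkv = qkv.reshape(B, L, 3, H, hd).transpose(2, 0, 3, 1, 4)
        return qkv[0], qkv[1], qkv[2]

    def _proj(self, blk, att):
        B = att.shape[0]
        E = self.cfg.embed_dim
        out = att.transpose(0, 2, 1, 3).reshape(B, -1, E)
        return out @ blk.attn.proj.W.data + blk.attn.proj.b.data

    def _mlp(self, blk, x):
        h = _ln_np(x, blk.ln2.gamma.data, blk.ln2.beta.data)
        h = _gelu_np(h @ blk.mlp.fc.W.data + blk.mlp.fc.b.data)
        return h @ blk.mlp.proj.W.data + blk.mlp.proj.b.data

    def logits(self) -> np.ndarray:
        """Logits at the newest coalescence-stream slot: predicts the next e."""
        net = self.net
        h = _ln_np(self._last_hidden, net.ln_f.gamma.data, net.ln_f.beta.data)
        return h @ net.head.W.data + net.head.b.data

    def step(self, tokens: np.ndarray) -> None:
        """Append sampled tokens ê_{i} (i = current count + 1) to the context."""
        if self.n_tokens >= self.K:
            raise ValueError("context full")
        cfg = self.cfg
        tokens = np.asarray(tokens, dtype=np.int64).reshape(self.B)
        pos = float(self.n_tokens)  # shared phase with mutation slot
        ang = pos * self._rot_base
        cos = np.concatenate([np.cos(ang), np.cos(ang)]).astype(np.float32)
        sin = np.concatenate([np.sin(ang), np.sin(ang)]).astype(np.float32)
        x = self.net.coal_embed.W.data[tokens][:, None, :]  # (B, 1, E)
        for li, blk in enumerate(self.net.blocks):
            h = _ln_np(x, blk.ln1.gamma.data, blk.ln1.beta.data)
            q, k, v = self._qkv(blk, h)
            q = _rot_np(q, cos, sin)
            k = _rot_np(k, cos, sin)
            self.k_cache[li] = np.concatenate([self.k_cache[li], k], axis=2)
            self.v_cache[li] = np.concatenate([self.v_cache[li], v], axis=2)
            scores = q @ np.swapaxes(self.k_cache[li], -1, -2) / np.sqrt(self.hd)
            att = _softmax_np(scores) @ self.v_cache[li]
            x = x + self._proj(blk, att)
            x = x + self._mlp(blk, x)
        self.n_tokens += 1
        self._last_hidden = x[:, -1]


def sample_trajectory(net: CoalescenceTransformer, mc_density: np.ndarray,
                      access: np.ndarray, rng: np.random.Generator,
                      temperature: float = 1.0,
                      rngs_per_row: list[np.random.Generator] | None = None
                      ) -> np.ndarray:
    """Autoregressively sample one token trajectory per batch row: (B, K).

    If `rngs_per_row` is given, row i draws from its own generator (this
    is what makes batched and sequential cohort decoding identical).
    """
    was_training = net.training
    net.eval()
    try:
        dec = IncrementalDecoder(net, mc_density, access)
        B, K = dec.B, dec.K
        out = np.zeros((B, K), dtype=np.int64)
        for i in range(K):
            logits = dec.logits() / max(temperature, 1e-8)
            probs = _softmax_np(logits)
            cdf = np.cumsum(probs, axis=-1)
            if rngs_per_row is None:
                u = rng.random(B)
            else:
                u = np.array([g.random() for g in rngs_per_row])
            out[:, i] = np.minimum((cdf < u[:, None]).sum(axis=-1),
                                   probs.shape[-1] - 1)
            if i < K - 1:
                dec.step(out[:, i])
    finally:
        net.train(was_training)
    return out


# ---------------------------------------------------------------------------
# sample-size adapter


@dataclass(frozen=True)
class AdapterConfig:
    source_n: int  # SFS channels of the smaller cohort
    target_n: int  # SFS channels the pretrained backbone expects
    bottleneck: int = 32
    init_scale: float = 0.0


class SampleSizeAdapter(Module):
    """Near-identity input stage mapping cohort SFS channels to the
    pretrained dimensionality.

    Per genomic window (pointwise over Z, WS, K): layer norm, a gated
    bottleneck that rescales and recombines frequency channels, and a
    residual linear projection to the target width. The gate starts at
    `init_scale` (default 0), so at initialization the output equals the
    residual projection exactly.
    """

    def __init__(self, config: AdapterConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        self.ln = LayerNorm(config.source_n)
        self.down = Linear(config.source_n, config.bottleneck, rng)
        self.up = Linear(config.bottleneck, config.target_n, rng)
        self.residual = Linear(config.source_n, config.target_n, rng, bias=False)
        self.gate = Tensor(np.full(1, config.init_scale), requires_grad=True)

    def __call__(self, x) -> Tensor:
        """(..., N_src) -> (..., N_tgt); all leading axes pointwise."""
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
        res = self.residual(x)
        z = self.up(ag.gelu(self.down(self.ln(x))))
        return res + self.gate * z


# ---------------------------------------------------------------------------
# sklearn-style estimator surface


class TmrcaTranslator(BaseEstimator):
    """Next-coalescence sequence model with a scikit-learn interface.

    fit(X, y) trains the transformer on featurized simulations where
    ``X = (mc_density, accessibility)`` with shapes (B, 2, WS, K, N) and
    (B, WS, K), and ``y`` holds the per-window true TMRCA / intercept
    ratios (B, K). predict(X) returns posterior-mean ratio trajectories;
    sample(X) returns replicate trajectories. Absolute-time calibration
    is applied downstream (see `coaltrace.inference.decode_pair`).
    """

    def __init__(self, n_windows: int = 50, embed_dim: int = 64, n_layers: int = 2,
                 n_heads: int = 4, n_bins: int = N_BINS_DEFAULT, dropout: float = 0.1,
                 n_scales: int = 7, n_freq: int = 49, epochs: int = 5,
                 batch_size: int = 16, base_lr: float = 3e-4,
                 rollout: str = "self_sample", seed: int = 0):
        self.n_windows = n_windows
        self.embed_dim = embed_dim
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.n_bins = n_bins
        self.dropout = dropout
        self.n_scales = n_scales
        self.n_freq = n_freq
        self.epochs = epochs
        self.batch_size = batch_size
        self.base_lr = base_lr
        self.rollout = rollout
        self.seed = seed

    def _config(self) -> ModelConfig:
        return ModelConfig(n_windows=self.n_windows, n_bins=self.n_bins,
                           embed_dim=self.embed_dim, n_layers=self.n_layers,
                           n_heads=self.n_heads, dropout=self.dropout,
                           n_scales=self.n_scales, n_freq=self.n_freq)

    def fit(self, X, y):
        from .training import FeatureDataset, TrainConfig, train

        mc, access = X
        grid = TimeDiscretization.ratio_grid(self.n_bins)
        ds = FeatureDataset(mc_density=np.asarray(mc, dtype=np.float32),
                            access=np.asarray(access, dtype=np.float32),
                            ratios=np.asarray(y, dtype=np.float64))
        cfg = TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                          base_lr=self.base_lr, rollout=self.rollout, seed=self.seed)
        net = CoalescenceTransformer(self._config(), seed=self.seed)
        ckpt = train(net, ds, cfg, grid=grid)
        self.net_ = ckpt.net
        self.grid_ = ckpt.grid
        self.history_ = ckpt.history
        self.n_parameters_ = self.net_.n_parameters()
        return self

    def sample(self, X, n_reps: int = 15, temperature: float = 1.0,
               seed: int = 0) -> np.ndarray:
        """Replicate ratio trajectories: (B, n_reps, K)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "net_")
        mc, access = X
        mc = np.asarray(mc, dtype=np.float32)
        access = np.asarray(access, dtype=np.float32)
        B = mc.shape[0]
        out = np.zeros((B, n_reps, self.n_windows))
        rng = np.random.default_rng(seed)
        for r in range(n_reps):
            toks = sample_trajectory(self.net_, mc, access, rng, temperature)
            out[:, r, :] = self.grid_.decode(toks)
        return out

    def predict(self, X, n_reps: int = 15, seed: int = 0) -> np.ndarray:
        """Posterior-mean ratio trajectory per input: (B, K)."""
        return self.sample(X, n_reps=n_reps, seed=seed).mean(axis=1)
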