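"""Patch-based channel-independent transformer for CTG classification.

Architecture, per channel (FHR and TOCO are processed by separate,
independently parameterised paths):

1. **Instance normalisation** — each channel of each window is standardised
   to zero mean / unit variance using statistics over *observed* samples
   only; unobserved positions are zeroed so they can never influence the
   output.
2. **Patching** — the length-L series is cut into N = floor((L-P)/S) + 1
   patches of length P at stride S; a patch is *valid* when at least half
   its samples were observed.
3. **Patch embedding** — a linear projection W_P (P x d) plus a learned
   positional table W_pos (N x d) turn patches into tokens.
4. **Transformer encoder** — stacked layers of multi-head self-attention
   and a position-wise feed-forward network, with residual connections and
   post-layer normalisation.  Invalid patches are masked out of attention
   with additive -inf scores.
5. **Masked global average pooling** over valid tokens.
6. The two pooled channel vectors are concatenated and a dense layer with
   a sigmoid produces the adverse-outcome probability; training minimises
   binary cross-entropy.

The module exposes both the building blocks as plain-numpy functions (for
inspection and testing) and the trainable network :class:`PatchTransformerNet`
built on the package's autodiff engine.  The scikit-learn estimator wrapper
lives in :mod:`ctgformer.estimator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .autodiff import Tensor, concatenate
from .exceptions import (
    CTGError,
    DegenerateChannelError,
    DegenerateWindowError,
    ParameterError,
)

__all__ = [
    "ModelConfig",
    "NormStats",
    "PatchSet",
    "Prediction",
    "instance_normalize",
    "make_patches",
    "patch_count",
    "embed_patches",
    "attention",
    "pool_tokens",
    "aggregate_channels",
    "classify",
    "bce_loss",
    "PatchTransformerNet",
    "EncoderLayer",
]

EPS_NORM = 1e-8  # instance-norm denominator guard
EPS_PROB = 1e-7  # probability clamp for the cross-entropy
NEG_INF = -1e9  # additive attention mask for invalid keys
MIN_OBSERVED_PATCH_FRACTION = 0.5  # a patch is valid iff >= 50% observed

_ACTIVATIONS = ("relu", "gelu", "elu")


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the network.

    Defaults are the tuned operating configuration for one-hour, two-channel
    CTG windows: 6 encoder layers, 4 heads, model width 512, feed-forward
    width 128, non-overlapping patches of length 16 and ReLU activations.
    ``smooth_kernel`` optionally enables a learnable, identity-initialised
    per-channel moving-average convolution (applied between instance
    normalisation and patching); 0 disables it.
    """

    n_layers: int = 6
    n_heads: int = 4
    d_model: int = 512
    d_ff: int = 128
    dropout: float = 0.1
    fc_dropout: float = 0.4
    attn_dropout: float = 0.2
    patch_len: int = 16
    stride: int = 16
    activation: str = "relu"
    seq_len: int = 960
    n_channels: int = 2
    smooth_kernel: int = 0

    def __post_init__(self):
        if self.patch_len > self.seq_len:
            raise ParameterError("patch_len must not exceed seq_len")
        if self.stride < 1:
            raise ParameterError("stride must be >= 1")
        if self.d_model % self.n_heads != 0:
            raise ParameterError("d_model must be divisible by n_heads")
        for name in ("dropout", "fc_dropout", "attn_dropout"):
            if not (0.0 <= getattr(self, name) < 1.0):
                raise ParameterError(f"{name} must be in [0, 1)")
        if self.activation not in _ACTIVATIONS:
            raise ParameterError(f"activation must be one of {_ACTIVATIONS}")
        if self.n_layers < 1 or self.n_heads < 1 or self.d_model < 1 or self.d_ff < 1:
            raise ParameterError("layer/head/width counts must be positive")
        if self.smooth_kernel and self.smooth_kernel % 2 == 0:
            raise ParameterError("smooth_kernel must be odd (same-padding)")

    @property
    def n_patches(self) -> int:
        return patch_count(self.seq_len, self.patch_len, self.stride)

    @property
    def d_head(self) -> int:
        return self.d_model // self.n_heads


@dataclass
class NormStats:
    """Per-sequence, per-channel normalisation statistics (observed samples)."""

    mu: float
    sigma: float


@dataclass
class PatchSet:
    """Per-channel patch matrix with per-patch validity flags."""

    patches: np.ndarray  # (N, P)
    patch_valid: np.ndarray  # (N,) bool

    @property
    def n(self) -> int:
        return self.patches.shape[0]


@dataclass
class Prediction:
    """Classifier output: adverse-outcome probability and its logit."""

    probability: float
    logit: float

    @property
    def label(self) -> int:
        return int(self.probability >= 0.5)


# ----------------------------------------------------------- functional ops
def instance_normalize(values, valid_mask=None):
    """Standardise one channel over its observed samples.

    Returns ``(normalized, NormStats)``; masked positions are set to 0 so
    their (meaningless) input values cannot propagate.  Uses the population
    standard deviation with an epsilon guard, so a constant channel maps to
    all zeros.
    """
    values = np.asarray(values, dtype=np.float64)
    if valid_mask is None:
        valid_mask = np.ones(values.shape, dtype=bool)
    valid_mask = np.asarray(valid_mask, dtype=bool)
    obs = values[valid_mask]
    if obs.size == 0:
        raise DegenerateChannelError("no observed samples in channel")
    mu = float(obs.mean())
    sigma = float(obs.std())
    out = np.zeros_like(values)
    out[valid_mask] = (obs - mu) / (sigma + EPS_NORM)
    return out, NormStats(mu=mu, sigma=sigma)


def patch_count(seq_len: int, patch_len: int, stride: int) -> int:
    """Number of patches: N = floor((L - P) / S) + 1."""
    if patch_len > seq_len:
        raise ParameterError("patch_len must not exceed seq_len")
    if stride < 1:
        raise ParameterError("stride must be >= 1")
    return (seq_len - patch_len) // stride + 1


def patch_index(seq_len: int, patch_len: int, stride: int) -> np.ndarray:
    """(N, P) integer index matrix; patch j covers [j*S, j*S + P)."""
    n = patch_count(seq_len, patch_len, stride)
    starts = np.arange(n) * stride
    return starts[:, None] + np.arange(patch_len)[None, :]


def make_patches(series, valid_mask, patch_len: int, stride: int) -> PatchSet:
    """Cut one channel into patches with per-patch validity.

    A patch is valid iff at least half of its samples were observed.
    """
    series = np.asarray(series, dtype=np.float64)
    valid_mask = np.asarray(valid_mask, dtype=bool)
    idx = patch_index(series.shape[-1], patch_len, stride)
    patches = series[idx]
    frac = valid_mask[idx].mean(axis=1)
    return PatchSet(patches=patches, patch_valid=frac >= MIN_OBSERVED_PATCH_FRACTION)


def embed_patches(patchset: PatchSet, projection: np.ndarray, positional: np.ndarray):
    """Project patches into the latent space and add positional encodings."""
    projection = np.asarray(projection, dtype=np.float64)
    positional = np.asarray(positional, dtype=np.float64)
    if projection.shape[0] != patchset.patches.shape[1]:
        raise ParameterError("projection must be (P, d)")
    if positional.shape[0] != patchset.n:
        raise ParameterError("positional table must be (N, d)")
    return patchset.patches @ projection + positional


def attention(Q, K, V, token_valid=None):
    """Scaled dot-product attention with validity masking (reference form).

    Invalid tokens get -inf scores as keys (zero attention weight) and a
    zero context row as queries.  Raises if a valid query would attend over
    no valid key.
    """
    Q, K, V = (np.asarray(a, dtype=np.float64) for a in (Q, K, V))
    d_k = K.shape[-1]
    if token_valid is None:
        token_valid = np.ones(K.shape[0], dtype=bool)
    token_valid = np.asarray(token_valid, dtype=bool)
    if not token_valid.any() and Q.shape[0] > 0:
        raise CTGError("no valid keys for attention")
    scores = Q @ K.T / np.sqrt(d_k)
    scores = np.where(token_valid[None, :], scores, -np.inf)
    shifted = scores - scores.max(axis=-1, keepdims=True)
    w = np.exp(shifted)
    w /= w.sum(axis=-1, keepdims=True)
    context = w @ V
    context[~token_valid[: Q.shape[0]]] = 0.0
    return context


def pool_tokens(tokens, token_valid=None):
    """Masked global average pooling: the mean over valid tokens only."""
    tokens = np.asarray(tokens, dtype=np.float64)
    if token_valid is None:
        token_valid = np.ones(tokens.shape[0], dtype=bool)
    token_valid = np.asarray(token_valid, dtype=bool)
    if not token_valid.any():
        raise DegenerateWindowError("no valid token to pool")
    return tokens[token_valid].mean(axis=0)


def aggregate_channels(g_fhr, g_toco):
    """Fuse pooled channel representations by concatenation (FHR first)."""
    g_fhr = np.asarray(g_fhr, dtype=np.float64)
    g_toco = np.asarray(g_toco, dtype=np.float64)
    if g_fhr.shape != g_toco.shape:
        raise ParameterError("channel vectors must have equal shape")
    return np.concatenate([g_fhr, g_toco], axis=-1)


def classify(g, W_c, b_c) -> Prediction:
    """Dense layer plus sigmoid on the aggregated representation."""
    logit = float(np.asarray(g, dtype=np.float64) @ np.asarray(W_c).reshape(-1) + float(b_c))
    return Prediction(probability=float(expit(logit)), logit=logit)


def bce_loss(y, y_hat) -> float:
    """Binary cross-entropy, mean over the batch, probabilities clamped."""
    y = np.asarray(y, dtype=np.float64)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ParameterError("labels must be 0 or 1")
    p = np.clip(np.asarray(y_hat, dtype=np.float64), EPS_PROB, 1.0 - EPS_PROB)
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log1p(-p))))


# -------------------------------------------------------------- the network
def _dropout(x: Tensor, p: float, training: bool, rng) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * keep


def _layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc * (var + eps).pow(-0.5) * gamma + beta


def _activate(x: Tensor, kind: str) -> Tensor:
    if kind == "relu":
        return x.relu()
    if kind == "gelu":
        return x.gelu()
    return x.elu()


class EncoderLayer:
    """One transformer encoder block: MHSA and FFN, each with a residual
    connection followed by layer normalisation."""

    def __init__(self, config: ModelConfig, rng):
        d, f = config.d_model, config.d_ff
        self.config = config

        def lin(fan_in, fan_out):
            std = np.sqrt(2.0 / (fan_in + fan_out))
            return Tensor(rng.normal(0.0, std, size=(fan_in, fan_out)), requires_grad=True)

        def bias(fan_out):
            return Tensor(np.zeros(fan_out), requires_grad=True)

        self.Wq, self.bq = lin(d, d), bias(d)
        self.Wk, self.bk = lin(d, d), bias(d)
        self.Wv, self.bv = lin(d, d), bias(d)
        self.Wo, self.bo = lin(d, d), bias(d)
        self.ln1_g, self.ln1_b = Tensor(np.ones(d), requires_grad=True), bias(d)
        self.W1, self.b1 = lin(d, f), bias(f)
        self.W2, self.b2 = lin(f, d), bias(d)
        self.ln2_g, self.ln2_b = Tensor(np.ones(d), requires_grad=True), bias(d)

    def parameters(self):
        return [self.Wq, self.bq, self.Wk, self.bk, self.Wv, self.bv,
                self.Wo, self.bo, self.ln1_g, self.ln1_b,
                self.W1, self.b1, self.W2, self.b2, self.ln2_g, self.ln2_b]

    def _mhsa(self, x: Tensor, key_bias: np.ndarray, training: bool, rng) -> Tensor:
        cfg = self.config
        B, N = x.shape[0], x.shape[1]
        h, dk = cfg.n_heads, cfg.d_head

        def heads(t: Tensor) -> Tensor:
            return t.reshape(B, N, h, dk).transpose((0, 2, 1, 3))

        q = heads(x @ self.Wq + self.bq)
        k = heads(x @ self.Wk + self.bk)
        v = heads(x @ self.Wv + self.bv)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dk)) + key_bias
        w = scores.softmax(axis=-1)
        w = _dropout(w, cfg.attn_dropout, training, rng)
        ctx = (w @ v).transpose((0, 2, 1, 3)).reshape(B, N, cfg.d_model)
        return ctx @ self.Wo + self.bo

    def __call__(self, x: Tensor, key_bias: np.ndarray, training: bool = False,
                 rng=None) -> Tensor:
        cfg = self.config
        x = _layer_norm(x + self._mhsa(x, key_bias, training, rng),
                        self.ln1_g, self.ln1_b)
        hidden = _activate(x @ self.W1 + self.b1, cfg.activation)
        hidden = _dropout(hidden, cfg.dropout, training, rng)
        ffn = hidden @ self.W2 + self.b2
        return _layer_norm(x + ffn, self.ln2_g, self.ln2_b)


class _ChannelPath:
    """Patch embedding plus encoder stack for one signal channel."""

    def __init__(self, config: ModelConfig, rng):
        P, d, N = config.patch_len, config.d_model, config.n_patches
        std = np.sqrt(2.0 / (P + d))
        self.W_P = Tensor(rng.normal(0.0, std, size=(P, d)), requires_grad=True)
        self.W_pos = Tensor(rng.normal(0.0, 0.02, size=(N, d)), requires_grad=True)
        if config.smooth_kernel:
            kern = np.zeros(config.smooth_kernel)
            kern[config.smooth_kernel // 2] = 1.0  # identity init
            self.conv = Tensor(kern, requires_grad=True)
        else:
            self.conv = None
        self.layers = [EncoderLayer(config, rng) for _ in range(config.n_layers)]

    def parameters(self):
        out = [self.W_P, self.W_pos]
        if self.conv is not None:
            out.append(self.conv)
        for layer in self.layers:
            out.extend(layer.parameters())
        return out


class PatchTransformerNet:
    """The full two-channel network; parameters live in autodiff tensors."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        self.channels = [_ChannelPath(config, rng) for _ in range(config.n_channels)]
        d_agg = config.n_channels * config.d_model
        std = np.sqrt(2.0 / (d_agg + 1))
        self.W_c = Tensor(rng.normal(0.0, std, size=(d_agg, 1)), requires_grad=True)
        self.b_c = Tensor(np.zeros(1), requires_grad=True)
        self._idx = patch_index(config.seq_len, config.patch_len, config.stride)

    # ------------------------------------------------------------- plumbing
    def parameters(self):
        out = []
        for ch in self.channels:
            out.extend(ch.parameters())
        out.extend([self.W_c, self.b_c])
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ParameterError("state dict does not match the architecture")
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ParameterError(f"shape mismatch for parameter p{i}")
            p.data = arr.copy()

    # -------------------------------------------------------------- forward
    def _prepare(self, values: np.ndarray, mask: np.ndarray):
        """Instance-normalise, zero-fill and patch a (B, C, L) batch."""
        cfg = self.config
        values = np.asarray(values, dtype=np.float64)
        mask = np.asarray(mask, dtype=bool)
        if values.ndim != 3 or values.shape[1] != cfg.n_channels \
                or values.shape[2] != cfg.seq_len:
            raise ParameterError(
                f"expected (batch, {cfg.n_channels}, {cfg.seq_len}) input"
            )
        obs_count = mask.sum(axis=2)
        if np.any(obs_count == 0):
            raise DegenerateChannelError("a window channel has no observed samples")
        msum = np.where(mask, values, 0.0).sum(axis=2)
        mu = msum / obs_count
        centred = np.where(mask, values - mu[:, :, None], 0.0)
        sigma = np.sqrt((centred**2).sum(axis=2) / obs_count)
        x = np.where(mask, centred / (sigma + EPS_NORM)[:, :, None], 0.0)
        patch_valid = (
            mask[..., self._idx].mean(axis=-1) >= MIN_OBSERVED_PATCH_FRACTION
        )  # (B, C, N)
        if np.any(~patch_valid.any(axis=-1)):
            raise DegenerateWindowError("a window channel has no valid patch")
        return x, patch_valid

    def forward(self, values, mask, training: bool = False, rng=None) -> Tensor:
        """Return the batch logits as a graph node of shape (B,)."""
        cfg = self.config
        if training and rng is None:
            rng = np.random.default_rng(0)
        x, patch_valid = self._prepare(values, mask)
        B = x.shape[0]
        pooled = []
        for c, path in enumerate(self.channels):
            if path.conv is not None:
                xt = self._smooth_channel(x[:, c], path.conv)
                patches = xt.gather_last(self._idx)  # (B, N, P)
            else:
                patches = Tensor(x[:, c][..., self._idx])
            tok = patches @ path.W_P + path.W_pos
            tok = _dropout(tok, cfg.dropout, training, rng)
            pv = patch_valid[:, c]  # (B, N)
            key_bias = np.where(pv, 0.0, NEG_INF)[:, None, None, :]
            for layer in path.layers:
                tok = layer(tok, key_bias, training, rng)
            tv = pv.astype(np.float64)
            g = (tok * tv[:, :, None]).sum(axis=1) / tv.sum(axis=1)[:, None]
            pooled.append(g)
        agg = concatenate(pooled, axis=-1)
        agg = _dropout(agg, cfg.fc_dropout, training, rng)
        logits = (agg @ self.W_c + self.b_c).reshape(B)
        return logits

    def _smooth_channel(self, x_c: np.ndarray, kernel: Tensor) -> Tensor:
        """Learnable same-padded 1-D convolution on a constant input batch."""
        K = kernel.shape[0]
        half = K // 2
        padded = np.pad(x_c, ((0, 0), (half, half)))
        L = x_c.shape[1]
        idx = np.arange(L)[:, None] + np.arange(K)[None, :]
        unfolded = Tensor(padded[:, idx])  # (B, L, K) constant
        return (unfolded @ kernel.reshape(K, 1)).reshape(x_c.shape[0], L)

    def predict_proba(self, values, mask) -> np.ndarray:
        """Deterministic evaluation-mode probabilities, clamped away from 0/1."""
        logits = self.forward(values, mask, training=False).data
        return np.clip(expit(logits), EPS_PROB, 1.0 - EPS_PROB)
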