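"""Three-stage motor-imagery decoder: CNN -> BiLSTM -> patch Transformer.

The network maps an epoched EEG trial ``X ∈ R^{C×T}`` (default 22 channels,
1000 samples = 4 s at 250 Hz) to a posterior over motor-imagery classes:

1. **Spatial–spectral encoder** — four 1-D convolution blocks (conv, batch
   norm, ReLU, max-pool).  Convolution is stride-1 and length-preserving;
   all temporal reduction comes from the pool of size 2, so
   ``T' = T // 2**4`` (62 for T=1000).
2. **Temporal encoder** — a two-layer bidirectional LSTM over the T'
   feature frames; forward and backward hidden states are concatenated,
   giving frames of width ``2·d_h``.
3. **Patch Transformer** — the BiLSTM output is cut into overlapping
   patches of ``p`` frames with stride ``s``, each flattened (time-major)
   and affinely projected to ``d`` dimensions, layer-normalized, and given
   sinusoidal positional encodings.  ``L`` pre-norm Transformer encoder
   layers (multi-head self-attention + GELU feed-forward of width ``2d``)
   followed by a final normalization and mean pooling yield a fixed-length
   embedding, classified by a two-layer head with softmax.

Parameter accounting (:func:`count_parameters`) follows the exact layer
conventions above: conv bias plus batch-norm scale/shift per block, two
bias vectors per LSTM gate block (input- and hidden-side), patch projection
with one layer norm, per-layer attention/FF biases with two layer norms per
Transformer layer plus one final, and an affine d→d→n_classes head.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from ._seeds import rng_for

__all__ = [
    "ModelConfig",
    "ParameterBreakdown",
    "MACBreakdown",
    "CBTNet",
    "derive_temporal_length",
    "n_patches",
    "sinusoidal_encoding",
    "count_parameters",
    "estimate_macs",
    "cross_entropy",
    "save_checkpoint",
    "load_checkpoint",
]


class InvalidConfigError(ValueError):
    """Raised when a model configuration is internally inconsistent."""


class DimensionError(ValueError):
    """Raised when an input array does not match the configuration."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """Every architectural hyperparameter of the decoder."""

    n_channels: int = 22
    n_samples: int = 1000
    conv_out_channels: tuple = (32, 64, 128, 128)
    conv_kernel: int = 5
    pool_size: int = 2
    conv_dropout: float = 0.25
    lstm_hidden: int = 128
    lstm_layers: int = 2
    lstm_dropout: float = 0.3
    patch_size: int = 24
    stride: int = 12
    embed_dim: int = 128
    tf_layers: int = 2
    n_heads: int = 4
    ff_dim: int | None = None  # defaults to 2 * embed_dim
    tf_dropout: float = 0.1
    n_classes: int = 4
    head_activation: str = "gelu"  # parameter-count neutral; "gelu" or "identity"

    def __post_init__(self):
        if self.ff_dim is None:
            object.__setattr__(self, "ff_dim", 2 * self.embed_dim)
        object.__setattr__(self, "conv_out_channels", tuple(self.conv_out_channels))
        counts = (
            self.n_channels, self.n_samples, self.conv_kernel, self.pool_size,
            self.lstm_hidden, self.lstm_layers, self.patch_size, self.stride,
            self.embed_dim, self.tf_layers, self.n_heads, self.ff_dim,
            self.n_classes, *self.conv_out_channels,
        )
        if any(c < 1 for c in counts):
            raise InvalidConfigError("all counts must be >= 1")
        if self.conv_kernel % 2 != 1:
            raise InvalidConfigError("conv_kernel must be odd (length-preserving padding)")
        for p in (self.conv_dropout, self.lstm_dropout, self.tf_dropout):
            if not 0.0 <= p < 1.0:
                raise InvalidConfigError("dropout fractions must be in [0, 1)")
        if self.embed_dim % self.n_heads != 0:
            raise InvalidConfigError(
                f"embed_dim {self.embed_dim} not divisible by n_heads {self.n_heads}"
            )
        if not 1 <= self.stride <= self.patch_size:
            raise InvalidConfigError("need 1 <= stride <= patch_size")
        if self.head_activation not in ("gelu", "identity"):
            raise InvalidConfigError("head_activation must be 'gelu' or 'identity'")
        tprime = derive_temporal_length(self.n_samples, self)
        if self.patch_size > tprime:
            raise InvalidConfigError(
                f"patch_size {self.patch_size} exceeds derived temporal length {tprime}"
            )

    @property
    def temporal_length(self) -> int:
        return derive_temporal_length(self.n_samples, self)

    @property
    def lstm_input_dims(self) -> tuple:
        dims = [self.conv_out_channels[-1]]
        dims += [2 * self.lstm_hidden] * (self.lstm_layers - 1)
        return tuple(dims)


def desk_scale_config(**overrides) -> ModelConfig:
    """A reduced decoder for CPU-scale experiments on synthetic data.

    Same three-stage architecture, scaled down: narrow conv blocks with
    pool size 3 (T' = 12 for 4-s trials), a single 16-unit BiLSTM layer,
    4-frame patches with 50% overlap, a one-layer two-head Transformer
    with 32-dimensional embeddings, and light dropout.  ~27k parameters.
    """
    base = dict(
        conv_out_channels=(8, 16, 16, 16),
        pool_size=3,
        lstm_hidden=16,
        lstm_layers=1,
        patch_size=4,
        stride=2,
        embed_dim=32,
        tf_layers=1,
        n_heads=2,
        conv_dropout=0.1,
        lstm_dropout=0.1,
        tf_dropout=0.1,
    )
    base.update(overrides)
    return ModelConfig(**base)


def derive_temporal_length(T: int, config: ModelConfig | None = None) -> int:
    """Feature length after the conv stack: floor-divide by pool per block."""
    cfg = config or ModelConfig()
    if T < cfg.conv_kernel:
        raise InvalidConfigError(f"T={T} shorter than kernel {cfg.conv_kernel}")
    t = T
    for _ in cfg.conv_out_channels:
        t = t // cfg.pool_size
    if t < 1:
        raise InvalidConfigError(f"temporal length collapses to {t} for T={T}")
    return t


def n_patches(t_prime: int, patch_size: int, stride: int) -> int:
    """Number of sliding patches: ``floor((T' - p) / s) + 1``."""
    if patch_size > t_prime:
        raise InvalidConfigError(
            f"patch_size {patch_size} exceeds sequence length {t_prime}"
        )
    return (t_prime - patch_size) // stride + 1


def sinusoidal_encoding(n_positions: int, dim: int) -> np.ndarray:
    """Non-learned sinusoidal positional encodings, shape (N, d)."""
    pos = np.arange(n_positions)[:, None].astype(float)
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    enc = np.empty((n_positions, dim))
    enc[:, 0::2] = np.sin(angle[:, 0::2])
    enc[:, 1::2] = np.cos(angle[:, 1::2])
    return enc


# ---------------------------------------------------------------------------
# parameter bookkeeping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterBreakdown:
    spatial_spectral: int
    temporal_encoder: int
    patch_embedding: int
    transformer_encoder: int
    classification_head: int

    @property
    def total(self) -> int:
        return (
            self.spatial_spectral
            + self.temporal_encoder
            + self.patch_embedding
            + self.transformer_encoder
            + self.classification_head
        )

    def as_dict(self) -> dict:
        d = asdict(self)
        d["total"] = self.total
        return d


def count_parameters(config: ModelConfig | None = None) -> ParameterBreakdown:
    """Closed-form trainable-parameter counts per component."""
    cfg = config or ModelConfig()
    k = cfg.conv_kernel
    conv = 0
    cin = cfg.n_channels
    for cout in cfg.conv_out_channels:
        conv += cin * cout * k + cout  # kernel + bias
        conv += 2 * cout  # batch-norm scale + shift
        cin = cout

    dh = cfg.lstm_hidden
    lstm = 0
    for din in cfg.lstm_input_dims:
        # per direction: 4 gates x (input weights + recurrent weights + 2 biases)
        lstm += 2 * (4 * (din * dh + dh * dh + 2 * dh))

    d = cfg.embed_dim
    patch = cfg.patch_size * 2 * dh * d + d  # projection + bias
    patch += 2 * d  # one layer norm

    ff = cfg.ff_dim
    per_layer = 4 * (d * d + d)  # q, k, v, out projections with bias
    per_layer += d * ff + ff + ff * d + d  # feed-forward pair
    per_layer += 2 * (2 * d)  # two layer norms
    tf = cfg.tf_layers * per_layer + 2 * d  # + final norm

    head = d * d + d + d * cfg.n_classes + cfg.n_classes

    return ParameterBreakdown(conv, lstm, patch, tf, head)


@dataclass(frozen=True)
class MACBreakdown:
    """Per-component multiply-accumulate counts for one trial."""

    spatial_spectral: int
    temporal_encoder: int
    patch_embedding: int
    transformer_encoder: int
    classification_head: int

    @property
    def total(self) -> int:
        return (
            self.spatial_spectral
            + self.temporal_encoder
            + self.patch_embedding
            + self.transformer_encoder
            + self.classification_head
        )

    def as_dict(self) -> dict:
        d = asdict(self)
        d["total"] = self.total
        return d


def estimate_macs(config: ModelConfig | None = None) -> MACBreakdown:
    """Deterministic MAC estimate counting multiplies only.

    Convolution, recurrent, projection, attention, feed-forward and head
    multiplies are counted; normalizations, activations and softmax are
    not.  Used as the latency surrogate in architecture search.
    """
    cfg = config or ModelConfig()
    k = cfg.conv_kernel
    length = cfg.n_samples
    conv = 0
    cin = cfg.n_channels
    for cout in cfg.conv_out_channels:
        conv += length * cin * cout * k  # stride-1, length-preserving
        length //= cfg.pool_size
        cin = cout

    tprime = cfg.temporal_length
    dh = cfg.lstm_hidden
    lstm = 0
    for din in cfg.lstm_input_dims:
        lstm += 2 * tprime * 4 * (din * dh + dh * dh)

    d = cfg.embed_dim
    N = n_patches(tprime, cfg.patch_size, cfg.stride)
    patch = N * (cfg.patch_size * 2 * dh) * d

    ff = cfg.ff_dim
    per_layer = 4 * N * d * d  # q, k, v, out projections
    per_layer += 2 * N * N * d  # scores QK^T and weighted values AV
    per_layer += N * (d * ff + ff * d)
    tf = cfg.tf_layers * per_layer

    head = d * d + d * cfg.n_classes
    return MACBreakdown(conv, lstm, patch, tf, head)


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

def _glorot(rng, shape):
    fan_in, fan_out = shape[0], shape[-1]
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def init_parameters(config: ModelConfig, seed: int) -> dict:
    """Seed-deterministic initial parameters keyed by component path."""
    cfg = config
    params: dict[str, Tensor] = {}
    k = cfg.conv_kernel

    cin = cfg.n_channels
    for i, cout in enumerate(cfg.conv_out_channels):
        rng = rng_for(seed, "conv", i)
        params[f"conv.{i}.W"] = ad.parameter(_glorot(rng, (cout, cin * k)))
        params[f"conv.{i}.b"] = ad.parameter(np.zeros(cout))
        params[f"conv.{i}.gamma"] = ad.parameter(np.ones(cout))
        params[f"conv.{i}.beta"] = ad.parameter(np.zeros(cout))
        cin = cout

    dh = cfg.lstm_hidden
    for layer, din in enumerate(cfg.lstm_input_dims):
        for direction in ("fw", "bw"):
            rng = rng_for(seed, "lstm", layer, direction)
            pre = f"lstm.l{layer}.{direction}"
            params[f"{pre}.Wx"] = ad.parameter(_glorot(rng, (din, 4 * dh)))
            params[f"{pre}.Wh"] = ad.parameter(_glorot(rng, (dh, 4 * dh)))
            bx = np.zeros(4 * dh)
            bx[dh : 2 * dh] = 1.0  # forget-gate bias opens the memory path
            params[f"{pre}.bx"] = ad.parameter(bx)
            params[f"{pre}.bh"] = ad.parameter(np.zeros(4 * dh))

    d = cfg.embed_dim
    rng = rng_for(seed, "patch")
    params["patch.We"] = ad.parameter(_glorot(rng, (cfg.patch_size * 2 * dh, d)))
    params["patch.be"] = ad.parameter(np.zeros(d))
    params["patch.gamma"] = ad.parameter(np.ones(d))
    params["patch.beta"] = ad.parameter(np.zeros(d))

    ff = cfg.ff_dim
    for layer in range(cfg.tf_layers):
        rng = rng_for(seed, "tf", layer)
        pre = f"tf.l{layer}"
        for name in ("Wq", "Wk", "Wv", "Wo"):
            params[f"{pre}.{name}"] = ad.parameter(_glorot(rng, (d, d)))
        for name in ("bq", "bk", "bv", "bo"):
            params[f"{pre}.{name}"] = ad.parameter(np.zeros(d))
        params[f"{pre}.ln1_g"] = ad.parameter(np.ones(d))
        params[f"{pre}.ln1_b"] = ad.parameter(np.zeros(d))
        params[f"{pre}.ln2_g"] = ad.parameter(np.ones(d))
        params[f"{pre}.ln2_b"] = ad.parameter(np.zeros(d))
        params[f"{pre}.W1"] = ad.parameter(_glorot(rng, (d, ff)))
        params[f"{pre}.b1"] = ad.parameter(np.zeros(ff))
        params[f"{pre}.W2"] = ad.parameter(_glorot(rng, (ff, d)))
        params[f"{pre}.b2"] = ad.parameter(np.zeros(d))
    params["tf.final_g"] = ad.parameter(np.ones(d))
    params["tf.final_b"] = ad.parameter(np.zeros(d))

    rng = rng_for(seed, "head")
    params["head.W1"] = ad.parameter(_glorot(rng, (d, d)))
    params["head.b1"] = ad.parameter(np.zeros(d))
    params["head.W2"] = ad.parameter(_glorot(rng, (d, cfg.n_classes)))
    params["head.b2"] = ad.parameter(np.zeros(cfg.n_classes))
    return params


_COMPONENT_PREFIXES = {
    "spatial_spectral": "conv.",
    "temporal_encoder": "lstm.",
    "patch_embedding": "patch.",
    "transformer_encoder": "tf.",
    "classification_head": "head.",
}


class CBTNet:
    """Conv–BiLSTM–Transformer decoder with explicit parameter dict.

    Parameters are an ordinary ``{name: Tensor}`` mapping so that
    meta-learning can produce adapted copies without mutating the model.
    Batch-norm running statistics live outside the parameter dict (they
    are not trained by gradient descent).
    """

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        self.config = config or ModelConfig()
        self.seed = seed
        self.params = init_parameters(self.config, seed)
        self.bn_state = {
            f"conv.{i}": {
                "mean": np.zeros(c),
                "var": np.ones(c),
                "momentum": 0.1,
                "initialized": False,
            }
            for i, c in enumerate(self.config.conv_out_channels)
        }

    # -- stages -----------------------------------------------------------

    def encode_spatial_spectral(
        self, X, params=None, *, train=False, rng=None, bn_mode=None
    ) -> Tensor:
        """Four conv blocks: (B, C, T) -> (B, D, T')."""
        cfg = self.config
        params = params or self.params
        x = ad.tensor(X)
        squeeze = x.ndim == 2
        if squeeze:
            x = ad.reshape(x, (1,) + x.shape)
        if x.shape[-2] != cfg.n_channels or x.shape[-1] != cfg.n_samples:
            raise DimensionError(
                f"expected (.., {cfg.n_channels}, {cfg.n_samples}), got {x.shape}"
            )
        mode = bn_mode or ("batch" if train else "running")
        halfk = cfg.conv_kernel // 2
        for i in range(len(cfg.conv_out_channels)):
            u = ad.unfold1d(ad.pad_last(x, halfk, halfk), cfg.conv_kernel)
            W = params[f"conv.{i}.W"]
            b = ad.reshape(params[f"conv.{i}.b"], (-1, 1))
            y = ad.add(ad.matmul(W, u), b)
            y = self._batch_norm(y, params, f"conv.{i}", mode, update=train)
            y = ad.relu(y)
            y = ad.maxpool_last(y, cfg.pool_size)
            if train and cfg.conv_dropout > 0 and rng is not None:
                y = ad.dropout(y, cfg.conv_dropout, rng)
            x = y
        return ad.reshape(x, x.shape[1:]) if squeeze else x

    def _batch_norm(self, y, params, key, mode, update, eps=1e-5):
        gamma = ad.reshape(params[f"{key}.gamma"], (-1, 1))
        beta = ad.reshape(params[f"{key}.beta"], (-1, 1))
        state = self.bn_state[key]
        if mode == "running" and state["initialized"]:
            mean = state["mean"][None, :, None]
            var = state["var"][None, :, None]
            inv = 1.0 / np.sqrt(var + eps)
            return ad.add(ad.mul(ad.add(y, -mean), ad.mul(gamma, inv)), beta)
        mean = ad.tmean(y, axis=(0, 2), keepdims=True)
        centered = ad.add(y, ad.mul(mean, -1.0))
        var = ad.tmean(ad.mul(centered, centered), axis=(0, 2), keepdims=True)
        if update:
            m = state["momentum"]
            bm, bv = mean.data.reshape(-1), var.data.reshape(-1)
            if not state["initialized"]:
                state["mean"], state["var"] = bm.copy(), bv.copy()
                state["initialized"] = True
            else:
                state["mean"] = (1 - m) * state["mean"] + m * bm
                state["var"] = (1 - m) * state["var"] + m * bv
        inv = ad.power(ad.add(var, eps), -0.5)
        return ad.add(ad.mul(ad.mul(centered, inv), gamma), beta)

    def encode_temporal(self, F, params=None, *, train=False, rng=None) -> Tensor:
        """BiLSTM over feature frames: (B, D, T') -> (B, T', 2*dh)."""
        cfg = self.config
        params = params or self.params
        x = ad.tensor(F)
        squeeze = x.ndim == 2
        if squeeze:
            x = ad.reshape(x, (1,) + x.shape)
        x = ad.swapaxes(x, 1, 2)  # (B, T', D)
        for layer in range(cfg.lstm_layers):
            fw = self._lstm_direction(x, params, layer, "fw", reverse=False)
            bw = self._lstm_direction(x, params, layer, "bw", reverse=True)
            x = ad.concatenate([fw, bw], axis=2)
            if (
                train
                and cfg.lstm_dropout > 0
                and rng is not None
                and layer < cfg.lstm_layers - 1
            ):
                x = ad.dropout(x, cfg.lstm_dropout, rng)
        return ad.reshape(x, x.shape[1:]) if squeeze else x

    def _lstm_direction(self, x, params, layer, direction, reverse):
        cfg = self.config
        dh = cfg.lstm_hidden
        pre = f"lstm.l{layer}.{direction}"
        Wx, Wh = params[f"{pre}.Wx"], params[f"{pre}.Wh"]
        bias = ad.add(params[f"{pre}.bx"], params[f"{pre}.bh"])
        B, T = x.shape[0], x.shape[1]
        h = ad.tensor(np.zeros((B, dh)))
        c = ad.tensor(np.zeros((B, dh)))
        # project all inputs at once; the recurrence loops over time
        xproj = ad.add(ad.matmul(x, Wx), bias)  # (B, T, 4dh)
        steps = range(T - 1, -1, -1) if reverse else range(T)
        outs = [None] * T
        for t in steps:
            z = ad.add(xproj[:, t], ad.matmul(h, Wh))
            i = ad.sigmoid(z[:, :dh])
            f = ad.sigmoid(z[:, dh : 2 * dh])
            g = ad.tanh(z[:, 2 * dh : 3 * dh])
            o = ad.sigmoid(z[:, 3 * dh :])
            c = ad.add(ad.mul(f, c), ad.mul(i, g))
            h = ad.mul(o, ad.tanh(c))
            outs[t] = h
        return ad.stack(outs, axis=1)  # (B, T, dh)

    def tokenize_patches(self, H, params=None) -> Tensor:
        """Overlapping patches -> projected, normalized, positioned tokens."""
        cfg = self.config
        params = params or self.params
        x = ad.tensor(H)
        squeeze = x.ndim == 2
        if squeeze:
            x = ad.reshape(x, (1,) + x.shape)
        tprime = x.shape[1]
        N = n_patches(tprime, cfg.patch_size, cfg.stride)
        patches = []
        for j in range(N):
            start = j * cfg.stride
            patch = x[:, start : start + cfg.patch_size]  # (B, p, 2dh)
            patches.append(
                ad.reshape(patch, (x.shape[0], cfg.patch_size * x.shape[2]))
            )
        Z = ad.stack(patches, axis=1)  # (B, N, p*2dh)
        Z = ad.add(ad.matmul(Z, params["patch.We"]), params["patch.be"])
        Z = ad.layer_norm(Z, params["patch.gamma"], params["patch.beta"])
        Z = ad.add(Z, sinusoidal_encoding(N, cfg.embed_dim))
        return ad.reshape(Z, Z.shape[1:]) if squeeze else Z

    def apply_transformer(self, Z, params=None, *, train=False, rng=None) -> Tensor:
        """Pre-norm encoder layers + final norm + mean pooling: -> (B, d)."""
        cfg = self.config
        params = params or self.params
        x = ad.tensor(Z)
        squeeze = x.ndim == 2
        if squeeze:
            x = ad.reshape(x, (1,) + x.shape)
        for layer in range(cfg.tf_layers):
            pre = f"tf.l{layer}"
            a = ad.layer_norm(x, params[f"{pre}.ln1_g"], params[f"{pre}.ln1_b"])
            attn = self._attention(a, params, pre, train=train, rng=rng)
            if train and cfg.tf_dropout > 0 and rng is not None:
                attn = ad.dropout(attn, cfg.tf_dropout, rng)
            x = ad.add(x, attn)
            b = ad.layer_norm(x, params[f"{pre}.ln2_g"], params[f"{pre}.ln2_b"])
            h = ad.gelu(ad.add(ad.matmul(b, params[f"{pre}.W1"]), params[f"{pre}.b1"]))
            h = ad.add(ad.matmul(h, params[f"{pre}.W2"]), params[f"{pre}.b2"])
            if train and cfg.tf_dropout > 0 and rng is not None:
                h = ad.dropout(h, cfg.tf_dropout, rng)
            x = ad.add(x, h)
        x = ad.layer_norm(x, params["tf.final_g"], params["tf.final_b"])
        pooled = ad.tmean(x, axis=1)  # (B, d)
        return ad.reshape(pooled, pooled.shape[1:]) if squeeze else pooled

    def _attention(self, a, params, pre, *, train, rng):
        cfg = self.config
        d, h = cfg.embed_dim, cfg.n_heads
        dk = d // h
        B, N = a.shape[0], a.shape[1]

        def heads(name):
            proj = ad.add(ad.matmul(a, params[f"{pre}.{name[0].upper()}{name[1:]}"]),
                          params[f"{pre}.b{name[1]}"])
            return ad.swapaxes(ad.reshape(proj, (B, N, h, dk)), 1, 2)  # (B, h, N, dk)

        q = heads("Wq")
        k = heads("Wk")
        v = heads("Wv")
        scores = ad.mul(ad.matmul(q, ad.swapaxes(k, -1, -2)), 1.0 / math.sqrt(dk))
        att = ad.softmax(scores, axis=-1)
        if train and cfg.tf_dropout > 0 and rng is not None:
            att = ad.dropout(att, cfg.tf_dropout, rng)
        out = ad.matmul(att, v)  # (B, h, N, dk)
        out = ad.reshape(ad.swapaxes(out, 1, 2), (B, N, d))
        return ad.add(ad.matmul(out, params[f"{pre}.Wo"]), params[f"{pre}.bo"])

    def attention_weights(self, Z, layer: int = 0) -> np.ndarray:
        """Attention probabilities of one layer (for inspection/tests)."""
        cfg = self.config
        params = self.params
        x = ad.tensor(Z)
        if x.ndim == 2:
            x = ad.reshape(x, (1,) + x.shape)
        for i in range(layer + 1):
            pre = f"tf.l{i}"
            a = ad.layer_norm(x, params[f"{pre}.ln1_g"], params[f"{pre}.ln1_b"])
            d, h = cfg.embed_dim, cfg.n_heads
            dk = d // h
            B, N = a.shape[0], a.shape[1]
            q = ad.swapaxes(ad.reshape(
                ad.add(ad.matmul(a, params[f"{pre}.Wq"]), params[f"{pre}.bq"]),
                (B, N, h, dk)), 1, 2)
            k = ad.swapaxes(ad.reshape(
                ad.add(ad.matmul(a, params[f"{pre}.Wk"]), params[f"{pre}.bk"]),
                (B, N, h, dk)), 1, 2)
            scores = ad.mul(ad.matmul(q, ad.swapaxes(k, -1, -2)), 1.0 / math.sqrt(dk))
            att = ad.softmax(scores, axis=-1)
            if i == layer:
                return att.data
            attn = self._attention(a, params, pre, train=False, rng=None)
            x = ad.add(x, attn)
            b = ad.layer_norm(x, params[f"{pre}.ln2_g"], params[f"{pre}.ln2_b"])
            hdd = ad.gelu(ad.add(ad.matmul(b, params[f"{pre}.W1"]), params[f"{pre}.b1"]))
            x = ad.add(x, ad.add(ad.matmul(hdd, params[f"{pre}.W2"]), params[f"{pre}.b2"]))
        raise AssertionError("unreachable")

    def logits(self, X, params=None, *, train=False, rng=None, bn_mode=None) -> Tensor:
        params = params or self.params
        F = self.encode_spatial_spectral(X, params, train=train, rng=rng, bn_mode=bn_mode)
        H = self.encode_temporal(F, params, train=train, rng=rng)
        Z = self.tokenize_patches(H, params)
        pooled = self.apply_transformer(Z, params, train=train, rng=rng)
        h = ad.add(ad.matmul(pooled, params["head.W1"]), params["head.b1"])
        if self.config.head_activation == "gelu":
            h = ad.gelu(h)
        return ad.add(ad.matmul(h, params["head.W2"]), params["head.b2"])

    def forward(self, X, params=None, *, train=False, rng=None, bn_mode=None) -> Tensor:
        """Class posterior(s): softmax over the head logits."""
        return ad.softmax(
            self.logits(X, params, train=train, rng=rng, bn_mode=bn_mode), axis=-1
        )

    def predict_proba(self, X, params=None, batch_size: int = 64) -> np.ndarray:
        """Eval-mode posteriors as a plain array, batched for memory."""
        X = np.asarray(X)
        if X.ndim == 2:
            X = X[None]
        chunks = []
        with ad.no_grad():
            for lo in range(0, X.shape[0], batch_size):
                chunks.append(self.forward(X[lo : lo + batch_size], params).data)
        return np.concatenate(chunks, axis=0)

    def predict(self, X, params=None, batch_size: int = 64) -> np.ndarray:
        return self.predict_proba(X, params, batch_size).argmax(axis=-1)

    # -- bookkeeping -------------------------------------------------------

    def parameter_breakdown_from_arrays(self) -> ParameterBreakdown:
        """Count the actual parameter arrays, grouped by component."""
        counts = dict.fromkeys(_COMPONENT_PREFIXES, 0)
        for name, t in self.params.items():
            for comp, prefix in _COMPONENT_PREFIXES.items():
                if name.startswith(prefix):
                    counts[comp] += t.size
        return ParameterBreakdown(**counts)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels under the logits."""
    ls = ad.log_softmax(logits, axis=-1)
    rows = np.arange(ls.shape[0])
    picked = ls[rows, np.asarray(labels)]
    return ad.mul(ad.tmean(picked), -1.0)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: CBTNet, path) -> None:
    """Single-file archive: parameters + batch-norm state + config JSON."""
    arrays = {f"p/{k}": v.data for k, v in model.params.items()}
    for key, st in model.bn_state.items():
        arrays[f"bn/{key}/mean"] = st["mean"]
        arrays[f"bn/{key}/var"] = st["var"]
        arrays[f"bn/{key}/init"] = np.array(int(st["initialized"]))
    cfg = asdict(model.config)
    arrays["config_json"] = np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8
    ).copy()
    np.savez(path, **arrays)


def load_checkpoint(path) -> CBTNet:
    with np.load(path) as data:
        cfg_json = bytes(data["config_json"]).decode()
        cfg_dict = json.loads(cfg_json)
        cfg_dict["conv_out_channels"] = tuple(cfg_dict["conv_out_channels"])
        model = CBTNet(ModelConfig(**cfg_dict), seed=0)
        for k in model.params:
            model.params[k] = ad.parameter(data[f"p/{k}"])
        for key, st in model.bn_state.items():
            st["mean"] = data[f"bn/{key}/mean"]
            st["var"] = data[f"bn/{key}/var"]
            st["initialized"] = bool(int(data[f"bn/{key}/init"]))
    return model
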