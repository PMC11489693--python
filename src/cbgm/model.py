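"""The CBGM classifier: CNN -> BiGRU -> multi-head self-attention -> softmax.

The network consumes a 300-sample heartbeat pulse and emits a probability
vector over the five beat classes.  Three conv/batch-norm/max-pool triplets
extract local morphology; a bidirectional GRU models the temporal context
of the pooled feature sequence; multi-head scaled dot-product self-attention
re-weights the sequence (per head: softmax(Q K^T / sqrt(d_k)) V with Q, K, V
linear projections of the input, heads concatenated and recombined by an
output projection); a dropout + dense softmax head classifies.  The default
architecture counts 13 hidden layers: 3 x (conv + batch-norm + pool) = 9,
BiGRU, attention, dropout, dense.

Everything runs on the package's own numpy autograd, so the same forward
graph serves training, inference and Grad-CAM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from ._autograd import Parameter, Tensor, batchnorm, concat, no_grad, stack
from .exceptions import ConfigError
from .signal_io import CLASSES, Segment

__all__ = [
    "ModelConfig",
    "AttentionParams",
    "ModelOutput",
    "CBGMModel",
    "attention_head",
    "multi_head",
    "count_parameters",
    "save_weights",
    "load_weights",
]


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``conv_blocks`` lists (n_filters, kernel_size, pool_size) for the three
    triplets.  ``d_model`` is the attention width and must equal the width
    of the sequence entering attention (2 * gru_hidden with the BiGRU, the
    last conv filter count without it) and be divisible by ``n_heads``.
    """

    input_length: int = 300
    conv_blocks: tuple = ((32, 5, 2), (64, 5, 2), (128, 3, 2))
    gru_hidden: int = 64
    bidirectional: bool = True
    n_heads: int = 8
    d_model: int = 128
    dropout_p: float = 0.3
    n_classes: int = 5
    use_bigru: bool = True
    use_attention: bool = True

    def __post_init__(self):
        self.conv_blocks = tuple(tuple(b) for b in self.conv_blocks)
        if len(self.conv_blocks) != 3:
            raise ConfigError("conv_blocks must list exactly 3 triplets")
        if self.n_classes != 5:
            raise ConfigError("the classifier is a 5-class model")
        if self.input_length != Segment.SEGMENT_LENGTH:
            raise ConfigError(f"input_length must be {Segment.SEGMENT_LENGTH}")
        if self.n_heads < 1:
            raise ConfigError("n_heads must be >= 1")
        if self.d_model % self.n_heads != 0:
            raise ConfigError("d_model must be divisible by n_heads")
        if not 0 <= self.dropout_p < 1:
            raise ConfigError("dropout_p must be in [0, 1)")
        seq_width = (
            (2 if self.bidirectional else 1) * self.gru_hidden
            if self.use_bigru
            else self.conv_blocks[-1][0]
        )
        if self.use_attention and self.d_model != seq_width:
            raise ConfigError(
                f"d_model ({self.d_model}) must equal the attention input "
                f"width ({seq_width})"
            )

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads

    @property
    def d_v(self) -> int:
        return self.d_model // self.n_heads

    def feature_length(self) -> int:
        """Time steps surviving the three pooling stages."""
        t = self.input_length
        for _, _, pool in self.conv_blocks:
            t //= pool
        return t

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


# --------------------------------------------------------------------------
# Layers
# --------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, *shape) -> np.ndarray:
    fan_in = int(np.prod(shape[:-1])) or 1
    fan_out = shape[-1]
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape)


class Conv1d:
    """'Same'-padded 1-D convolution, (B, T, C_in) -> (B, T, C_out)."""

    def __init__(self, in_ch, out_ch, kernel, rng):
        self.weight = Parameter(_glorot(rng, kernel, in_ch, out_ch))
        self.bias = Parameter(np.zeros(out_ch))

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[1] < self.weight.shape[0]:
            raise ValueError(
                f"input length {x.shape[1]} shorter than kernel "
                f"{self.weight.shape[0]}"
            )
        return x.conv1d(self.weight, self.bias)

    def parameters(self):
        return [self.weight, self.bias]


class BatchNorm1d:
    """Per-channel batch normalization over (batch, time)."""

    def __init__(self, n_ch, momentum=0.1, eps=1e-5):
        self.gamma = Parameter(np.ones(n_ch))
        self.beta = Parameter(np.zeros(n_ch))
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self.momentum, self.eps = momentum, eps

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        if train:
            m = x.data.mean(axis=(0, 1))
            v = x.data.var(axis=(0, 1))
            self.running_mean += self.momentum * (m - self.running_mean)
            self.running_var += self.momentum * (v - self.running_var)
            return batchnorm(x, self.gamma, self.beta, self.eps)
        norm = (x - Tensor(self.running_mean)) * Tensor(
            1.0 / np.sqrt(self.running_var + self.eps)
        )
        return norm * self.gamma + self.beta

    def parameters(self):
        return [self.gamma, self.beta]


class Linear:
    def __init__(self, n_in, n_out, rng):
        self.weight = Parameter(_glorot(rng, n_in, n_out))
        self.bias = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    def parameters(self):
        return [self.weight, self.bias]


class GRU:
    """Single-layer GRU, optionally bidirectional; (B, T, C) -> (B, T, D*H).

    Gate equations per step (z update, r reset, n candidate):
    z = sigmoid(x W_z + h U_z + b_z), r = sigmoid(x W_r + h U_r + b_r),
    n = tanh(x W_n + r * (h U_n) + b_n), h' = (1 - z) n + z h.
    """

    GATES = ("z", "r", "n")

    def __init__(self, in_size, hidden, rng, bidirectional=True):
        self.hidden = hidden
        self.bidirectional = bidirectional
        self.dirs = []
        for _ in range(2 if bidirectional else 1):
            self.dirs.append(
                {
                    g: {
                        "W": Parameter(_glorot(rng, in_size, hidden)),
                        "U": Parameter(_glorot(rng, hidden, hidden)),
                        "b": Parameter(np.zeros(hidden)),
                    }
                    for g in self.GATES
                }
            )

    def _run(self, x: Tensor, p: dict, reverse: bool) -> list:
        B, T, _ = x.shape
        # input projections for the whole sequence at once
        xz = (x @ p["z"]["W"] + p["z"]["b"]).unbind(axis=1)
        xr = (x @ p["r"]["W"] + p["r"]["b"]).unbind(axis=1)
        xn = (x @ p["n"]["W"] + p["n"]["b"]).unbind(axis=1)
        h = Tensor(np.zeros((B, self.hidden)))
        outs = []
        steps = range(T - 1, -1, -1) if reverse else range(T)
        for t in steps:
            z = (xz[t] + h @ p["z"]["U"]).sigmoid()
            r = (xr[t] + h @ p["r"]["U"]).sigmoid()
            n = (xn[t] + r * (h @ p["n"]["U"])).tanh()
            h = (1.0 - z) * n + z * h
            outs.append(h)
        if reverse:
            outs.reverse()
        return outs

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[1] < 1:
            raise ValueError("GRU requires a non-empty time dimension")
        fwd = stack(self._run(x, self.dirs[0], reverse=False), axis=1)
        if not self.bidirectional:
            return fwd
        bwd = stack(self._run(x, self.dirs[1], reverse=True), axis=1)
        return concat([fwd, bwd], axis=-1)

    def parameters(self):
        return [
            d[g][k] for d in self.dirs for g in self.GATES for k in ("W", "U", "b")
        ]


def attention_head(x: Tensor, w_q: Tensor, w_k: Tensor, w_v: Tensor):
    """One scaled dot-product self-attention head.

    Returns ``(output, weights)`` where
    weights = softmax((X W_q)(X W_k)^T / sqrt(d_k)) row-wise and
    output = weights @ (X W_v).
    """
    if not isinstance(x, Tensor):
        x = Tensor(x)
    w_q, w_k, w_v = (t if isinstance(t, Tensor) else Tensor(t) for t in (w_q, w_k, w_v))
    d_k = w_q.shape[-1]
    if d_k == 0:
        raise ConfigError("d_k must be positive")
    q, k, v = x @ w_q, x @ w_k, x @ w_v
    scores = (q @ k.transpose(*range(k.ndim - 2), k.ndim - 1, k.ndim - 2)) * (
        1.0 / np.sqrt(d_k)
    )
    weights = scores.softmax(axis=-1)
    return weights @ v, weights


@dataclass
class AttentionParams:
    """Per-head projection matrices plus the output projection."""

    w_q: list
    w_k: list
    w_v: list
    w_o: Tensor


def multi_head(x: Tensor, params: AttentionParams, h: int):
    """Multi-head attention: concat(head_1..head_h) W_o.

    Returns ``(output, per_head_weights)``.  With ``h = 1`` and an identity
    output projection this reduces exactly to :func:`attention_head`.
    """
    if len(params.w_q) != h:
        raise ConfigError(f"expected {h} head projections, got {len(params.w_q)}")
    outs, weights = [], []
    for i in range(h):
        o, w = attention_head(x, params.w_q[i], params.w_k[i], params.w_v[i])
        outs.append(o)
        weights.append(w)
    cat = outs[0] if h == 1 else concat(outs, axis=-1)
    w_o = params.w_o if isinstance(params.w_o, Tensor) else Tensor(params.w_o)
    return cat @ w_o, weights


class MultiHeadSelfAttention:
    def __init__(self, d_model, n_heads, rng):
        if d_model % n_heads != 0:
            raise ConfigError("d_model must be divisible by n_heads")
        d_k = d_model // n_heads
        self.n_heads = n_heads
        self.params = AttentionParams(
            w_q=[Parameter(_glorot(rng, d_model, d_k)) for _ in range(n_heads)],
            w_k=[Parameter(_glorot(rng, d_model, d_k)) for _ in range(n_heads)],
            w_v=[Parameter(_glorot(rng, d_model, d_k)) for _ in range(n_heads)],
            w_o=Parameter(_glorot(rng, d_model, d_model)),
        )

    def __call__(self, x: Tensor):
        return multi_head(x, self.params, self.n_heads)

    def parameters(self):
        p = self.params
        return p.w_q + p.w_k + p.w_v + [p.w_o]


@dataclass
class ModelOutput:
    """Forward-pass result for a batch."""

    logits: np.ndarray
    probabilities: np.ndarray
    attention: Optional[list]  # per head: (B, T, T) row-stochastic
    embedding: np.ndarray      # penultimate (pre-dense) features


# --------------------------------------------------------------------------
# The model
# --------------------------------------------------------------------------

class CBGMModel:
    """CNN-BiGRU-multi-head-attention classifier over 300-sample pulses."""

    def __init__(self, config: Optional[ModelConfig] = None, seed: int = 0):
        self.config = config or ModelConfig()
        rng = np.random.default_rng(seed)
        cfg = self.config
        self.convs, self.bns, self.pools = [], [], []
        in_ch = 1
        for n_filters, kernel, pool in cfg.conv_blocks:
            self.convs.append(Conv1d(in_ch, n_filters, kernel, rng))
            self.bns.append(BatchNorm1d(n_filters))
            self.pools.append(pool)
            in_ch = n_filters
        seq_width = in_ch
        self.gru = None
        if cfg.use_bigru:
            self.gru = GRU(in_ch, cfg.gru_hidden, rng, cfg.bidirectional)
            seq_width = (2 if cfg.bidirectional else 1) * cfg.gru_hidden
        self.attention = None
        if cfg.use_attention:
            self.attention = MultiHeadSelfAttention(cfg.d_model, cfg.n_heads, rng)
            seq_width = cfg.d_model
        self.head = Linear(cfg.feature_length() * seq_width, cfg.n_classes, rng)
        # populated on every forward pass (used by Grad-CAM)
        self.conv_activations: list = []
        self.last_attention: Optional[list] = None

    # -- plumbing ----------------------------------------------------------
    def parameters(self) -> list:
        params = []
        for c, b in zip(self.convs, self.bns):
            params += c.parameters() + b.parameters()
        if self.gru is not None:
            params += self.gru.parameters()
        if self.attention is not None:
            params += self.attention.parameters()
        params += self.head.parameters()
        return params

    def layer_census(self) -> list:
        """Names of the hidden layers, in order (13 for the full model)."""
        names = []
        for i in range(len(self.convs)):
            names += [f"conv{i + 1}", f"batchnorm{i + 1}", f"maxpool{i + 1}"]
        if self.gru is not None:
            names.append("bigru")
        if self.attention is not None:
            names.append("attention")
        names += ["dropout", "dense"]
        return names

    @staticmethod
    def _as_batch(x) -> np.ndarray:
        if isinstance(x, Segment):
            x = x.values
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        return x

    # -- forward -----------------------------------------------------------
    def forward_tensor(
        self,
        x,
        train: bool = False,
        rng: Optional[np.random.Generator] = None,
    ) -> Tensor:
        """Forward pass returning the logits tensor (graph retained)."""
        cfg = self.config
        xb = self._as_batch(x)
        if xb.shape[1] != cfg.input_length:
            raise ValueError(
                f"expected input length {cfg.input_length}, got {xb.shape[1]}"
            )
        t = Tensor(xb[:, :, None])
        self.conv_activations = []
        for conv, bn, pool in zip(self.convs, self.bns, self.pools):
            t = bn(conv(t), train=train).relu()
            if pool > 1:
                t = t.max_pool1d(pool)
            self.conv_activations.append(t)
        if self.gru is not None:
            t = self.gru(t)
        self.last_attention = None
        if self.attention is not None:
            t, weights = self.attention(t)
            self.last_attention = [w.data for w in weights]
        if train and cfg.dropout_p > 0:
            if rng is None:
                rng = np.random.default_rng(0)
            mask = (rng.random(t.shape) >= cfg.dropout_p) / (1.0 - cfg.dropout_p)
            t = t * Tensor(mask)
        B = t.shape[0]
        self._embedding = t.reshape(B, -1)
        return self.head(self._embedding)

    def forward(self, x) -> ModelOutput:
        """Inference-mode forward pass (no autodiff graph)."""
        with no_grad():
            logits = self.forward_tensor(x, train=False)
        probs = logits.softmax(axis=-1).data
        return ModelOutput(
            logits=logits.data,
            probabilities=probs,
            attention=self.last_attention,
            embedding=self._embedding.data,
        )

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        X = self._as_batch(X)
        return np.concatenate(
            [
                self.forward(X[i : i + batch_size]).probabilities
                for i in range(0, len(X), batch_size)
            ]
        )

    def predict(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return self.predict_proba(X, batch_size).argmax(axis=1)

    # -- weights -----------------------------------------------------------
    def state_arrays(self) -> list:
        arrays = [p.data for p in self.parameters()]
        for bn in self.bns:
            arrays += [bn.running_mean, bn.running_var]
        return arrays

    def set_state(self, arrays: list) -> None:
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError("weight checkpoint does not match architecture")
        params = self.parameters()
        for p, a in zip(params, arrays[: len(params)]):
            p.data[...] = a
        k = len(params)
        for bn in self.bns:
            bn.running_mean[...] = arrays[k]
            bn.running_var[...] = arrays[k + 1]
            k += 2


def count_parameters(config: ModelConfig) -> int:
    """Total trainable scalar parameters of the configured model."""
    model = CBGMModel(config, seed=0)
    return sum(p.data.size for p in model.parameters())


def save_weights(model: CBGMModel, path: str) -> None:
    arrays = {f"a{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, config=json.dumps(model.config.to_dict()), **arrays)


def load_weights(path: str) -> CBGMModel:
    with np.load(path, allow_pickle=False) as z:
        cfg = ModelConfig.from_dict(json.loads(str(z["config"])))
        model = CBGMModel(cfg, seed=0)
        arrays = [z[f"a{i}"] for i in range(len(z.files) - 1)]
    model.set_state(arrays)
    return model
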