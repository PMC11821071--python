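"""Learnable layer primitives of the fully-gated denoising autoencoder.

Five building blocks, each a pure, deterministic-at-inference transform on
real-valued sequence tensors:

* **self-ONN convolution** — a 1-D convolution whose nodal function is a
  learnable degree-``q`` polynomial (truncated MacLaurin series): the input is
  raised element-wise to powers ``1..q`` and each power is cross-correlated
  with its own kernel bank.  ``q = 1`` reduces exactly to an ordinary
  convolution.  The constant (order-0) term is folded into a single per-output
  bias shared across orders.
* **gated self-ONN** — two parallel self-ONN paths; the gate path is squashed
  by a sigmoid (optionally dropped out during training) and multiplies the
  input path element-wise.
* **gated deconvolution** — the decoder counterpart: two parallel transpose
  convolutions (stride 2 in the full model), gated the same way.
* **channel attention** — global max- and average-pooled channel descriptors
  pass through one shared kernel-3 convolution; the sum of the two sigmoids
  forms a per-channel mask in (0, 2).
* **residual gate** — the decoder feature map is multiplied by a sigmoid mask
  built from point convolutions of itself and of the encoder skip; the skip
  content enters only through the mask.

Public forwards accept either a time-major numpy array of shape ``(L,)`` or
``(L, C)`` (returned in kind), or a batched autodiff ``Tensor`` of shape
``(B, L, C)`` for use inside the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import (
    Tensor,
    astensor,
    conv1d,
    conv_transpose1d,
    dropout,
    sigmoid,
)

__all__ = [
    "SelfONNParams",
    "GatedLayerParams",
    "AttentionParams",
    "ResidualGateParams",
    "InstanceNormParams",
    "selfonn1d_forward",
    "gated_selfonn_forward",
    "gated_deconv_forward",
    "channel_attention_forward",
    "residual_gate_forward",
    "instance_norm_forward",
]


def _fan_in_uniform(rng: np.random.Generator, shape, fan_in: int, dtype):
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


@dataclass
class SelfONNParams:
    """Weights of one self-ONN (or plain/transpose conv) path.

    W has one kernel bank per polynomial order: shape ``(q, K, Cin, Cout)``.
    b is a single bias per output channel, shared across orders.
    """

    W: Tensor
    b: Tensor

    def __post_init__(self):
        if self.W.ndim != 4:
            raise ValueError("W must have shape (q, K, Cin, Cout)")
        q, K, cin, cout = self.W.shape
        if q < 1:
            raise ValueError(f"polynomial order q must be >= 1, got {q}")
        if K % 2 == 0:
            raise ValueError(f"kernel length must be odd, got {K}")
        if self.b.shape != (cout,):
            raise ValueError("bias length must equal the output channel count")

    @property
    def q(self) -> int:
        return self.W.shape[0]

    @property
    def in_channels(self) -> int:
        return self.W.shape[2]

    @property
    def out_channels(self) -> int:
        return self.W.shape[3]

    @property
    def kernel_size(self) -> int:
        return self.W.shape[1]

    @classmethod
    def init(cls, q, cin, cout, K=9, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        fan = cin * K * q
        return cls(
            W=Tensor(_fan_in_uniform(rng, (q, K, cin, cout), fan, dtype), requires_grad=True),
            b=Tensor(_fan_in_uniform(rng, (cout,), fan, dtype), requires_grad=True),
        )

    def parameters(self):
        return [self.W, self.b]


@dataclass
class GatedLayerParams:
    """Input path + gate path of identical shape, plus the gate dropout rate."""

    input_path: SelfONNParams
    gate_path: SelfONNParams
    dropout_rate: float = 0.0

    def __post_init__(self):
        a, g = self.input_path, self.gate_path
        if (a.in_channels, a.out_channels, a.kernel_size) != (
            g.in_channels,
            g.out_channels,
            g.kernel_size,
        ):
            raise ValueError("input and gate paths must have identical shapes")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")

    def parameters(self):
        return self.input_path.parameters() + self.gate_path.parameters()


@dataclass
class AttentionParams:
    """Shared kernel-3 convolution over the channel axis, with bias."""

    w: Tensor
    b: Tensor
    dropout_rate: float = 0.0

    def __post_init__(self):
        if self.w.shape != (3,):
            raise ValueError("attention kernel length is fixed to 3")

    @classmethod
    def init(cls, rng=None, dropout_rate=0.0, dtype=np.float32):
        rng = rng or np.random.default_rng()
        return cls(
            w=Tensor(_fan_in_uniform(rng, (3,), 3, dtype), requires_grad=True),
            b=Tensor(np.zeros(1, dtype=dtype), requires_grad=True),
            dropout_rate=dropout_rate,
        )

    def parameters(self):
        return [self.w, self.b]


@dataclass
class ResidualGateParams:
    """Two full C->C point convolutions (kernel length 1) with biases."""

    Win: Tensor
    bin: Tensor
    Wres: Tensor
    bres: Tensor
    dropout_rate: float = 0.0

    def __post_init__(self):
        C = self.Win.shape[1]
        for name, t, shape in (
            ("Win", self.Win, (1, C, C)),
            ("bin", self.bin, (C,)),
            ("Wres", self.Wres, (1, C, C)),
            ("bres", self.bres, (C,)),
        ):
            if t.shape != shape:
                raise ValueError(f"{name} must have shape {shape}, got {t.shape}")

    @classmethod
    def init(cls, channels, rng=None, dropout_rate=0.0, dtype=np.float32):
        rng = rng or np.random.default_rng()
        return cls(
            Win=Tensor(_fan_in_uniform(rng, (1, channels, channels), channels, dtype), requires_grad=True),
            bin=Tensor(np.zeros(channels, dtype=dtype), requires_grad=True),
            Wres=Tensor(_fan_in_uniform(rng, (1, channels, channels), channels, dtype), requires_grad=True),
            bres=Tensor(np.zeros(channels, dtype=dtype), requires_grad=True),
            dropout_rate=dropout_rate,
        )

    def parameters(self):
        return [self.Win, self.bin, self.Wres, self.bres]


@dataclass
class InstanceNormParams:
    """Per-channel affine parameters for instance normalization."""

    gamma: Tensor
    beta: Tensor
    eps: float = 1e-3

    def __post_init__(self):
        if self.gamma.shape != self.beta.shape or self.gamma.ndim != 1:
            raise ValueError("gamma and beta must be equal-length vectors")
        if self.eps <= 0:
            raise ValueError("eps must be positive")

    @classmethod
    def init(cls, channels, eps=1e-3, dtype=np.float32):
        return cls(
            gamma=Tensor(np.ones(channels, dtype=dtype), requires_grad=True),
            beta=Tensor(np.zeros(channels, dtype=dtype), requires_grad=True),
            eps=eps,
        )

    def parameters(self):
        return [self.gamma, self.beta]


# ---------------------------------------------------------------------------
# forward transforms
# ---------------------------------------------------------------------------


def _to_blc(x):
    """Accept (L,), (L, C) ndarray or (B, L, C) Tensor; return (tensor, restore)."""
    if isinstance(x, Tensor):
        if x.ndim != 3:
            raise ValueError("Tensor inputs must have shape (B, L, C)")
        return x, None
    arr = np.asarray(x, dtype=np.float64) if np.asarray(x).dtype.kind != "f" else np.asarray(x)
    if not np.all(np.isfinite(arr)):
        raise ValueError("input contains non-finite values")
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ValueError("array inputs must have shape (L,) or (L, C)")

    def restore(t: Tensor) -> np.ndarray:
        out = t.data[0]  # (L, Cout)
        return out[:, 0] if squeeze else out

    return Tensor(arr[None, :, :]), restore


def selfonn1d_forward(x, p: SelfONNParams, *, powers=None):
    """Degree-q polynomial ('self-ONN') convolution, stride 1, 'same' padding.

    ``y[:, co] = b[co] + sum_{n=1..q} crosscorr(x**n, W[n])[:, co]``.

    ``powers`` lets a caller that evaluates several paths on the same input
    reuse the precomputed list ``[x, x**2, ..., x**q]``.
    """
    t, restore = _to_blc(x)
    if powers is None:
        powers = [t]
        for n in range(2, p.q + 1):
            powers.append(t ** n)
    y = conv1d(powers[0], p.W[0], p.b)
    for n in range(1, p.q):
        y = y + conv1d(powers[n], p.W[n])
    return y if restore is None else restore(y)


def gated_selfonn_forward(x, gp: GatedLayerParams, training=False, rng=None):
    """Eq. y = ONN_i(x) * dropout(sigmoid(ONN_g(x))).

    Dropout is active only in training mode and only when the layer has more
    than one output channel.
    """
    t, restore = _to_blc(x)
    q = gp.input_path.q
    powers = [t]
    for n in range(2, q + 1):
        powers.append(t ** n)
    feat = selfonn1d_forward(t, gp.input_path, powers=powers)
    gate = sigmoid(selfonn1d_forward(t, gp.gate_path, powers=powers))
    if training and gp.dropout_rate > 0 and gp.input_path.out_channels > 1:
        gate = dropout(gate, gp.dropout_rate, rng or np.random.default_rng())
    y = feat * gate
    return y if restore is None else restore(y)


def _deconv_path(t: Tensor, p: SelfONNParams, stride: int) -> Tensor:
    # transpose conv uses the order-1 kernel bank, already in (K, Cin, Cout) layout
    return conv_transpose1d(t, p.W[0], p.b, stride=stride)


def gated_deconv_forward(x, gp: GatedLayerParams, stride=2, training=False, rng=None):
    """Gated transpose convolution; output length is exactly stride * L."""
    t, restore = _to_blc(x)
    L = t.shape[1]
    feat = _deconv_path(t, gp.input_path, stride)
    gate = sigmoid(_deconv_path(t, gp.gate_path, stride))
    if feat.shape[1] != stride * L:
        raise RuntimeError(
            f"transpose-conv length contract violated: {feat.shape[1]} != {stride * L}"
        )
    if training and gp.dropout_rate > 0 and gp.input_path.out_channels > 1:
        gate = dropout(gate, gp.dropout_rate, rng or np.random.default_rng())
    y = feat * gate
    return y if restore is None else restore(y)


def channel_attention_forward(x, ap: AttentionParams, training=False, rng=None):
    """Per-channel mask from pooled descriptors; mask values lie in (0, 2)."""
    t, restore = _to_blc(x)
    B, L, C = t.shape
    # pooled descriptors become a length-C, single-channel sequence for the
    # shared kernel-3 convolution along the channel axis
    xmax = t.max(axis=1).reshape(B, C, 1)
    xavg = t.mean(axis=1).reshape(B, C, 1)
    W = ap.w.reshape(3, 1, 1)
    omega = sigmoid(conv1d(xmax, W, ap.b)) + sigmoid(conv1d(xavg, W, ap.b))
    if training and ap.dropout_rate > 0 and C > 1:
        omega = dropout(omega, ap.dropout_rate, rng or np.random.default_rng())
    y = t * omega.reshape(B, 1, C)
    return y if restore is None else restore(y)


def residual_gate_forward(x_in, x_res, rp: ResidualGateParams, training=False, rng=None):
    """y = x_in * sigmoid(pointconv(x_in) + dropout(pointconv(x_res)))."""
    tin, restore = _to_blc(x_in)
    tres, _ = _to_blc(x_res)
    if tin.shape != tres.shape:
        raise ValueError(f"shape mismatch: {tin.shape} vs {tres.shape}")
    a = conv1d(tin, rp.Win, rp.bin)
    r = conv1d(tres, rp.Wres, rp.bres)
    if training and rp.dropout_rate > 0 and tin.shape[2] > 1:
        r = dropout(r, rp.dropout_rate, rng or np.random.default_rng())
    y = tin * sigmoid(a + r)
    return y if restore is None else restore(y)


def instance_norm_forward(x, np_: InstanceNormParams):
    """Standardize each sample and channel over the time axis, then affine."""
    t, restore = _to_blc(x)
    C = t.shape[2]
    if np_.gamma.shape[0] != C:
        raise ValueError("channel count does not match the affine parameters")
    mu = t.mean(axis=1, keepdims=True)
    xc = t - mu
    var = (xc ** 2).mean(axis=1, keepdims=True)
    inv = (var + np_.eps) ** -0.5
    y = xc * inv * np_.gamma.reshape(1, 1, C) + np_.beta.reshape(1, 1, C)
    return y if restore is None else restore(y)
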