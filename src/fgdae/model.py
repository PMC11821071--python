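"""Assembly of the fully-gated denoising autoencoder (FGDAE).

A U-Net-shaped denoising autoencoder for single-channel ECG segments of 512
samples: five encoder blocks (gated self-ONN -> instance norm -> LeakyReLU ->
max-pool -> channel attention), five decoder blocks (gated transpose
convolution, stride 2 -> instance norm -> LeakyReLU -> channel attention), and
four residual gates that let each encoder skip modulate the matching decoder
feature map through a sigmoid mask (no concatenation).

Default channel schedule for the encoder outputs is (16, 32, 64, 64, 1); the
decoder mirrors it back to a single channel.  With a 512-sample input the
feature-map trace is::

    encoder: 256x16 -> 128x32 -> 64x64 -> 32x64 -> 16x1
    decoder:  32x64 -> 64x64 -> 128x32 -> 256x16 -> 512x1

Under this configuration the network has 263,248 trainable parameters at
q = 1, and each additional polynomial order adds exactly the 121,248 encoder
kernel weights of one extra bank per self-ONN path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._autodiff import Tensor, leaky_relu, maxpool1d
from .layers import (
    AttentionParams,
    GatedLayerParams,
    InstanceNormParams,
    ResidualGateParams,
    SelfONNParams,
    channel_attention_forward,
    gated_deconv_forward,
    gated_selfonn_forward,
    instance_norm_forward,
    residual_gate_forward,
)

__all__ = [
    "ModelConfig",
    "FGDAEModel",
    "build_fgdae",
    "fgdae_denoise",
    "count_trainable_parameters",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    q: int = 1
    encoder_out_channels: tuple = (16, 32, 64, 64, 1)
    kernel: int = 9
    pool: int = 2
    deconv_stride: int = 2
    attention_kernel: int = 3
    leaky_slope: float = 0.3
    dropout_base: float = 0.001
    input_length: int = 512
    input_channels: int = 1
    instance_norm_eps: float = 1e-3

    def __post_init__(self):
        if self.q < 1:
            raise ValueError("q must be >= 1")
        if len(self.encoder_out_channels) != 5:
            raise ValueError("encoder schedule must have 5 entries")
        if self.encoder_out_channels[-1] != 1:
            raise ValueError("the bottleneck (encoder block 5) must have 1 channel")
        if self.input_length % 2 ** 5:
            raise ValueError("input length must be divisible by 2^5")
        if self.kernel % 2 == 0:
            raise ValueError("kernel length must be odd")

    def to_dict(self):
        d = asdict(self)
        d["encoder_out_channels"] = list(self.encoder_out_channels)
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        d["encoder_out_channels"] = tuple(d["encoder_out_channels"])
        return cls(**d)


@dataclass
class _Block:
    gated: GatedLayerParams
    norm: InstanceNormParams
    attention: AttentionParams

    def parameters(self):
        return self.gated.parameters() + self.norm.parameters() + self.attention.parameters()


@dataclass
class FGDAEModel:
    config: ModelConfig
    encoder_blocks: list
    decoder_blocks: list
    residual_gates: list

    def parameters(self):
        ps = []
        for b in self.encoder_blocks + self.decoder_blocks:
            ps += b.parameters()
        for g in self.residual_gates:
            ps += g.parameters()
        return ps

    def encoder_parameters(self):
        """Trainable parameters of the five encoder blocks (L1-penalty scope)."""
        ps = []
        for b in self.encoder_blocks:
            ps += b.parameters()
        return ps

    def parameter_dict(self):
        """Stable name -> Tensor mapping for checkpointing."""
        names = {}
        for i, b in enumerate(self.encoder_blocks):
            names.update(_block_names(f"enc{i}", b))
        for i, b in enumerate(self.decoder_blocks):
            names.update(_block_names(f"dec{i}", b))
        for i, g in enumerate(self.residual_gates):
            for attr in ("Win", "bin", "Wres", "bres"):
                names[f"gate{i}.{attr}"] = getattr(g, attr)
        return names


def _block_names(prefix, b: _Block):
    return {
        f"{prefix}.input.W": b.gated.input_path.W,
        f"{prefix}.input.b": b.gated.input_path.b,
        f"{prefix}.gate.W": b.gated.gate_path.W,
        f"{prefix}.gate.b": b.gated.gate_path.b,
        f"{prefix}.norm.gamma": b.norm.gamma,
        f"{prefix}.norm.beta": b.norm.beta,
        f"{prefix}.att.w": b.attention.w,
        f"{prefix}.att.b": b.attention.b,
    }


def build_fgdae(cfg: ModelConfig = None, seed: int = 0, dtype=np.float32) -> FGDAEModel:
    """Instantiate the network with seeded fan-in-uniform weight init."""
    cfg = cfg or ModelConfig()
    rng = np.random.default_rng(seed)

    def gated(q, cin, cout, drop):
        return GatedLayerParams(
            input_path=SelfONNParams.init(q, cin, cout, cfg.kernel, rng, dtype),
            gate_path=SelfONNParams.init(q, cin, cout, cfg.kernel, rng, dtype),
            dropout_rate=drop,
        )

    def block(q, cin, cout, drop):
        return _Block(
            gated=gated(q, cin, cout, drop),
            norm=InstanceNormParams.init(cout, cfg.instance_norm_eps, dtype),
            attention=AttentionParams.init(rng, cfg.dropout_base, dtype),
        )

    enc_sched = list(cfg.encoder_out_channels)
    enc_in = [cfg.input_channels] + enc_sched[:-1]
    encoder = [
        block(cfg.q, cin, cout, cfg.dropout_base * cfg.q)
        for cin, cout in zip(enc_in, enc_sched)
    ]

    # decoder mirrors the encoder back to one channel: 1 -> 64 -> 64 -> 32 -> 16 -> 1
    dec_out = enc_sched[-2::-1] + [cfg.input_channels]
    dec_in = [enc_sched[-1]] + dec_out[:-1]
    decoder = [
        block(1, cin, cout, cfg.dropout_base) for cin, cout in zip(dec_in, dec_out)
    ]

    # residual gate i pairs decoder block i's output with encoder block (4-i)'s output
    gates = [
        ResidualGateParams.init(dec_out[i], rng, cfg.dropout_base, dtype)
        for i in range(4)
    ]
    return FGDAEModel(cfg, encoder, decoder, gates)


def _encoder_block(t, b: _Block, cfg, training, rng):
    t = gated_selfonn_forward(t, b.gated, training, rng)
    t = instance_norm_forward(t, b.norm)
    t = leaky_relu(t, cfg.leaky_slope)
    t = maxpool1d(t, cfg.pool)
    return channel_attention_forward(t, b.attention, training, rng)


def _decoder_block(t, b: _Block, cfg, training, rng):
    t = gated_deconv_forward(t, b.gated, cfg.deconv_stride, training, rng)
    t = instance_norm_forward(t, b.norm)
    t = leaky_relu(t, cfg.leaky_slope)
    return channel_attention_forward(t, b.attention, training, rng)


def fgdae_forward(model: FGDAEModel, t: Tensor, training=False, rng=None) -> Tensor:
    """Batched forward pass on a (B, L, C) Tensor (autodiff-aware)."""
    cfg = model.config
    skips = []
    for b in model.encoder_blocks:
        t = _encoder_block(t, b, cfg, training, rng)
        skips.append(t)
    for i, b in enumerate(model.decoder_blocks):
        t = _decoder_block(t, b, cfg, training, rng)
        if i < 4:
            t = residual_gate_forward(t, skips[3 - i], model.residual_gates[i], training, rng)
    return t


def fgdae_denoise(model: FGDAEModel, x, training=False, seed=None) -> np.ndarray:
    """Denoise a batch of segments.

    x: array of shape (B, L, 1), (B, L) or (L,); returns the same shape.
    Inference calls are deterministic (dropout off).
    """
    arr = np.asarray(x, dtype=model.encoder_blocks[0].gated.input_path.W.data.dtype)
    orig_shape = arr.shape
    if arr.ndim == 1:
        arr = arr[None, :, None]
    elif arr.ndim == 2:
        arr = arr[:, :, None]
    if not np.all(np.isfinite(arr)):
        raise ValueError("input contains non-finite values")
    t = Tensor(arr)  # (B, L, C)
    rng = np.random.default_rng(seed) if training else None
    out = fgdae_forward(model, t, training, rng)
    y = out.data
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite output from the network")
    return y.reshape(orig_shape)


def count_trainable_parameters(model: FGDAEModel) -> int:
    """Exact number of learnable scalars in the model."""
    return int(sum(p.data.size for p in model.parameters()))


# ---------------------------------------------------------------------------
# checkpoints: a single .npz archive of named weight arrays + the JSON config
# ---------------------------------------------------------------------------


def save_checkpoint(model: FGDAEModel, path):
    arrays = {k: v.data for k, v in model.parameter_dict().items()}
    arrays["__config__"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> FGDAEModel:
    with np.load(path) as z:
        cfg = ModelConfig.from_dict(json.loads(bytes(z["__config__"].tobytes()).decode()))
        model = build_fgdae(cfg, seed=0)
        params = model.parameter_dict()
        for k, t in params.items():
            t.data = z[k].copy()
    return model
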