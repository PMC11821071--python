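"""Composite training objective.

Four components, summed without further weighting:

* ``J_recon`` — per segment, the sum of squared distances (SSD) plus
  ``lambda_mad`` times the maximum absolute distance (MAD); mean over the
  batch.  SSD drives overall closeness, the MAD term rejects outliers.
* ``J_grad`` — the largest absolute deviation between the first differences
  of target and estimate (unscaled); mean over the batch.  Encourages the
  estimate to track fine morphological detail.
* ``J_morph`` — ``lambda_morph * (1 - min_i corr(x_i, xhat_i))`` over the
  batch, with Pearson correlation; the unscaled term lies in [0, 2].
  Penalizing the batch minimum targets the hardest segment.
* ``J_reg`` — ``lambda_reg`` times the L1 norm of all encoder-block
  parameters, promoting a sparse encoder.

All functions accept plain arrays (vectors or batches) and return floats,
or autodiff tensors (inside the training loop) and return scalar tensors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, astensor

__all__ = [
    "LossConfig",
    "reconstruction_loss",
    "gradient_loss",
    "morphology_loss",
    "encoder_l1_penalty",
    "total_loss",
]


@dataclass
class LossConfig:
    lambda_mad: float = 50.0
    lambda_morph: float = 10.0
    lambda_reg: float = 0.01
    corr_eps: float = 1e-8

    def __post_init__(self):
        if min(self.lambda_mad, self.lambda_morph, self.lambda_reg) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.corr_eps <= 0:
            raise ValueError("corr_eps must be positive")


def _as_batch(x) -> Tensor:
    """Vector, list of vectors, or (B, N) array/Tensor -> (B, N) Tensor."""
    if isinstance(x, Tensor):
        return x if x.ndim == 2 else x.reshape(1, -1)
    arr = np.atleast_2d(np.asarray(x, dtype=float))
    return Tensor(arr)


def _check_pair(x: Tensor, xhat: Tensor, min_len: int = 1):
    if x.shape != xhat.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {xhat.shape}")
    if x.shape[1] < min_len:
        raise ValueError(f"segments must have at least {min_len} samples")


def _maybe_float(val: Tensor, inputs) -> "Tensor | float":
    if any(isinstance(v, Tensor) for v in inputs):
        return val
    return float(val.data)


def reconstruction_loss(x, xhat, lc: LossConfig = None):
    """SSD + lambda_mad * MAD per segment, averaged over the batch."""
    lc = lc or LossConfig()
    tx, th = _as_batch(x), _as_batch(xhat)
    _check_pair(tx, th)
    d = tx - th
    per = (d ** 2).sum(axis=1) + lc.lambda_mad * d.abs().max(axis=1)
    return _maybe_float(per.mean(), (x, xhat))


def gradient_loss(x, xhat):
    """Maximum absolute difference of the first differences, batch mean."""
    tx, th = _as_batch(x), _as_batch(xhat)
    _check_pair(tx, th, min_len=2)
    dx = tx[:, 1:] - tx[:, :-1]
    dh = th[:, 1:] - th[:, :-1]
    per = (dx - dh).abs().max(axis=1)
    return _maybe_float(per.mean(), (x, xhat))


def morphology_loss(batch_x, batch_xhat, lc: LossConfig = None):
    """lambda_morph * (1 - batch-minimum Pearson correlation).

    A segment whose standard deviation falls below ``corr_eps`` is treated
    as zero-variance and contributes correlation 0 (worst-case-safe); for
    every other pair the correlation is the exact Pearson coefficient, so a
    perfectly (anti)correlated pair yields an unscaled term of exactly 0 (2).
    """
    lc = lc or LossConfig()
    tx, th = _as_batch(batch_x), _as_batch(batch_xhat)
    _check_pair(tx, th, min_len=2)
    if tx.shape[0] < 1:
        raise ValueError("batch must contain at least one pair")
    xc = tx - tx.mean(axis=1, keepdims=True)
    hc = th - th.mean(axis=1, keepdims=True)
    cov = (xc * hc).mean(axis=1)
    sx = (xc ** 2).mean(axis=1).sqrt()
    sh = (hc ** 2).mean(axis=1).sqrt()
    # constant mask selecting well-defined correlations; degenerate segments
    # get denominator 1 and a zeroed numerator, i.e. correlation 0
    valid = ((sx.data > lc.corr_eps) & (sh.data > lc.corr_eps)).astype(sx.data.dtype)
    denom = sx * sh * valid + (1.0 - valid)
    corr = cov * Tensor(valid) * denom ** -1.0
    # Pearson correlation is bounded; clamp the float rounding beyond +/-1 so
    # the loss term's range extremes (0 and 2) are attained exactly
    hi = corr.data > 1.0
    lo = corr.data < -1.0
    if hi.any() or lo.any():
        keep = (~hi & ~lo).astype(corr.data.dtype)
        corr = corr * Tensor(keep) + Tensor(hi.astype(corr.data.dtype) - lo.astype(corr.data.dtype))
    val = lc.lambda_morph * (1.0 + (-corr.min()))
    return _maybe_float(val, (batch_x, batch_xhat))


def encoder_l1_penalty(model, lc: LossConfig = None, parameter_mask=None):
    """lambda_reg * sum of |w| over the encoder-block parameters.

    ``parameter_mask`` optionally selects a subset (callable name -> bool on
    the model's parameter_dict naming) of encoder parameters to penalize.
    """
    lc = lc or LossConfig()
    if parameter_mask is None:
        params = model.encoder_parameters()
    else:
        params = [
            t for name, t in model.parameter_dict().items()
            if name.startswith("enc") and parameter_mask(name)
        ]
    total = None
    for p in params:
        term = p.abs().sum()
        total = term if total is None else total + term
    if total is None:
        return 0.0
    return lc.lambda_reg * total


def total_loss(batch, model, lc: LossConfig = None, training=False, rng=None):
    """Full objective on a (noisy, clean) batch; returns (total, components).

    ``batch`` is a tuple of arrays of shape (B, N): the corrupted inputs and
    the clean targets.  The model is run on the noisy inputs (with dropout if
    ``training``) and every loss component is evaluated against the clean
    targets.  ``total`` is a scalar autodiff tensor; ``components`` maps each
    term name to its float value for logging.
    """
    from .model import fgdae_forward  # local import to avoid a cycle

    lc = lc or LossConfig()
    noisy, clean = batch
    noisy = np.asarray(noisy)
    clean = np.asarray(clean)
    if noisy.shape != clean.shape:
        raise ValueError("noisy and clean batches must have identical shapes")
    B = noisy.shape[0]
    xhat = fgdae_forward(model, Tensor(noisy.reshape(B, -1, 1)), training, rng)
    xhat = xhat.reshape(B, -1)
    target = Tensor(clean.reshape(B, -1))

    jrecon = reconstruction_loss(target, xhat, lc)
    jgrad = gradient_loss(target, xhat)
    jmorph = morphology_loss(target, xhat, lc)
    jreg = encoder_l1_penalty(model, lc)
    total = jrecon + jgrad + jmorph + jreg

    components = {}
    for name, t in (("recon", jrecon), ("grad", jgrad), ("morph", jmorph), ("reg", jreg)):
        v = float(t.data) if isinstance(t, Tensor) else float(t)
        if not np.isfinite(v):
            raise FloatingPointError(f"non-finite loss component: {name}")
        components[name] = v
    components["total"] = float(total.data)
    return total, components
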