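"""Optimization loop and evaluation driver.

Adam with an initial learning rate of 1e-3 and batch size 64; the learning
rate halves when the validation loss fails to improve by at least 0.05 for
two consecutive epochs (floored at 1e-10), and training stops early after
ten consecutive epochs without improvement.  The weights achieving the best
validation loss are kept.

All randomness (shuffling, dropout) is seeded; a run with the same seed and
data reproduces its loss trajectory exactly.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass

import numpy as np

from .losses import LossConfig, total_loss
from .metrics import METRIC_NAMES, compute_metrics, stratified_report
from .model import FGDAEModel, fgdae_denoise

__all__ = ["TrainConfig", "AdamState", "lr_schedule_step", "train", "evaluate"]


@dataclass
class TrainConfig:
    batch_size: int = 64
    lr0: float = 1e-3
    lr_factor: float = 0.5
    lr_min: float = 1e-10
    plateau_min_delta: float = 0.05
    plateau_patience: int = 2
    early_stop_patience: int = 10
    max_epochs: int = 100_000
    seed: int = 0
    validation_fraction: float = 0.2

    def __post_init__(self):
        if not 0 < self.lr_factor < 1:
            raise ValueError("lr_factor must lie in (0, 1)")
        if self.lr_min <= 0:
            raise ValueError("lr_min must be positive")
        if min(self.plateau_patience, self.early_stop_patience) < 1:
            raise ValueError("patience values must be >= 1")


def _stale_epochs(history, min_delta):
    """Consecutive trailing epochs whose val loss failed to improve the
    running best by at least ``min_delta``."""
    best = history[0]
    stale = 0
    for v in history[1:]:
        if best - v >= min_delta:
            stale = 0
        else:
            stale += 1
        best = min(best, v)
    return stale


def lr_schedule_step(history, current_lr: float, tc: TrainConfig = None) -> float:
    """Plateau schedule: halve the rate when improvement stalls.

    Called once per epoch with the full validation-loss history.  The rate is
    reduced each time the stale count reaches a fresh multiple of the
    patience (so after a reduction the schedule waits a full patience window
    again), and never drops below ``lr_min``.
    """
    tc = tc or TrainConfig()
    if not len(history):
        raise ValueError("history must be non-empty")
    stale = _stale_epochs(list(history), tc.plateau_min_delta)
    if stale > 0 and stale % tc.plateau_patience == 0:
        return max(current_lr * tc.lr_factor, tc.lr_min)
    return current_lr


class AdamState:
    """Per-parameter Adam moments (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if g is None:
                continue
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def _val_loss(model, noisy, clean, lc, batch_size):
    vals = []
    weights = []
    for i in range(0, len(noisy), batch_size):
        _, comp = total_loss((noisy[i : i + batch_size], clean[i : i + batch_size]), model, lc)
        vals.append(comp["total"])
        weights.append(len(noisy[i : i + batch_size]))
    return float(np.average(vals, weights=weights))


def train(
    model: FGDAEModel,
    train_pairs,
    val_pairs=None,
    lc: LossConfig = None,
    tc: TrainConfig = None,
    log=None,
):
    """Optimize the model; returns (history, best_state).

    ``train_pairs``/``val_pairs`` are PairSet-like objects with ``noisy`` and
    ``clean`` arrays.  When ``val_pairs`` is None, a seeded random
    ``validation_fraction`` of the training pairs is held out.  ``history``
    is a list of per-epoch dicts (loss components, val loss, lr);
    ``best_state`` maps parameter names to the best-validation weights.
    """
    lc = lc or LossConfig()
    tc = tc or TrainConfig()
    rng = np.random.default_rng(tc.seed)

    noisy = np.asarray(train_pairs.noisy, dtype=np.float32)
    clean = np.asarray(train_pairs.clean, dtype=np.float32)
    if len(noisy) == 0:
        raise ValueError("empty training set")
    if val_pairs is None:
        idx = rng.permutation(len(noisy))
        n_val = max(1, int(round(tc.validation_fraction * len(noisy))))
        val_idx, tr_idx = idx[:n_val], idx[n_val:]
        vnoisy, vclean = noisy[val_idx], clean[val_idx]
        noisy, clean = noisy[tr_idx], clean[tr_idx]
    else:
        vnoisy = np.asarray(val_pairs.noisy, dtype=np.float32)
        vclean = np.asarray(val_pairs.clean, dtype=np.float32)

    params = model.parameters()
    opt = AdamState(params)
    lr = tc.lr0
    history = []
    best_val = np.inf
    best_state = {k: v.data.copy() for k, v in model.parameter_dict().items()}
    stale_early = 0

    for epoch in range(tc.max_epochs):
        order = rng.permutation(len(noisy))
        comps_sum = None
        n_batches = 0
        for i in range(0, len(order), tc.batch_size):
            sel = order[i : i + tc.batch_size]
            try:
                loss, comps = total_loss(
                    (noisy[sel], clean[sel]), model, lc, training=True, rng=rng
                )
            except FloatingPointError:
                sys.stderr.write("non-finite loss; stopping with last good weights\n")
                return history, best_state
            for p in params:
                p.zero_grad()
            loss.backward()
            opt.step(lr)
            n_batches += 1
            if comps_sum is None:
                comps_sum = dict(comps)
            else:
                for k in comps_sum:
                    comps_sum[k] += comps[k]
        epoch_comps = {k: v / n_batches for k, v in comps_sum.items()}
        val = _val_loss(model, vnoisy, vclean, lc, tc.batch_size)
        record = {"epoch": epoch, "lr": lr, "val_loss": val, **{f"train_{k}": v for k, v in epoch_comps.items()}}
        history.append(record)
        if log is not None:
            log(record)

        if val < best_val:
            best_val = val
            best_state = {k: v.data.copy() for k, v in model.parameter_dict().items()}
            stale_early = 0
        else:
            stale_early += 1
            if stale_early >= tc.early_stop_patience:
                break
        lr = lr_schedule_step([h["val_loss"] for h in history], lr, tc)
    return history, best_state


def restore_state(model: FGDAEModel, state: dict):
    """Load a parameter-name -> array mapping back into the model."""
    for k, t in model.parameter_dict().items():
        t.data = state[k].copy()


def evaluate(model: FGDAEModel, test_pairs, batch_size: int = 256):
    """Denoise the test pairs and aggregate the seven metrics.

    Returns ``(summary, by_amplitude, by_noise_type, per_segment)`` where
    ``summary`` maps each metric to (mean, std) over all pairs, the two
    stratified frames follow the benchmark's table layout and
    ``per_segment`` is the raw metric table.
    """
    noisy = np.asarray(test_pairs.noisy, dtype=np.float32)
    denoised = np.empty_like(noisy)
    for i in range(0, len(noisy), batch_size):
        denoised[i : i + batch_size] = fgdae_denoise(model, noisy[i : i + batch_size])
    reports = [
        compute_metrics(c, d).as_dict() for c, d in zip(test_pairs.clean, denoised)
    ]
    import pandas as pd

    per_segment = pd.DataFrame(reports)
    summary = {m: (float(per_segment[m].mean()), float(per_segment[m].std())) for m in METRIC_NAMES}
    triples = list(zip(test_pairs.clean, denoised, test_pairs.recipes))
    by_amp = stratified_report(triples, "amplitude")
    by_type = stratified_report(triples, "noise_type")
    return summary, by_amp, by_type, per_segment
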