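"""Synthetic clean ECG and artifact generation.

Stand-ins for the clean-ECG and ambulatory-noise recordings so that the
whole pipeline — segmentation, Random-Mixed-Noise corruption, training and
the seven-metric evaluation — runs end to end with no data download.

The clean ECG is a quasi-periodic sum of five Gaussian bumps per beat
(P, Q, R, S, T) at fixed phase offsets within each RR interval, with
per-beat heart-rate jitter and millivolt-scale amplitudes.  The three
artifact classes mirror the statistical structure of their ambulatory
counterparts:

* **BW** (baseline wander) — random-phase sinusoids below 0.7 Hz plus a
  low-pass-filtered random walk: slow, smooth drift.
* **MA** (muscle artifact) — band-limited (~5–50 Hz) noise under random
  burst envelopes: EMG-like crackle that comes and goes.
* **EM** (electrode motion) — sparse step discontinuities plus smoothed
  large spikes over mild background noise: the abrupt, ECG-like transients
  that make electrode motion the hardest artifact class.

Everything is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .dataprep import (
    NoiseSplit,
    PairSet,
    SEGMENT_LENGTH,
    corrupt_segment,
    sample_rmn_recipe,
    segment_signal,
)

__all__ = ["SynthConfig", "synth_ecg", "synth_artifact", "make_synthetic_benchmark"]


@dataclass
class SynthConfig:
    fs: float = 360.0
    duration: float = 30.0
    heart_rate: float = 70.0      # bpm, mean
    heart_rate_jitter: float = 3.0  # bpm std of per-beat variation
    # wave amplitudes in mV; R dominant as in a normal lead-II morphology
    amp_p: float = 0.15
    amp_q: float = -0.10
    amp_r: float = 1.00
    amp_s: float = -0.25
    amp_t: float = 0.35
    # artifact band parameters
    bw_max_hz: float = 0.7
    ma_band_hz: tuple = (5.0, 50.0)
    em_steps_per_min: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.fs != 360.0:
            raise ValueError("the pipeline operates at 360 Hz")
        if self.heart_rate <= 0:
            raise ValueError("heart rate must be positive")
        if self.amp_r <= max(abs(self.amp_p), abs(self.amp_t)):
            raise ValueError("the R wave must dominate the beat")


# (phase offset as fraction of the RR interval relative to R, width fraction)
_WAVES = {
    "p": (-0.22, 0.025),
    "q": (-0.045, 0.010),
    "r": (0.0, 0.012),
    "s": (0.045, 0.010),
    "t": (0.30, 0.060),
}


def synth_ecg(cfg: SynthConfig = None, duration: float | None = None) -> np.ndarray:
    """Quasi-periodic Gaussian-bump ECG, zero-mean, in mV."""
    cfg = cfg or SynthConfig()
    duration = cfg.duration if duration is None else duration
    rng = np.random.default_rng(cfg.seed)
    n = int(round(duration * cfg.fs))
    t = np.arange(n) / cfg.fs
    x = np.zeros(n)
    amps = {"p": cfg.amp_p, "q": cfg.amp_q, "r": cfg.amp_r, "s": cfg.amp_s, "t": cfg.amp_t}
    r_time = 0.5  # first beat placed away from the edge
    while r_time < duration + 1.0:
        bpm = cfg.heart_rate + (
            rng.normal(0.0, cfg.heart_rate_jitter) if cfg.heart_rate_jitter > 0 else 0.0
        )
        bpm = max(bpm, 20.0)
        rr = 60.0 / bpm
        for wave, (frac, wfrac) in _WAVES.items():
            mu = r_time + frac * rr
            sig = max(wfrac * rr, 1.5 / cfg.fs)
            lo = max(0, int((mu - 5 * sig) * cfg.fs))
            hi = min(n, int((mu + 5 * sig) * cfg.fs) + 1)
            if lo < hi:
                x[lo:hi] += amps[wave] * np.exp(-0.5 * ((t[lo:hi] - mu) / sig) ** 2)
        r_time += rr
    return x - x.mean()


def _bw(rng, n, fs, fmax):
    t = np.arange(n) / fs
    x = np.zeros(n)
    for _ in range(5):
        f = rng.uniform(0.02, 0.9 * fmax)
        x += rng.uniform(0.1, 0.5) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    walk = np.cumsum(rng.normal(0, 1.0, n)) / np.sqrt(n)
    sos = butter(4, min(0.6 * fmax, 0.45 * fs), btype="low", fs=fs, output="sos")
    x += sosfiltfilt(sos, walk)
    return x


def _ma(rng, n, fs, band):
    sos = butter(4, band, btype="bandpass", fs=fs, output="sos")
    noise = sosfiltfilt(sos, rng.normal(0, 1.0, n))
    # burst envelope: smoothed on/off gating with random activity level
    env_sos = butter(2, 0.8, btype="low", fs=fs, output="sos")
    gate = sosfiltfilt(env_sos, (rng.random(n) < 0.4).astype(float))
    env = np.clip(gate, 0.0, None) ** 2 + 0.05
    return noise * env


def _em(rng, n, fs, steps_per_min):
    x = np.zeros(n)
    n_steps = max(1, rng.poisson(steps_per_min * n / (60 * fs)))
    for _ in range(n_steps):
        pos = rng.integers(0, n)
        x[pos:] += rng.uniform(0.5, 2.0) * rng.choice([-1.0, 1.0])
    # smoothed large spikes resembling QRS-like transients
    t = np.arange(n) / fs
    for _ in range(max(1, n_steps // 2)):
        mu = rng.uniform(0, n / fs)
        sig = rng.uniform(0.02, 0.08)
        x += rng.uniform(1.0, 3.0) * rng.choice([-1.0, 1.0]) * np.exp(
            -0.5 * ((t - mu) / sig) ** 2
        )
    x += 0.05 * rng.normal(0, 1.0, n)
    return x - x.mean()


def synth_artifact(kind: str, n: int, cfg: SynthConfig = None, seed: int | None = None) -> np.ndarray:
    """One artifact channel of length ``n`` samples of the requested class."""
    cfg = cfg or SynthConfig()
    if n < SEGMENT_LENGTH:
        raise ValueError(f"artifact series must have at least {SEGMENT_LENGTH} samples")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    kind = kind.lower()
    if kind == "bw":
        return _bw(rng, n, cfg.fs, cfg.bw_max_hz)
    if kind == "ma":
        return _ma(rng, n, cfg.fs, cfg.ma_band_hz)
    if kind == "em":
        return _em(rng, n, cfg.fs, cfg.em_steps_per_min)
    raise ValueError(f"unknown artifact kind: {kind}")


def _synthetic_split(cfg, role, n_samples, seed):
    series = {
        t: synth_artifact(t, n_samples, cfg, seed=seed + i)
        for i, t in enumerate(("bw", "ma", "em"))
    }
    return NoiseSplit("nv1", role, series)


def make_synthetic_benchmark(
    cfg: SynthConfig = None,
    n_train: int = 2048,
    n_test: int = 256,
    seed: int = 0,
):
    """Fully synthetic train/test pair sets mirroring the RMN benchmark.

    Clean ECG 'records' with per-record heart rates and amplitudes are
    segmented and corrupted exactly as real records would be; train and test
    use artifact series generated from disjoint seeds (the uncorrelated-noise
    contract of the real noise splits).
    """
    cfg = cfg or SynthConfig()
    if min(n_train, n_test) < 1:
        raise ValueError("pair counts must be >= 1")
    rng = np.random.default_rng(seed)
    sets = {}
    for role, count, noise_seed in (
        ("train", n_train, seed * 2 + 1),
        ("test", n_test, seed * 2 + 100_003),
    ):
        split = _synthetic_split(cfg, role, 120_000, noise_seed)
        noisy_l, clean_l, recipes = [], [], []
        while len(noisy_l) < count:
            # one synthetic 'subject': its own rate, amplitude scale and seed
            rec_cfg = SynthConfig(
                duration=90.0,
                heart_rate=float(rng.uniform(55, 95)),
                heart_rate_jitter=float(rng.uniform(1, 5)),
                amp_r=float(rng.uniform(0.8, 1.4)),
                amp_t=float(rng.uniform(0.2, 0.45)),
                seed=int(rng.integers(0, 2 ** 31 - 1)),
            )
            ecg = synth_ecg(rec_cfg)
            for seg in segment_signal(ecg, source_record=f"synth{len(noisy_l)}"):
                recipe = sample_rmn_recipe(rng, split)
                noisy = corrupt_segment(seg, split, recipe)
                clean_l.append(seg.samples)
                noisy_l.append(noisy.samples)
                recipes.append(recipe)
                if len(noisy_l) >= count:
                    break
        sets[role] = PairSet(
            np.stack(noisy_l),
            np.stack(clean_l),
            recipes,
            manifest={"role": role, "seed": seed, "synthetic": True},
        )
    return sets["train"], sets["test"]
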