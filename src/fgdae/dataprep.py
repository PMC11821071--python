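"""Benchmark construction for noise-stress denoising experiments.

The benchmark corrupts clean two-channel ECG records (15-minute, 250 Hz
recordings resampled to 360 Hz) with real ambulatory artifact recordings
(baseline wander, muscle artifact, electrode motion; two channels, 360 Hz).
Pipeline per record channel:

1. resample to 360 Hz,
2. slide a 512-sample window with 256-sample overlap and subtract each
   segment's mean (no amplitude normalization),
3. draw a Random-Mixed-Noise (RMN) recipe per segment — one of the 8
   presence/absence combinations of the three artifact types plus an
   independent uniform amplitude scale in [0.2, 2],
4. add the summed artifact slices, rescaled so the noise peak equals the
   drawn scale times the clean segment's peak.

Noise records are split so that training and testing never share a channel
or a half ("noise split versions" nv1/nv2), keeping the two noise sets
uncorrelated.

File I/O: a minimal reader for WFDB records (.hea header + .dat signal file,
formats 16 and 212, gain/baseline applied to yield physical units) and
two-column CSV; pair sets round-trip through .npz archives with a JSON
manifest entry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.signal import resample_poly

__all__ = [
    "SignalSegment",
    "NoiseRecipe",
    "NoiseSplit",
    "PairSet",
    "TEST_RECORD_IDS",
    "COMBINATION_FLAGS",
    "load_record",
    "write_wfdb_record",
    "resample_signal",
    "segment_signal",
    "make_noise_splits",
    "sample_rmn_recipe",
    "corrupt_segment",
    "build_benchmark",
]

SEGMENT_LENGTH = 512
SEGMENT_OVERLAP = 256
TARGET_FS = 360.0

#: The 14 test-set subject identifiers of the inter-patient split.
TEST_RECORD_IDS = (
    "sel123", "sel233", "sel302", "sel307", "sel820", "sel853",
    "sel16420", "sel16795", "sel0106", "sel0121", "sel32", "sel49",
    "sel14046", "sel15815",
)

#: Combination id (1..8) -> (bw, ma, em) presence flags.
COMBINATION_FLAGS = {
    1: (False, False, False),
    2: (True, False, False),
    3: (False, True, False),
    4: (True, True, False),
    5: (False, False, True),
    6: (True, False, True),
    7: (False, True, True),
    8: (True, True, True),
}

NOISE_TYPES = ("bw", "ma", "em")


@dataclass
class SignalSegment:
    """One 512-sample ECG window in millivolts at 360 Hz."""

    samples: np.ndarray
    fs: float = TARGET_FS
    source_record: str = ""
    channel: int = 0
    start_index: int = 0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (SEGMENT_LENGTH,):
            raise ValueError(f"segment must have exactly {SEGMENT_LENGTH} samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("segment contains non-finite values")


@dataclass
class NoiseRecipe:
    """One RMN draw: which artifact types, how strong, and which noise slices."""

    combination: int
    scale_a: float
    noise_offsets: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        if self.combination not in COMBINATION_FLAGS:
            raise ValueError(f"combination must be 1..8, got {self.combination}")
        if not 0.2 <= self.scale_a <= 2.0:
            raise ValueError(f"scale_a must lie in [0.2, 2], got {self.scale_a}")

    @property
    def flags(self):
        return COMBINATION_FLAGS[self.combination]

    @property
    def active_types(self):
        return tuple(t for t, f in zip(NOISE_TYPES, self.flags) if f)


@dataclass
class NoiseSplit:
    """The artifact series assigned to one role (train or test) of a version."""

    version: str
    role: str
    series: dict

    def __post_init__(self):
        if self.version not in ("nv1", "nv2"):
            raise ValueError("version must be 'nv1' or 'nv2'")
        if self.role not in ("train", "test"):
            raise ValueError("role must be 'train' or 'test'")
        missing = [t for t in NOISE_TYPES if t not in self.series]
        if missing:
            raise ValueError(f"missing noise types: {missing}")


@dataclass
class PairSet:
    """Aligned (noisy, clean, recipe) triples plus a provenance manifest."""

    noisy: np.ndarray
    clean: np.ndarray
    recipes: list
    manifest: dict = field(default_factory=dict)

    def __len__(self):
        return self.noisy.shape[0]

    def __post_init__(self):
        if self.noisy.shape != self.clean.shape:
            raise ValueError("noisy and clean arrays must have identical shapes")
        if self.noisy.shape[0] != len(self.recipes):
            raise ValueError("one recipe per pair is required")

    def triples(self, denoised=None):
        """Iterate (clean, denoised-or-noisy, recipe) for metric evaluation."""
        est = self.noisy if denoised is None else denoised
        for i in range(len(self)):
            yield self.clean[i], est[i], self.recipes[i]

    def save(self, path):
        rec = [
            {"combination": r.combination, "scale_a": r.scale_a,
             "noise_offsets": r.noise_offsets, "seed": r.seed}
            for r in self.recipes
        ]
        np.savez_compressed(
            path,
            noisy=self.noisy,
            clean=self.clean,
            recipes=np.frombuffer(json.dumps(rec).encode(), dtype=np.uint8),
            manifest=np.frombuffer(json.dumps(self.manifest).encode(), dtype=np.uint8),
        )

    @classmethod
    def load(cls, path):
        with np.load(path) as z:
            rec = json.loads(bytes(z["recipes"].tobytes()).decode())
            manifest = json.loads(bytes(z["manifest"].tobytes()).decode())
            recipes = [NoiseRecipe(**r) for r in rec]
            return cls(z["noisy"].copy(), z["clean"].copy(), recipes, manifest)


# ---------------------------------------------------------------------------
# record I/O
# ---------------------------------------------------------------------------


def _parse_header(hea_path: Path):
    lines = [
        ln.strip()
        for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.strip().startswith("#")
    ]
    if not lines:
        raise ValueError(f"{hea_path}: empty WFDB header")
    rec = lines[0].split()
    if len(rec) < 2:
        raise ValueError(f"{hea_path}: malformed record line: {lines[0]!r}")
    name = rec[0].split("/")[0]
    nsig = int(rec[1])
    fs = float(rec[2].split("/")[0]) if len(rec) > 2 else 250.0
    nsamp = int(rec[3]) if len(rec) > 3 else None
    sig_specs = []
    for ln in lines[1 : 1 + nsig]:
        parts = ln.split()
        if len(parts) < 2:
            raise ValueError(f"{hea_path}: malformed signal line: {ln!r}")
        fname = parts[0]
        fmt = parts[1].split("x")[0].split(":")[0].split("+")[0]
        gain, baseline, adc_zero = 200.0, None, 0
        if len(parts) > 2:
            gfield = parts[2].split("/")[0]
            if "(" in gfield:
                gpart, bpart = gfield.split("(")
                gain = float(gpart)
                baseline = int(bpart.rstrip(")"))
            else:
                gain = float(gfield)
        if len(parts) > 4:
            adc_zero = int(float(parts[4]))
        if gain == 0.0:
            gain = 200.0  # WFDB convention for unspecified gain
        if baseline is None:
            baseline = adc_zero
        sig_specs.append({"file": fname, "fmt": fmt, "gain": gain, "baseline": baseline})
    if len(sig_specs) != nsig:
        raise ValueError(f"{hea_path}: expected {nsig} signal lines")
    return name, nsig, fs, nsamp, sig_specs


def _read_dat(path: Path, fmt: str, nsig: int, nsamp):
    raw = path.read_bytes()
    if fmt == "16":
        flat = np.frombuffer(raw, dtype="<i2")
        n = flat.size // nsig
        digital = flat[: n * nsig].reshape(n, nsig)
    elif fmt == "212":
        b = np.frombuffer(raw, dtype=np.uint8)
        b = b[: (b.size // 3) * 3].reshape(-1, 3).astype(np.int32)
        first = ((b[:, 1] & 0x0F) << 8) | b[:, 0]
        second = ((b[:, 1] & 0xF0) << 4) | b[:, 2]
        pairs = np.empty(b.shape[0] * 2, dtype=np.int32)
        pairs[0::2], pairs[1::2] = first, second
        pairs = np.where(pairs > 2047, pairs - 4096, pairs)  # 12-bit two's complement
        n = pairs.size // nsig
        digital = pairs[: n * nsig].reshape(n, nsig)
    else:
        raise ValueError(f"unsupported WFDB signal format: {fmt}")
    if nsamp is not None:
        digital = digital[:nsamp]
    return digital


def load_record(path, format: str | None = None):
    """Read a WFDB record (.hea) or a CSV file.

    Returns ``(signals, fs)`` with ``signals`` of shape (n_samples,
    n_channels) in physical units.  For CSV, pass ``format='CSV'`` or a
    ``.csv`` path; the sampling rate must then be present as an ``# fs=...``
    comment or defaults to 360.
    """
    path = Path(path)
    kind = (format or ("CSV" if path.suffix.lower() == ".csv" else "WFDB")).upper()
    if kind == "CSV":
        fs = TARGET_FS
        for ln in path.read_text().splitlines():
            if ln.startswith("#") and "fs=" in ln:
                fs = float(ln.split("fs=")[1].split()[0])
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        return df.to_numpy(dtype=float), fs
    if kind != "WFDB":
        raise ValueError(f"unknown record format: {format}")
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"missing WFDB header: {hea}")
    name, nsig, fs, nsamp, specs = _parse_header(hea)
    fmts = {s["fmt"] for s in specs}
    files = {s["file"] for s in specs}
    if len(fmts) > 1 or len(files) > 1:
        raise ValueError("multi-file or mixed-format WFDB records are not supported")
    dat = hea.parent / specs[0]["file"]
    if not dat.exists():
        raise FileNotFoundError(f"missing WFDB signal file: {dat}")
    digital = _read_dat(dat, specs[0]["fmt"], nsig, nsamp)
    phys = np.empty(digital.shape, dtype=float)
    for j, s in enumerate(specs):
        phys[:, j] = (digital[:, j] - s["baseline"]) / s["gain"]
    return phys, fs


def write_wfdb_record(path, signals, fs, gain: float = 200.0, units: str = "mV"):
    """Write a (n_samples, n_channels) physical-units array as a format-16
    WFDB record (used for fixtures and export)."""
    path = Path(path)
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if signals.shape[0] < signals.shape[1]:
        raise ValueError("signals must be (n_samples, n_channels)")
    n, nsig = signals.shape
    digital = np.clip(np.round(signals * gain), -32768, 32767).astype("<i2")
    name = path.stem
    lines = [f"{name} {nsig} {fs:g} {n}"]
    for j in range(nsig):
        lines.append(f"{name}.dat 16 {gain:g}(0)/{units} 16 0 {digital[0, j]} 0 0 ch{j}")
    path.with_suffix(".hea").write_text("\n".join(lines) + "\n")
    path.with_suffix(".dat").write_bytes(digital.reshape(-1).tobytes())


# ---------------------------------------------------------------------------
# preparation pipeline
# ---------------------------------------------------------------------------


def resample_signal(x, fs_in: float, fs_out: float = TARGET_FS) -> np.ndarray:
    """Band-limited (polyphase) resampling; identity when the rates match."""
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    x = np.asarray(x, dtype=float)
    if fs_in == fs_out:
        return x.copy()
    ratio = (
        Fraction(fs_out).limit_denominator(10 ** 6)
        / Fraction(fs_in).limit_denominator(10 ** 6)
    ).limit_denominator(1000)
    return resample_poly(x, ratio.numerator, ratio.denominator, axis=0)


def segment_signal(
    x,
    window: int = SEGMENT_LENGTH,
    overlap: int = SEGMENT_OVERLAP,
    subtract_mean: bool = True,
    fs: float = TARGET_FS,
    source_record: str = "",
    channel: int = 0,
):
    """Sliding-window segmentation; trailing partial windows are dropped."""
    if not window > overlap >= 0:
        raise ValueError("window must exceed overlap (both non-negative)")
    x = np.asarray(x, dtype=float)
    stride = window - overlap
    segments = []
    for start in range(0, len(x) - window + 1, stride):
        s = x[start : start + window]
        if subtract_mean:
            s = s - s.mean()
        segments.append(
            SignalSegment(s, fs=fs, source_record=source_record, channel=channel, start_index=start)
        )
    return segments


def make_noise_splits(nstdb_bw, nstdb_ma, nstdb_em, version: str = "nv1"):
    """Assign noise channel-halves to train/test per the split version.

    Each artifact record must be two-channel, shape (n, 2).  Version nv1
    trains on the first half ('a') of channel 1 and tests on the second half
    ('b') of channel 2; nv2 swaps the channels.  Train and test therefore
    never share a channel or a half.
    """
    if version not in ("nv1", "nv2"):
        raise ValueError("version must be 'nv1' or 'nv2'")
    series = {}
    for t, arr in zip(NOISE_TYPES, (nstdb_bw, nstdb_ma, nstdb_em)):
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError(f"{t} noise record must be two-channel (n, 2)")
        series[t] = arr
    train_ch, test_ch = (0, 1) if version == "nv1" else (1, 0)
    train = {t: a[: len(a) // 2, train_ch].copy() for t, a in series.items()}
    test = {t: a[len(a) // 2 :, test_ch].copy() for t, a in series.items()}
    return (
        NoiseSplit(version, "train", train),
        NoiseSplit(version, "test", test),
    )


def sample_rmn_recipe(
    rng: np.random.Generator,
    split: NoiseSplit,
    segment_length: int = SEGMENT_LENGTH,
) -> NoiseRecipe:
    """Draw one RMN recipe: combination, amplitude scale and slice offsets.

    The combination is uniform over the 8 rows, the scale uniform on
    [0.2, 2] and drawn independently; offsets are uniform over the valid
    slice starts of the assigned split.
    """
    combination = int(rng.integers(1, 9))
    scale_a = float(rng.uniform(0.2, 2.0))
    offsets = {}
    for t, flag in zip(NOISE_TYPES, COMBINATION_FLAGS[combination]):
        if flag:
            hi = len(split.series[t]) - segment_length
            if hi < 0:
                raise ValueError(f"{t} noise series shorter than one segment")
            offsets[t] = int(rng.integers(0, hi + 1))
    return NoiseRecipe(combination, scale_a, offsets)


def corrupt_segment(clean: SignalSegment, split: NoiseSplit, recipe: NoiseRecipe) -> SignalSegment:
    """Additively corrupt a clean segment according to the recipe.

    The flagged artifact slices are summed and rescaled as one so that the
    noise peak equals ``scale_a`` times the clean peak; combination 1 returns
    the clean samples unchanged.
    """
    n = len(clean.samples)
    if recipe.combination == 1:
        noisy = clean.samples.copy()
    else:
        combined = np.zeros(n)
        for t in recipe.active_types:
            off = recipe.noise_offsets[t]
            sl = split.series[t][off : off + n]
            if len(sl) != n:
                raise ValueError(f"{t} noise slice at offset {off} is too short")
            combined += sl
        peak_clean = float(np.max(np.abs(clean.samples)))
        peak_noise = float(np.max(np.abs(combined)))
        if peak_clean == 0.0:
            raise ValueError("clean segment has zero amplitude")
        if peak_noise == 0.0:
            raise ValueError("combined noise is identically zero")
        noisy = clean.samples + combined * (recipe.scale_a * peak_clean / peak_noise)
    return SignalSegment(
        noisy,
        fs=clean.fs,
        source_record=clean.source_record,
        channel=clean.channel,
        start_index=clean.start_index,
    )


def build_benchmark(
    qtdb_records: dict,
    noise_records: dict,
    version: str = "nv1",
    seed: int = 0,
    test_ids=None,
):
    """Assemble (noisy, clean, recipe) train/test pair sets.

    ``qtdb_records`` maps record name -> (signals (n, n_ch), fs);
    ``noise_records`` maps 'bw'/'ma'/'em' -> two-channel array at 360 Hz.
    Records named in ``test_ids`` (default: the 14 canonical test subjects)
    form the test set; every other record trains.  Deterministic under seed.
    """
    test_ids = TEST_RECORD_IDS if test_ids is None else tuple(test_ids)
    unknown = [t for t in test_ids if test_ids is not TEST_RECORD_IDS and t not in qtdb_records]
    if unknown:
        raise ValueError(f"unknown test identifiers: {unknown}")
    for t in NOISE_TYPES:
        if t not in noise_records:
            raise ValueError(f"missing noise record: {t}")
    train_split, test_split = make_noise_splits(
        noise_records["bw"], noise_records["ma"], noise_records["em"], version
    )
    rng = np.random.default_rng(seed)
    out = {"train": ([], [], []), "test": ([], [], [])}
    for name in sorted(qtdb_records):
        signals, fs = qtdb_records[name]
        signals = np.atleast_2d(np.asarray(signals, dtype=float))
        if signals.ndim == 2 and signals.shape[0] < signals.shape[1]:
            signals = signals.T
        role = "test" if name in test_ids else "train"
        split = test_split if role == "test" else train_split
        noisy_l, clean_l, recipes = out[role]
        for ch in range(signals.shape[1]):
            x = resample_signal(signals[:, ch], fs, TARGET_FS)
            for seg in segment_signal(x, source_record=name, channel=ch):
                recipe = sample_rmn_recipe(rng, split)
                noisy = corrupt_segment(seg, split, recipe)
                clean_l.append(seg.samples)
                noisy_l.append(noisy.samples)
                recipes.append(recipe)
    sets = {}
    for role, (noisy_l, clean_l, recipes) in out.items():
        if noisy_l:
            noisy = np.stack(noisy_l)
            clean = np.stack(clean_l)
        else:
            noisy = np.empty((0, SEGMENT_LENGTH))
            clean = np.empty((0, SEGMENT_LENGTH))
        sets[role] = PairSet(
            noisy,
            clean,
            recipes,
            manifest={"role": role, "version": version, "seed": seed, "synthetic": False},
        )
    return sets["train"], sets["test"]
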