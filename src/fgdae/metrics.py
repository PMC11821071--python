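"""Signal-quality metrics, stratified reporting and paired significance tests.

Seven per-segment error metrics between a clean reference ``x`` and a
denoised estimate ``xhat`` (all sums over the N samples of the segment):

* SSD — sum of squared distances, in mV^2 * samples (tabulated as mV).
* MAD — maximum absolute distance, mV.
* PRD — percentage root-mean-square difference, with the mean-centered
  denominator sum((x - mean(x))^2), in percent.
* CosSim — cosine similarity of the raw segments, dimensionless.
* RMSE — root mean squared error, mV.
* MAE — mean absolute error, mV.
* SNR — 10 log10(sum(x^2) / sum((x - xhat)^2)), dB.

Stratified reports aggregate mean +/- std per noise-amplitude bin or per
noise-type combination; significance between two methods' per-segment errors
uses the two-sided Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetricsReport",
    "SNR_CAP_DB",
    "compute_metrics",
    "stratified_report",
    "paired_wilcoxon",
    "AMPLITUDE_BINS",
    "COMBINATION_NAMES",
]

#: Reported SNR for a perfect reconstruction (the true value is infinite).
SNR_CAP_DB = 300.0

#: Left-closed amplitude bins; the last bin includes its right edge.
AMPLITUDE_BINS = ((0.2, 0.6), (0.6, 1.0), (1.0, 1.5), (1.5, 2.0))

#: Row order of the noise-type strata (combination ids 1..8).
COMBINATION_NAMES = (
    "Clean", "BW", "MA", "BW+MA", "EM", "BW+EM", "MA+EM", "BW+MA+EM",
)

METRIC_NAMES = ("ssd", "mad", "prd", "cos_sim", "rmse", "mae", "snr")


@dataclass(frozen=True)
class MetricsReport:
    ssd: float
    mad: float
    prd: float
    cos_sim: float
    rmse: float
    mae: float
    snr: float

    def as_dict(self):
        return asdict(self)


def compute_metrics(x, xhat) -> MetricsReport:
    """All seven error metrics for one clean/denoised segment pair."""
    x = np.asarray(x, dtype=float).ravel()
    xhat = np.asarray(xhat, dtype=float).ravel()
    if x.shape != xhat.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {xhat.shape}")
    if x.size < 2:
        raise ValueError("segments must have at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("reference segment contains non-finite values")

    d = x - xhat
    ssd = float(np.sum(d ** 2))
    mad = float(np.max(np.abs(d)))
    mae = float(np.mean(np.abs(d)))
    rmse = float(np.sqrt(np.mean(d ** 2)))

    denom = float(np.sum((x - x.mean()) ** 2))
    if denom == 0.0:
        raise ValueError("PRD is undefined for a constant reference segment")
    prd = float(np.sqrt(ssd / denom) * 100.0)

    nx = float(np.linalg.norm(x))
    nh = float(np.linalg.norm(xhat))
    cos_sim = 0.0 if nx == 0.0 or nh == 0.0 else float(np.dot(x, xhat) / (nx * nh))

    power = float(np.sum(x ** 2))
    snr = SNR_CAP_DB if ssd == 0.0 else float(10.0 * np.log10(power / ssd))
    snr = min(snr, SNR_CAP_DB)

    return MetricsReport(ssd, mad, prd, cos_sim, rmse, mae, snr)


def amplitude_stratum(scale_a: float) -> str:
    """Bin label for a noise amplitude scale; bins are left-closed."""
    for lo, hi in AMPLITUDE_BINS:
        if lo <= scale_a < hi or (hi == AMPLITUDE_BINS[-1][1] and scale_a == hi):
            return f"{lo}to{hi}"
    raise ValueError(f"amplitude scale {scale_a} outside [0.2, 2.0]")


def stratified_report(pairs, mode: str = "amplitude") -> pd.DataFrame:
    """Mean +/- std of each metric per stratum.

    ``pairs`` is an iterable of (clean, denoised, recipe) where the recipe
    carries ``scale_a`` and ``combination``.  ``mode`` is ``"amplitude"``
    (bins over the drawn noise scale) or ``"noise_type"`` (the 8 combination
    rows).  Returns a DataFrame indexed by stratum with columns
    ``<metric>_mean``, ``<metric>_std`` and ``n``.
    """
    if mode not in ("amplitude", "noise_type"):
        raise ValueError(f"unknown stratification mode: {mode}")
    rows = []
    for clean, denoised, recipe in pairs:
        if recipe is None:
            raise ValueError("each pair must carry its corruption recipe")
        rep = compute_metrics(clean, denoised).as_dict()
        if mode == "amplitude":
            rep["stratum"] = amplitude_stratum(recipe.scale_a)
        else:
            rep["stratum"] = COMBINATION_NAMES[recipe.combination - 1]
        rows.append(rep)
    if not rows:
        raise ValueError("no pairs supplied")
    df = pd.DataFrame(rows)
    order = (
        [f"{lo}to{hi}" for lo, hi in AMPLITUDE_BINS]
        if mode == "amplitude"
        else list(COMBINATION_NAMES)
    )
    out = {}
    grouped = df.groupby("stratum")
    for m in METRIC_NAMES:
        agg = grouped[m].agg(["mean", "std", "count"])
        out[f"{m}_mean"] = agg["mean"]
        out[f"{m}_std"] = agg["std"].fillna(0.0)  # singleton stratum -> std 0
    out["n"] = grouped[METRIC_NAMES[0]].count()
    res = pd.DataFrame(out)
    return res.reindex([s for s in order if s in res.index])


def paired_wilcoxon(errors_a, errors_b) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired per-segment errors.

    Zero differences are discarded (the classical convention); if every
    difference is zero the methods are indistinguishable and p is 1.
    """
    a = np.asarray(errors_a, dtype=float).ravel()
    b = np.asarray(errors_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired error vectors must have equal length")
    d = a - b
    if np.all(d == 0):
        return 1.0
    res = stats.wilcoxon(
        a, b, zero_method="wilcox", alternative="two-sided", method="auto"
    )
    return float(res.pvalue)
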