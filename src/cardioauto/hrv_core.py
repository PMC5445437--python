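"""Ectopic-interval filtering and time-/frequency-domain HRV.

The ectopic filter removes inter-beat intervals shortened by more than a
configurable fraction (default 18%) relative to the average of the three
preceding and three following intervals; everything downstream operates on
the surviving normal-to-normal (NN) series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import lombscargle, periodogram

#: Default rodent spectral bands (Hz).
DEFAULT_BANDS = {"lf": (0.20, 0.75), "hf": (0.75, 2.50)}

#: pNN threshold (ms); counts strict ">" exceedances.
PNN_THRESHOLD_MS = 15.0


@dataclass
class NNSeries:
    """Normal-to-normal intervals after ectopic filtering.

    ``times`` holds the end time (ms) of each retained interval so that
    spectral estimation can respect the uneven sampling left by removals.
    """

    intervals: np.ndarray
    times: np.ndarray
    source: str = "ecg"
    n_removed: int = 0
    removal_reasons: list = field(default_factory=list)  # (original index, reason)
    all_removed: bool = False

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class HrvResult:
    RMSSD: float = np.nan
    SDNN: float = np.nan
    CV: float = np.nan
    pNN15: float = np.nan
    LF: float = np.nan
    HF: float = np.nan
    LF_HF: float = np.nan
    mean_RR: float = np.nan
    HR: float = np.nan
    n_beats: int = 0
    low_confidence: bool = False


def filter_ectopic(
    intervals: np.ndarray,
    times: np.ndarray | None = None,
    threshold: float = 0.18,
    min_side: int = 2,
    source: str = "ecg",
) -> NNSeries:
    """Remove intervals shortened by more than ``threshold`` vs. the mean of
    up to 3 neighbors on each side.

    Edge intervals use the neighbors available (at least ``min_side`` per
    side, else the test is skipped for that interval).  Comparison is strict:
    an interval exactly at ``(1 - threshold) * neighbor mean`` survives.
    Order of survivors is preserved.
    """
    x = np.asarray(intervals, dtype=float)
    n = len(x)
    if times is None:
        times = np.cumsum(x)
    times = np.asarray(times, dtype=float)
    keep = np.ones(n, dtype=bool)
    reasons = []
    for i in range(n):
        lo = max(0, i - 3)
        hi = min(n, i + 4)
        nb = np.r_[x[lo:i], x[i + 1:hi]]
        if (i - lo) < min_side or (hi - 1 - i) < min_side:
            continue
        nb_mean = nb.mean()
        # strict inequality on the shortening fraction: exactly-at-threshold survives
        if (nb_mean - x[i]) / nb_mean > threshold:
            keep[i] = False
            reasons.append((i, f"shortened>{threshold:.0%} ({x[i]:.1f} vs mean {nb_mean:.1f} ms)"))
    nn = NNSeries(
        intervals=x[keep],
        times=times[keep],
        source=source,
        n_removed=int(n - keep.sum()),
        removal_reasons=reasons,
        all_removed=bool(n > 0 and keep.sum() == 0),
    )
    return nn


def time_domain(nn: NNSeries) -> HrvResult:
    """Time-domain HRV for one segment.

    SDNN uses the sample (n−1) denominator; CV = SDNN / mean RR; pNN15 is
    the fraction of successive differences strictly exceeding 15 ms.
    """
    x = nn.intervals
    res = HrvResult(n_beats=len(x))
    if len(x) == 0:
        return res
    res.mean_RR = float(np.mean(x))
    res.HR = 60_000.0 / res.mean_RR
    if len(x) >= 2:
        res.SDNN = float(np.std(x, ddof=1))
        res.CV = res.SDNN / res.mean_RR
    if len(x) >= 3:
        d = np.diff(x)
        res.RMSSD = float(np.sqrt(np.mean(d ** 2)))
        res.pNN15 = float(np.mean(np.abs(d) > PNN_THRESHOLD_MS))
    return res


def _band_powers_lomb(t_s, x, bands, oversample=4.0):
    span = t_s[-1] - t_s[0]
    var = float(np.var(x))
    if var == 0.0 or span <= 0:
        return {k: 0.0 for k in bands}
    df = 1.0 / (oversample * span)
    mean_dt = span / (len(x) - 1)
    f_max = max(0.5 / mean_dt, max(hi for _, hi in bands.values()))
    freqs = np.arange(df, f_max + df, df)
    pgram = lombscargle(t_s, x - x.mean(), 2 * np.pi * freqs)
    total = pgram.sum()
    if total <= 0:
        return {k: 0.0 for k in bands}
    scale = var / (total * df)  # Parseval: full-spectrum integral -> variance
    return {
        k: float(pgram[(freqs >= lo) & (freqs < hi)].sum() * df * scale)
        for k, (lo, hi) in bands.items()
    }


def _band_powers_interp(t_s, x, bands, fs=10.0):
    var = float(np.var(x))
    if var == 0.0:
        return {k: 0.0 for k in bands}
    grid = np.arange(t_s[0], t_s[-1], 1.0 / fs)
    xi = CubicSpline(t_s, x)(grid)
    freqs, psd = periodogram(xi - xi.mean(), fs=fs)
    return {
        k: float(np.trapezoid(psd[(freqs >= lo) & (freqs < hi)],
                              freqs[(freqs >= lo) & (freqs < hi)]))
        for k, (lo, hi) in bands.items()
    }


def frequency_domain(
    nn: NNSeries,
    bands: dict[str, tuple[float, float]] | None = None,
    method: str = "lomb",
    min_duration_s: float = 100.0,
    max_removed_frac: float = 0.20,
) -> HrvResult:
    """LF/HF band powers (ms²) of the interval series.

    Default estimator is a Lomb-Scargle periodogram on interval end times
    (robust to beats removed by the ectopic filter), normalized so the
    full-spectrum integral equals the series variance.  A cubic-interpolation
    + periodogram alternative is available as ``method="interp"``.
    A removal fraction above ``max_removed_frac`` flags the result
    low-confidence.
    """
    bands = DEFAULT_BANDS if bands is None else bands
    x = nn.intervals
    res = HrvResult(n_beats=len(x))
    if len(x) < 4:
        return res
    t_s = nn.times / 1000.0
    if (t_s[-1] - t_s[0]) < min_duration_s:
        res.low_confidence = True
    n_orig = len(x) + nn.n_removed
    if n_orig and nn.n_removed / n_orig > max_removed_frac:
        res.low_confidence = True
    if method == "lomb":
        powers = _band_powers_lomb(t_s, x, bands)
    elif method == "interp":
        powers = _band_powers_interp(t_s, x, bands)
    else:
        raise ValueError(f"unknown spectral method {method!r}")
    res.LF = powers.get("lf", np.nan)
    res.HF = powers.get("hf", np.nan)
    res.LF_HF = res.LF / res.HF if res.HF > 0 else np.nan
    res.mean_RR = float(np.mean(x))
    res.HR = 60_000.0 / res.mean_RR
    return res


def analyze_segment(
    intervals,
    times=None,
    source: str = "ecg",
    bands=None,
    method: str = "lomb",
    threshold: float = 0.18,
) -> tuple[NNSeries, HrvResult]:
    """Convenience pipeline: filter, then time- and frequency-domain HRV."""
    nn = filter_ectopic(intervals, times=times, threshold=threshold, source=source)
    td = time_domain(nn)
    fd = frequency_domain(nn, bands=bands, method=method)
    td.LF, td.HF, td.LF_HF = fd.LF, fd.HF, fd.LF_HF
    td.low_confidence = fd.low_confidence
    return nn, td
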