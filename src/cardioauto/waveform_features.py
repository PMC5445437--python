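"""Per-segment ECG morphology and hemodynamic features.

Morphology: PR, QTe (QRS reference to T end), rate-corrected QT
(Fridericia / Bazett against a reference RR), TpTe, ST amplitude, and
minimum ST slope.  Hemodynamics: segment-mean SBP/DBP, pulse pressure,
heart rate, rate-pressure product, and aortic dP/dt_max from the pressure
waveform.  Derivatives use central differences at native sampling with no
smoothing by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beat_io import BeatSeries

#: Default RR normalization (ms) for rodent QT correction.
DEFAULT_RR_REF = 150.0


@dataclass
class WaveformChunk:
    """Uniformly sampled waveform excerpt: ``samples[k]`` at ``t0 + k*dt`` ms."""

    channel: str  # "ecg" | "pressure" | "flow"
    t0: float     # ms
    dt: float     # ms per sample
    samples: np.ndarray

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if len(self.samples) < 2:
            raise ValueError("chunk needs at least 2 samples")

    @property
    def t_end(self) -> float:
        return self.t0 + (len(self.samples) - 1) * self.dt

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.samples)) * self.dt


@dataclass
class MorphologyResult:
    PR: float = np.nan
    QTe: float = np.nan
    QTcF: float = np.nan
    QTcB: float = np.nan
    TpTe: float = np.nan
    ST_amp: float = np.nan
    S_min_slope: float = np.nan


@dataclass
class HemodynamicsResult:
    SBP: float = np.nan
    DBP: float = np.nan
    PP: float = np.nan
    HR: float = np.nan
    dPdt_max: float = np.nan
    rate_pressure: float = np.nan


def qt_correct(qt: float, rr: float, formula: str = "fridericia", rr_ref: float = DEFAULT_RR_REF) -> float:
    """Rate-corrected QT (ms): ``QT / (RR / RR_ref) ** e`` with exponent 1/3
    (Fridericia) or 1/2 (Bazett).  Equals QT at RR = RR_ref."""
    if qt <= 0 or rr <= 0 or rr_ref <= 0:
        raise ValueError("QT, RR and RR_ref must be positive")
    exponent = {"fridericia": 1.0 / 3.0, "bazett": 0.5}.get(formula.lower())
    if exponent is None:
        raise ValueError(f"unknown QT correction formula {formula!r}")
    return qt / (rr / rr_ref) ** exponent


def st_metrics(ecg: WaveformChunk, t_s: float,
               slope_window_ms: float = 1.5,
               amp_window_ms: tuple[float, float] = (2.0, 4.0)) -> tuple[float, float]:
    """(minimum ST slope in mV/ms over ``(t_S, t_S+1.5]``,
    mean ST amplitude in mV over ``[t_S+2, t_S+4]``).

    Requires sampling at 0.5 ms or finer; windows exceeding the chunk are
    reported as NaN.
    """
    if ecg.dt > 0.5:
        raise ValueError("ST metrics need sampling interval <= 0.5 ms")
    t = ecg.times()
    x = ecg.samples
    slope = np.full(len(x), np.nan)
    slope[1:-1] = (x[2:] - x[:-2]) / (2 * ecg.dt)
    tol = 1e-6 * ecg.dt  # float-grid boundary tolerance
    m_slope = (t > t_s + tol) & (t <= t_s + slope_window_ms + tol)
    m_amp = (t >= t_s + amp_window_ms[0] - tol) & (t <= t_s + amp_window_ms[1] + tol)
    if t_s + amp_window_ms[1] > ecg.t_end or t_s < ecg.t0:
        return np.nan, np.nan
    s_min = float(np.nanmin(slope[m_slope])) if m_slope.any() else np.nan
    st_amp = float(np.mean(x[m_amp])) if m_amp.any() else np.nan
    return s_min, st_amp


def dpdt_max(pressure: WaveformChunk, window: tuple[float, float] | None = None) -> float:
    """Maximum first time-derivative of arterial pressure (mmHg/s) over the
    systolic upstroke within ``window`` (ms, defaults to the whole chunk)."""
    t = pressure.times()
    x = pressure.samples
    deriv = np.full(len(x), np.nan)
    deriv[1:-1] = (x[2:] - x[:-2]) / (2 * pressure.dt)  # mmHg/ms
    if window is not None:
        lo, hi = window
        deriv[(t < lo) | (t > hi)] = np.nan
    if np.all(np.isnan(deriv)) or np.nanmax(deriv) <= 0:
        return np.nan  # no upstroke in window
    return float(np.nanmax(deriv) * 1000.0)


def morphology(series: BeatSeries, rr_ref: float = DEFAULT_RR_REF) -> MorphologyResult:
    """Segment-mean ECG intervals from conducted beats with full fiducials.

    QTe is measured from the QRS reference point to T end; TpTe from T peak
    to T end.  QTc is the mean of per-beat corrected values using each
    beat's preceding RR.
    """
    df = series.beats
    cond = df["conducted"].astype(bool) if "conducted" in df.columns else np.ones(len(df), bool)
    sub = df.loc[np.asarray(cond)]
    res = MorphologyResult()
    if len(sub) < 2:
        return res
    t_r = sub["t_R"].to_numpy(float)
    pr = (sub["t_R"] - sub["t_P"]).to_numpy(float)
    qte = (sub["t_Tend"] - sub["t_R"]).to_numpy(float)
    tpte = (sub["t_Tend"] - sub["t_Tpeak"]).to_numpy(float)
    rr_prev = np.r_[np.nan, np.diff(t_r)]
    ok = ~np.isnan(qte) & ~np.isnan(rr_prev) & (rr_prev > 0) & (qte > 0)
    res.PR = float(np.nanmean(pr))
    res.QTe = float(np.nanmean(qte))
    res.TpTe = float(np.nanmean(tpte))
    if ok.any():
        res.QTcF = float(np.mean([qt_correct(q, r, "fridericia", rr_ref) for q, r in zip(qte[ok], rr_prev[ok])]))
        res.QTcB = float(np.mean([qt_correct(q, r, "bazett", rr_ref) for q, r in zip(qte[ok], rr_prev[ok])]))
    return res


def hemodynamics(series: BeatSeries, pressure: WaveformChunk | None = None) -> HemodynamicsResult:
    """Segment-mean pressures and derived indices.

    PP = SBP − DBP; rate-pressure product = HR × SBP / 1000; dP/dt_max is
    computed from the pressure waveform when one is supplied.
    """
    df = series.beats
    res = HemodynamicsResult()
    if "SBP" in df.columns:
        res.SBP = float(df["SBP"].mean())
    if "DBP" in df.columns:
        res.DBP = float(df["DBP"].mean())
    if not np.isnan(res.SBP) and not np.isnan(res.DBP):
        res.PP = res.SBP - res.DBP
    rr = series.rr_intervals()
    if len(rr):
        res.HR = 60_000.0 / float(np.mean(rr))
    if not np.isnan(res.HR) and not np.isnan(res.SBP):
        res.rate_pressure = res.HR * res.SBP / 1000.0
    if pressure is not None:
        res.dPdt_max = dpdt_max(pressure)
    return res
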