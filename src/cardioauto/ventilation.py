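"""Respiratory timing metrics and the pre-arrhythmia ventilatory screen.

Breath tables carry ``t_start < t_insp_end < t_end`` (ms) and an optional
per-breath end-expiratory ``pause`` (s).  Timing metrics are averaged in
10-min windows and then by day.  The screen labels the seconds immediately
preceding an arrhythmia event as apnea, braking, tachypnea, or none, using
explicit configurable thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beat_io import IntegrityError

#: Screen defaults: apnea = gap >= 2 missed expected breaths; braking =
#: instantaneous T_E >= 2x the day's median; tachypnea = instantaneous
#: f >= 1.5x the day's median.
DEFAULT_SCREEN = {"apnea_fold": 2.0, "braking_fold": 2.0, "tachypnea_fold": 1.5}

WINDOW_MS_RESP = 600_000.0


@dataclass
class VentilationSummary:
    T_I: float
    T_E: float
    T_T: float
    f: float          # breaths/min
    pause: float      # s
    n_breaths: int
    window_id: str = ""


def _check_breaths(breaths: pd.DataFrame) -> pd.DataFrame:
    b = breaths.sort_values("t_start").reset_index(drop=True)
    if not ((b["t_start"] < b["t_insp_end"]) & (b["t_insp_end"] < b["t_end"])).all():
        raise IntegrityError("breath phase times out of order")
    overlap = b["t_start"].to_numpy()[1:] < b["t_end"].to_numpy()[:-1]
    if overlap.any():
        raise IntegrityError(f"overlapping breaths at row {int(np.nonzero(overlap)[0][0]) + 1}")
    return b


def breath_timing(breaths: pd.DataFrame) -> pd.DataFrame:
    """Per-breath T_I, T_E, T_T (ms) columns appended; T_I + T_E == T_T."""
    b = breaths.copy()
    b["T_I"] = b["t_insp_end"] - b["t_start"]
    b["T_E"] = b["t_end"] - b["t_insp_end"]
    b["T_T"] = b["T_I"] + b["T_E"]
    return b


def summarize_breaths(
    breaths: pd.DataFrame,
    window_ms: float = WINDOW_MS_RESP,
    min_breaths: int = 5,
) -> list[VentilationSummary]:
    """Window means of T_I/T_E/T_T/f/pause for one animal-day.

    Windows with fewer than ``min_breaths`` breaths are dropped (missing,
    not zero).  ``f`` is 60000 / mean T_T.
    """
    if len(breaths) == 0:
        return []
    b = breath_timing(_check_breaths(breaths))
    k = (b["t_start"] // window_ms).astype(int)
    out = []
    for w, sub in b.groupby(k):
        if len(sub) < min_breaths:
            continue
        t_t = float(sub["T_T"].mean())
        out.append(
            VentilationSummary(
                T_I=float(sub["T_I"].mean()),
                T_E=float(sub["T_E"].mean()),
                T_T=t_t,
                f=60_000.0 / t_t,
                pause=float(sub["pause"].mean()) if "pause" in sub.columns else np.nan,
                n_breaths=len(sub),
                window_id=f"w{int(w):03d}",
            )
        )
    return out


def daily_means(breaths: pd.DataFrame, window_ms: float = WINDOW_MS_RESP,
                min_breaths: int = 5) -> pd.DataFrame:
    """Daily averages of the window means, per animal and day."""
    rows = []
    for (animal, day), sub in breaths.groupby(["animal_id", "day_label"], sort=False):
        wins = summarize_breaths(sub, window_ms=window_ms, min_breaths=min_breaths)
        if not wins:
            continue
        rows.append({
            "animal_id": str(animal), "day_label": str(day),
            "T_I": np.mean([w.T_I for w in wins]),
            "T_E": np.mean([w.T_E for w in wins]),
            "T_T": np.mean([w.T_T for w in wins]),
            "f": np.mean([w.f for w in wins]),
            "pause": np.mean([w.pause for w in wins]),
            "n_windows": len(wins),
        })
    return pd.DataFrame(rows)


def pre_event_screen(
    breaths: pd.DataFrame,
    event_time_ms: float,
    lookback_ms: float = 3000.0,
    thresholds: dict | None = None,
) -> str:
    """Label the ventilatory pattern in the ``lookback_ms`` before an event.

    Returns one of ``"apnea"``, ``"braking"``, ``"tachypnea"``, ``"none"``,
    or ``"unscreened"`` when breaths do not cover the lookback window.
    Reference medians (T_T, T_E) come from the full day's breaths.
    """
    th = {**DEFAULT_SCREEN, **(thresholds or {})}
    b = breath_timing(_check_breaths(breaths))
    if len(b) == 0 or b["t_start"].min() > event_time_ms - lookback_ms or b["t_end"].max() < event_time_ms - lookback_ms:
        return "unscreened"
    med_tt = float(b["T_T"].median())
    med_te = float(b["T_E"].median())
    win_lo = event_time_ms - lookback_ms
    in_win = b[(b["t_end"] > win_lo) & (b["t_start"] < event_time_ms)]

    # apnea: a breathless gap >= apnea_fold expected breath durations
    edges = np.r_[win_lo, in_win["t_start"].to_numpy(float), event_time_ms] if len(in_win) else np.array([win_lo, event_time_ms])
    ends = np.r_[win_lo, in_win["t_end"].to_numpy(float)] if len(in_win) else np.array([win_lo])
    gaps = edges[1:] - np.maximum.accumulate(ends)[: len(edges) - 1]
    if np.max(gaps, initial=0.0) >= th["apnea_fold"] * med_tt:
        return "apnea"
    if len(in_win) and (in_win["T_E"].max() >= th["braking_fold"] * med_te):
        return "braking"
    if len(in_win) and (in_win["T_T"].min() <= med_tt / th["tachypnea_fold"]):
        return "tachypnea"
    return "none"


def screen_events(
    breaths: pd.DataFrame,
    events: pd.DataFrame,
    lookback_ms: float = 3000.0,
    thresholds: dict | None = None,
) -> pd.DataFrame:
    """Screen every event row (columns ``animal_id``, ``day_label``,
    ``t_event``) against the matching animal-day breath records."""
    rows = []
    b = breaths.copy()
    b["animal_id"] = b["animal_id"].astype(str)
    b["day_label"] = b["day_label"].astype(str)
    for _, e in events.iterrows():
        day = b[(b["animal_id"] == str(e["animal_id"])) & (b["day_label"] == str(e["day_label"]))]
        label = pre_event_screen(day, float(e["t_event"]), lookback_ms=lookback_ms, thresholds=thresholds) if len(day) else "unscreened"
        rows.append({**e, "screen": label})
    return pd.DataFrame(rows)
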