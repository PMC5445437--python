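"""Beat/breath table I/O and segmentation into analysis windows.

Canonical on-disk form is a flat CSV with one row per beat.  All times are
milliseconds from recording start; beat indices are 0-based; analysis windows
are half-open ``[start, end)``.

Two input modes are supported:

- ``ecg``: per-beat ECG fiducials (``t_P``, ``t_R``, ``t_S``, ``t_Tpeak``,
  ``t_Tend``) plus per-beat arterial pressures;
- ``pulse``: inter-beat intervals derived from systolic-peak times (``t_sys``
  column) when ECG fiducials are unavailable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Columns of beats.csv.  Empty cell = missing.
BEAT_COLUMNS = [
    "animal_id", "group", "day_label", "segment_id",
    "t_P", "t_R", "t_S", "t_Tpeak", "t_Tend", "conducted", "SBP", "DBP",
]

#: Columns of breaths.csv.
BREATH_COLUMNS = [
    "animal_id", "day_label", "t_start", "t_insp_end", "t_end", "pause",
]

#: Analysis-window lengths in ms by window kind.
WINDOW_MS = {"ecg_5min": 300_000.0, "resp_10min": 600_000.0}


class SchemaError(ValueError):
    """A required column is absent or of the wrong kind."""


class IntegrityError(ValueError):
    """A beat-series invariant is violated (e.g. non-monotone beat times)."""


@dataclass
class BeatSeries:
    """Time-ordered per-beat annotations for one animal on one day/segment.

    ``beats`` holds one row per beat.  Conducted beats carry a ``t_R``; a
    non-conducted P wave has ``conducted == False`` and missing QRS/T
    fiducials.  In pulse mode ``t_sys`` (systolic peak time) substitutes for
    the ECG reference point.
    """

    beats: pd.DataFrame
    animal_id: str
    day_label: str
    group: str = ""
    segment_id: str = ""
    source: str = "ecg"  # "ecg" | "pulse"

    def __len__(self) -> int:
        return len(self.beats)

    @property
    def reference_times(self) -> np.ndarray:
        """Per-beat anchor time in ms: ``t_R`` (or ``t_sys`` in pulse mode),
        falling back to ``t_P`` for non-conducted beats."""
        col = "t_sys" if self.source == "pulse" else "t_R"
        t = self.beats[col].to_numpy(float)
        if "t_P" in self.beats.columns:
            t = np.where(np.isnan(t), self.beats["t_P"].to_numpy(float), t)
        return t

    def rr_intervals(self) -> np.ndarray:
        """Inter-beat intervals (ms) between successive conducted beats
        (successive systolic peaks in pulse mode)."""
        col = "t_sys" if self.source == "pulse" else "t_R"
        t = self.beats[col].to_numpy(float)
        t = t[~np.isnan(t)]
        return np.diff(t)

    def nn_candidates(self) -> tuple[np.ndarray, np.ndarray]:
        """(intervals, end times) between successive conducted beats,
        excluding intervals that span a non-conducted annotation (AV-block
        pauses are not normal-to-normal intervals)."""
        df = self.beats
        col = "t_sys" if self.source == "pulse" else "t_R"
        t = df[col].to_numpy(float)
        rows = np.nonzero(~np.isnan(t))[0]
        tv = t[rows]
        if "conducted" in df.columns:
            noncond = np.nonzero(~df["conducted"].astype(bool).to_numpy())[0]
        else:
            noncond = np.array([], dtype=int)
        rr = np.diff(tv)
        if len(noncond):
            spans = np.array([
                np.any((noncond > rows[k]) & (noncond < rows[k + 1]))
                for k in range(len(rr))
            ])
        else:
            spans = np.zeros(len(rr), dtype=bool)
        return rr[~spans], tv[1:][~spans]

    def rr_times(self) -> np.ndarray:
        """End time (ms) of each interval returned by :meth:`rr_intervals`."""
        col = "t_sys" if self.source == "pulse" else "t_R"
        t = self.beats[col].to_numpy(float)
        t = t[~np.isnan(t)]
        return t[1:]

    def validate(self) -> None:
        t = self.beats["t_sys" if self.source == "pulse" else "t_R"].to_numpy(float)
        finite = t[~np.isnan(t)]
        bad = np.nonzero(np.diff(finite) <= 0)[0]
        if bad.size:
            # map back to the row of the offending (second) beat
            idx = np.nonzero(~np.isnan(t))[0][bad[0] + 1]
            raise IntegrityError(
                f"beat times not strictly increasing at row {idx} "
                f"(animal={self.animal_id}, day={self.day_label})"
            )
        if {"SBP", "DBP"} <= set(self.beats.columns):
            sbp = self.beats["SBP"].to_numpy(float)
            dbp = self.beats["DBP"].to_numpy(float)
            both = ~np.isnan(sbp) & ~np.isnan(dbp)
            if np.any(sbp[both] <= dbp[both]):
                row = int(np.nonzero(both)[0][np.nonzero(sbp[both] <= dbp[both])[0][0]])
                raise IntegrityError(f"SBP <= DBP at row {row}")


@dataclass(frozen=True)
class SegmentIndex:
    """One half-open analysis window ``[start, end)`` within a recording."""

    segment_id: str
    animal_id: str
    day_label: str
    start: float
    end: float
    window_kind: str
    partial: bool = False


def read_beat_table(path, pulse_mode: bool = False) -> list[BeatSeries]:
    """Read beats.csv into validated :class:`BeatSeries`, grouped by
    animal/day(/segment).

    Missing annotations are preserved as NaN, never coerced to zero.  In
    ``pulse_mode`` the ``t_sys`` column is required instead of the ECG
    fiducials.
    """
    df = pd.read_csv(path)
    required = {"animal_id", "day_label"}
    required |= {"t_sys"} if pulse_mode else {"t_R"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"missing required column(s): {sorted(missing)}")
    tcol = "t_sys" if pulse_mode else "t_R"
    if not pd.api.types.is_numeric_dtype(df[tcol]):
        raise SchemaError(f"column {tcol!r} must be numeric")
    if "conducted" in df.columns:
        df["conducted"] = df["conducted"].astype(float).fillna(1.0).astype(bool)
    out = []
    keys = [k for k in ("animal_id", "day_label", "segment_id") if k in df.columns]
    for key, sub in df.groupby(keys, sort=False, dropna=False):
        key = key if isinstance(key, tuple) else (key,)
        meta = dict(zip(keys, key))
        sub = sub.reset_index(drop=True)
        series = BeatSeries(
            beats=sub,
            animal_id=str(meta["animal_id"]),
            day_label=str(meta["day_label"]),
            group=str(sub["group"].iloc[0]) if "group" in sub.columns else "",
            segment_id=str(meta.get("segment_id", "") or ""),
            source="pulse" if pulse_mode else "ecg",
        )
        series.validate()
        out.append(series)
    return out


def write_beat_table(series_list: list[BeatSeries], path) -> None:
    """Write a collection of series back to a flat CSV (round-trips
    :func:`read_beat_table` field-for-field)."""
    frames = []
    for s in series_list:
        df = s.beats.copy()
        df["animal_id"] = s.animal_id
        df["day_label"] = s.day_label
        if s.group:
            df["group"] = s.group
        if s.segment_id:
            df["segment_id"] = s.segment_id
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_breath_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"animal_id", "day_label", "t_start", "t_insp_end", "t_end"} - set(df.columns)
    if missing:
        raise SchemaError(f"missing required column(s): {sorted(missing)}")
    bad = ~((df["t_start"] < df["t_insp_end"]) & (df["t_insp_end"] < df["t_end"]))
    if bad.any():
        raise IntegrityError(f"breath timing invariant violated at row {int(np.nonzero(bad.to_numpy())[0][0])}")
    return df


def segment(
    series: BeatSeries,
    window_kind: str = "ecg_5min",
    window_ms: float | None = None,
    end_tolerance_ms: float = 2000.0,
    min_beats: int = 0,
) -> list[tuple[SegmentIndex, BeatSeries]]:
    """Cut one recording into contiguous half-open windows.

    Windows start at t=0 (recording start).  The trailing window is flagged
    ``partial`` unless the last beat reaches within ``end_tolerance_ms`` of
    the window end; partial windows are returned but downstream analyses
    exclude them by default.  ``min_beats`` drops windows with too few beats
    (recording dropouts); a window below the threshold is flagged partial.
    """
    if window_ms is None:
        window_ms = WINDOW_MS[window_kind]
    if len(series) == 0:
        return []
    t = series.reference_times
    t_last = float(np.nanmax(t))
    n_windows = max(1, math.ceil((t_last + 1e-9) / window_ms))
    out = []
    for k in range(n_windows):
        start, end = k * window_ms, (k + 1) * window_ms
        mask = (t >= start) & (t < end)
        sub = series.beats.loc[mask].reset_index(drop=True)
        partial = (t_last < end - end_tolerance_ms) or (min_beats and len(sub) < min_beats)
        idx = SegmentIndex(
            segment_id=f"{series.animal_id}_{series.day_label}_w{k:03d}",
            animal_id=series.animal_id,
            day_label=series.day_label,
            start=start,
            end=end,
            window_kind=window_kind,
            partial=bool(partial),
        )
        out.append((idx, replace(series, beats=sub, segment_id=idx.segment_id)))
    return out
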