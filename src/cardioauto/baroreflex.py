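"""Spontaneous baroreflex sensitivity by the sequence method.

Systolic pressure of beat *i* is paired with the subsequent inter-beat
interval (*i* → *i+1*, configurable lag).  Maximal monotone runs of at least
``min_len`` beats in which every SBP step is at least ``min_dsbp`` mmHg and
every interval step at least ``min_drr`` ms in the same direction are fitted
by least squares; runs whose interval-on-SBP correlation falls below
``min_r`` are rejected.  The segment estimate is the unweighted mean of
accepted sequence slopes (up- and down-sequences pooled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class BrsSequence:
    beat_indices: np.ndarray  # indices into the SBP series
    direction: str            # "up" | "down"
    slope: float              # ms/mmHg
    r: float
    accepted: bool


@dataclass
class BrsEstimate:
    slope: float        # ms/mmHg; NaN when no sequences qualified
    n_sequences: int
    n_up: int
    n_down: int
    segment_id: str = ""

    @property
    def defined(self) -> bool:
        return self.n_sequences >= 1


def find_sequences(
    sbp,
    intervals,
    min_len: int = 3,
    min_dsbp: float = 0.50,
    min_drr: float = 0.30,
    min_r: float = 0.50,
    lag: int = 1,
    break_on_ties: bool = True,
) -> list[BrsSequence]:
    """Locate baroreflex sequences in paired SBP / interval beat series.

    ``sbp[i]`` pairs with ``intervals[i + lag - 1]``, i.e. at the default
    lag of 1 the interval immediately following systolic peak *i*.  Ectopic
    beats must already be excluded.  Ties (steps below threshold or opposite
    sign) break a run; runs are maximal, not enumerated sub-sequences.
    """
    sbp = np.asarray(sbp, dtype=float)
    rr = np.asarray(intervals, dtype=float)
    offset = lag - 1
    n = min(len(sbp), len(rr) - offset)
    if n < min_len:
        return []
    s = sbp[:n]
    y = rr[offset:offset + n]
    ds = np.diff(s)
    dy = np.diff(y)
    up = (ds >= min_dsbp) & (dy >= min_drr)
    down = (ds <= -min_dsbp) & (dy <= -min_drr)
    if not break_on_ties:
        # zero-SBP steps tolerated inside a run if the interval keeps moving
        up |= (np.abs(ds) < min_dsbp) & (dy >= min_drr)
        down |= (np.abs(ds) < min_dsbp) & (dy <= -min_drr)

    sequences: list[BrsSequence] = []

    def flush(start: int, stop: int, direction: str) -> None:
        # run of steps [start, stop) -> beats start..stop inclusive
        length = stop - start + 1
        if length < min_len:
            return
        idx = np.arange(start, stop + 1)
        slope, _, r, _, _ = stats.linregress(s[idx], y[idx])
        sequences.append(
            BrsSequence(
                beat_indices=idx,
                direction=direction,
                slope=float(slope),
                r=float(r),
                accepted=bool(r >= min_r),
            )
        )

    run_start, run_dir = None, None
    for i in range(len(ds)):
        step_dir = "up" if up[i] else ("down" if down[i] else None)
        if step_dir == run_dir and run_dir is not None:
            continue
        if run_dir is not None:
            flush(run_start, i, run_dir)
        run_start, run_dir = i, step_dir
        if step_dir is None:
            run_start = run_dir = None
    if run_dir is not None:
        flush(run_start, len(ds), run_dir)
    return sequences


def estimate_brs(sequences: list[BrsSequence], segment_id: str = "") -> BrsEstimate:
    """Mean slope over accepted sequences; undefined when none qualify."""
    acc = [q for q in sequences if q.accepted]
    n_up = sum(q.direction == "up" for q in acc)
    n_down = sum(q.direction == "down" for q in acc)
    slope = float(np.mean([q.slope for q in acc])) if acc else float("nan")
    return BrsEstimate(
        slope=slope, n_sequences=len(acc), n_up=n_up, n_down=n_down,
        segment_id=segment_id,
    )


def brs_for_segment(sbp, intervals, segment_id: str = "", **kwargs) -> BrsEstimate:
    return estimate_brs(find_sequences(sbp, intervals, **kwargs), segment_id=segment_id)
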