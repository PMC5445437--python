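"""Rule-based classification of conduction and ectopy events.

Two families of rules operate on annotated beat streams:

- atrial premature beats (APB): conducted beats whose RR is >18% shorter
  than the mean of the neighboring 6 RRs, with a normal PR;
- non-conducted P waves, cascaded into ncAPB, second-degree AV block
  Mobitz I / Mobitz II, or advanced AV block.

"Normal PR" and "PR prolongation" are calibrated per animal from its
baseline day (mean ± 2 SD); the local baseline RR for fold-increase tests
is the median of the prior 4 conducted RRs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .beat_io import BeatSeries

EVENT_TYPES = ("APB", "ncAPB", "MobitzI", "MobitzII", "AdvancedAVB")

#: Exposure days audited for APBs (half of days, selected at random upstream).
DEFAULT_APB_AUDIT_DAYS = ("baseline", "1", "4", "6", "8", "11", "12")


@dataclass(frozen=True)
class PrCalibration:
    """Per-animal PR normal band from the baseline day: mean ± ``n_sd`` SD."""

    mean: float
    sd: float
    n_sd: float = 2.0

    def is_normal(self, pr: float) -> bool:
        return abs(pr - self.mean) <= self.n_sd * self.sd

    @property
    def prolongation_ms(self) -> float:
        """Total PR increase over 4 beats that counts as prolongation."""
        return self.n_sd * self.sd


@dataclass
class ArrhythmiaEvent:
    type: str
    anchor_index: int
    animal_id: str
    day_label: str
    evidence: dict = field(default_factory=dict)
    t_event: float = float("nan")  # ms; t_R for APB, t_P for non-conducted P


def calibrate_pr(baseline_series: list[BeatSeries] | BeatSeries, n_sd: float = 2.0) -> PrCalibration:
    """PR normal band from an animal's baseline-day conducted beats."""
    if isinstance(baseline_series, BeatSeries):
        baseline_series = [baseline_series]
    prs = []
    for s in baseline_series:
        df = s.beats
        mask = df["conducted"].astype(bool) if "conducted" in df.columns else np.ones(len(df), bool)
        pr = (df["t_R"] - df["t_P"]).to_numpy(float)[np.asarray(mask)]
        prs.append(pr[~np.isnan(pr)])
    pr = np.concatenate(prs) if prs else np.array([])
    if len(pr) < 2:
        raise ValueError("insufficient conducted beats with PR to calibrate")
    return PrCalibration(mean=float(pr.mean()), sd=float(pr.std(ddof=1)), n_sd=n_sd)


def _conducted_frame(series: BeatSeries) -> pd.DataFrame:
    df = series.beats
    mask = df["conducted"].astype(bool) if "conducted" in df.columns else pd.Series(True, index=df.index)
    sub = df.loc[np.asarray(mask)].copy()
    sub["row"] = np.nonzero(np.asarray(mask))[0]
    return sub


def detect_apb(
    series: BeatSeries,
    cal: PrCalibration,
    threshold: float = 0.18,
    audit: list | None = None,
) -> list[ArrhythmiaEvent]:
    """Flag conducted beats with >``threshold`` RR shortening vs. the
    neighboring 6 RRs and a normal PR.

    RRs spanning a non-conducted beat (block pauses) are excluded both as
    candidates and from neighbor averages, so AV-block pauses do not fake
    prematurity in adjacent normal beats.  Beats with missing PR are skipped
    with an audit note.
    """
    cond = _conducted_frame(series)
    t_r = cond["t_R"].to_numpy(float)
    rows = cond["row"].to_numpy(int)
    pr = (cond["t_R"] - cond["t_P"]).to_numpy(float)
    rr = np.diff(t_r)
    # interval k (between conducted beats k and k+1) spans a block if any
    # non-conducted row lies between their original rows
    noncond_rows = np.setdiff1d(np.arange(len(series)), rows)
    spans_block = np.array([
        np.any((noncond_rows > rows[k]) & (noncond_rows < rows[k + 1]))
        for k in range(len(rr))
    ]) if len(noncond_rows) else np.zeros(len(rr), bool)

    events = []
    valid = np.nonzero(~spans_block)[0]
    pos = {k: j for j, k in enumerate(valid)}  # interval index -> rank among valid
    for k in valid:
        j = pos[k]
        nb_idx = np.r_[valid[max(0, j - 3):j], valid[j + 1:j + 4]]
        if (j - max(0, j - 3)) < 3 or (len(valid[j + 1:j + 4])) < 3:
            continue
        nb_mean = rr[nb_idx].mean()
        if (nb_mean - rr[k]) / nb_mean <= threshold:  # strict > required
            continue
        beat_pr = pr[k + 1]  # PR of the premature (second) beat of interval k
        if np.isnan(beat_pr):
            if audit is not None:
                audit.append((rows[k + 1], "APB candidate skipped: PR missing"))
            continue
        if not cal.is_normal(beat_pr):
            continue
        events.append(
            ArrhythmiaEvent(
                type="APB",
                anchor_index=int(rows[k + 1]),
                animal_id=series.animal_id,
                day_label=series.day_label,
                t_event=float(t_r[k + 1]),
                evidence={
                    "rr_ms": float(rr[k]),
                    "neighbor_mean_rr_ms": float(nb_mean),
                    "rr_ratio": float(rr[k] / nb_mean),
                    "pr_ms": float(beat_pr),
                },
            )
        )
    return events


def classify_nonconducted_P(
    series: BeatSeries,
    i: int,
    cal: PrCalibration,
    threshold: float = 0.18,
    rr_fold_mobitz: float = 2.0,
    rr_fold_advanced: float = 3.0,
    audit: list | None = None,
) -> ArrhythmiaEvent | None:
    """Classify the non-conducted P wave at row ``i``.

    Decision cascade: premature P (PP < (1−threshold) × mean of prior 4
    PPs) → ncAPB; on-time P with RR across the block ≥ ``rr_fold_mobitz`` ×
    local baseline and PR prolongation over the prior 4 conducted beats or a
    shortened first post-block PR → Mobitz I; un-prolonged prior PRs with a
    normal first post-block PR → Mobitz II (RR fold in [2, 3)) or advanced
    AV block (RR fold ≥ 3).  Returns ``None`` (with an audit note) when the
    context needed by the rules is unavailable or no rule fires.
    """
    df = series.beats
    if bool(df["conducted"].iloc[i]):
        raise ValueError(f"beat {i} is conducted")

    def note(msg):
        if audit is not None:
            audit.append((i, msg))
        return None

    t_p = df["t_P"].to_numpy(float)
    prior_p = t_p[:i][~np.isnan(t_p[:i])]
    if len(prior_p) < 5 or np.isnan(t_p[i]):
        return note("unclassifiable: fewer than 5 prior P waves")
    pp = t_p[i] - prior_p[-1]
    prior_pps = np.diff(prior_p[-5:])
    pp_ratio = pp / prior_pps.mean()
    ev = {"pp_ms": float(pp), "pp_ratio": float(pp_ratio)}

    t_event = float(t_p[i])
    if pp_ratio < 1.0 - threshold:
        return ArrhythmiaEvent("ncAPB", i, series.animal_id, series.day_label, ev, t_event)
    if abs(pp_ratio - 1.0) > threshold:
        return note(f"unclassifiable: P neither premature nor on time (ratio {pp_ratio:.2f})")

    cond = _conducted_frame(series)
    prior = cond[cond["row"] < i]
    after = cond[cond["row"] > i]
    if len(prior) < 5 or len(after) < 1:
        return note("unclassifiable: fewer than 4 prior conducted RRs or no beat after block")
    t_prior = prior["t_R"].to_numpy(float)
    rr_block = float(after["t_R"].iloc[0] - t_prior[-1])
    baseline_rr = float(np.median(np.diff(t_prior[-5:])))
    rr_fold = rr_block / baseline_rr
    prior_prs = (prior["t_R"] - prior["t_P"]).to_numpy(float)[-4:]
    post_pr = float(after["t_R"].iloc[0] - after["t_P"].iloc[0])
    ev.update(
        rr_block_ms=rr_block, baseline_rr_ms=baseline_rr, rr_fold=float(rr_fold),
        prior_prs_ms=[float(v) for v in prior_prs], post_pr_ms=post_pr,
    )
    if np.any(np.isnan(prior_prs)) or np.isnan(post_pr):
        return note("unclassifiable: PR missing around block")
    if rr_fold < rr_fold_mobitz:
        return note(f"unclassifiable: RR across block only {rr_fold:.2f}x baseline")

    pr_increase = float(prior_prs[-1] - prior_prs[0])
    prolonged = bool(np.all(np.diff(prior_prs) >= 0) and pr_increase > cal.prolongation_ms)
    post_shortened = bool(post_pr < prior_prs.min())
    ev.update(pr_trend_increase_ms=pr_increase, pr_prolonged=prolonged,
              post_pr_shortened=post_shortened)
    if prolonged or post_shortened:
        return ArrhythmiaEvent("MobitzI", i, series.animal_id, series.day_label, ev, t_event)
    if cal.is_normal(post_pr):
        kind = "AdvancedAVB" if rr_fold >= rr_fold_advanced else "MobitzII"
        return ArrhythmiaEvent(kind, i, series.animal_id, series.day_label, ev, t_event)
    return note("unclassifiable: post-block PR abnormal without prolongation pattern")


def detect_events(
    series: BeatSeries,
    cal: PrCalibration,
    threshold: float = 0.18,
) -> tuple[list[ArrhythmiaEvent], list]:
    """Run the APB rule and the non-conducted-P cascade over one series."""
    audit: list = []
    events = detect_apb(series, cal, threshold=threshold, audit=audit)
    cond = series.beats["conducted"].astype(bool).to_numpy()
    for i in np.nonzero(~cond)[0]:
        ev = classify_nonconducted_P(series, int(i), cal, threshold=threshold, audit=audit)
        if ev is not None:
            events.append(ev)
    events.sort(key=lambda e: e.anchor_index)
    return events, audit


def count_events(
    events: list[ArrhythmiaEvent],
    design: pd.DataFrame,
    apb_audit_days: tuple[str, ...] = DEFAULT_APB_AUDIT_DAYS,
) -> pd.DataFrame:
    """Per-animal, per-day event counts.

    ``design`` must list the analyzed (animal_id, day_label) pairs; days with
    no analyzed segments are absent from the output, not zero.  APB counts
    are restricted to the audit-day subset.
    """
    rows = []
    for _, d in design[["animal_id", "day_label"]].drop_duplicates().iterrows():
        rec = {"animal_id": str(d["animal_id"]), "day_label": str(d["day_label"])}
        for t in EVENT_TYPES:
            if t == "APB" and rec["day_label"] not in apb_audit_days:
                rec[t] = np.nan
                continue
            rec[t] = sum(
                1 for e in events
                if e.type == t and e.animal_id == rec["animal_id"]
                and e.day_label == rec["day_label"]
            )
        rows.append(rec)
    return pd.DataFrame(rows)
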