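"""End-to-end glue: run the per-segment analyses over a study and build
the delta/effects tables.  Used by the CLI and by the determinism checks."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import arrhythmia, baroreflex, hrv_core, study_stats, ventilation, waveform_features
from .beat_io import BeatSeries, segment


def analyze_segments(beats: list[BeatSeries], window_kind: str = "ecg_5min",
                     window_ms: float | None = None,
                     bands: dict | None = None, method: str = "lomb") -> pd.DataFrame:
    """Per-segment HRV, BRS, morphology and hemodynamics for every full
    analysis window of every series."""
    rows = []
    for series in beats:
        for idx, sub in segment(series, window_kind, window_ms=window_ms):
            if idx.partial or len(sub) < 8:
                continue
            rr, rr_t = sub.nn_candidates()
            nn, hrv = hrv_core.analyze_segment(rr, times=rr_t, source=sub.source,
                                               bands=bands, method=method)
            cond = sub.beats[sub.beats["conducted"].astype(bool)] if "conducted" in sub.beats.columns else sub.beats
            sbp = cond["SBP"].to_numpy(float) if "SBP" in cond.columns else np.array([])
            brs = baroreflex.brs_for_segment(sbp[:-1], rr, segment_id=idx.segment_id) \
                if len(sbp) > 3 else baroreflex.BrsEstimate(np.nan, 0, 0, 0, idx.segment_id)
            morph = waveform_features.morphology(sub)
            hemo = waveform_features.hemodynamics(sub)
            rows.append({
                "animal_id": idx.animal_id, "group": series.group,
                "day_label": idx.day_label, "segment_id": idx.segment_id,
                "RMSSD": hrv.RMSSD, "SDNN": hrv.SDNN, "CV": hrv.CV,
                "pNN15": hrv.pNN15, "LF": hrv.LF, "HF": hrv.HF,
                "LF_HF": hrv.LF_HF, "HR": hrv.HR, "mean_RR": hrv.mean_RR,
                "BRS": brs.slope if brs.defined else np.nan,
                "n_brs_sequences": brs.n_sequences,
                "PR": morph.PR, "QTe": morph.QTe, "QTcF": morph.QTcF,
                "QTcB": morph.QTcB, "TpTe": morph.TpTe,
                "SBP": hemo.SBP, "DBP": hemo.DBP, "PP": hemo.PP,
                "rate_pressure": hemo.rate_pressure,
            })
    return pd.DataFrame(rows)


def detect_arrhythmias(beats: list[BeatSeries], design: pd.DataFrame,
                       apb_audit_days=arrhythmia.DEFAULT_APB_AUDIT_DAYS):
    """Calibrate PR per animal on its baseline day, then classify events
    and build daily counts."""
    by_animal: dict[str, list[BeatSeries]] = {}
    for s in beats:
        by_animal.setdefault(s.animal_id, []).append(s)
    events, audits = [], []
    for animal, series_list in by_animal.items():
        baseline = [s for s in series_list if s.day_label == "baseline"]
        if not baseline:
            continue
        cal = arrhythmia.calibrate_pr(baseline)
        for s in series_list:
            ev, audit = arrhythmia.detect_events(s, cal)
            events.extend(ev)
            audits.extend((s.animal_id, s.day_label, *a) for a in audit)
    counts = arrhythmia.count_events(events, design, apb_audit_days=apb_audit_days)
    return events, counts, audits


def run_study(study: dict, window_ms: float | None = None) -> dict:
    """Analyze a generated/ingested study end to end.

    Returns per-segment results, arrhythmia events and counts, daily
    ventilation summaries, the delta table, and overall LMM effect
    estimates for the core endpoints.
    """
    seg = analyze_segments(study["beats"], window_ms=window_ms)
    events, counts, _ = detect_arrhythmias(study["beats"], study["design"])
    vent = ventilation.daily_means(study["breaths"])
    endpoints = ["RMSSD", "SDNN", "CV", "BRS", "SBP", "DBP", "PP", "PR", "QTcF"]
    deltas = study_stats.make_deltas(seg, endpoints=endpoints)
    effects = []
    for ep in ("RMSSD", "BRS", "PP"):
        try:
            effects.extend(study_stats.fit_lmm(deltas, ep, exposed_group="exposed"))
        except (ValueError, RuntimeError):
            continue
    effects_df = pd.DataFrame([{
        "endpoint": e.endpoint, "contrast": e.contrast, "estimate": e.estimate,
        "se": e.se, "p_value": e.p_value, "model": e.model,
    } for e in effects])
    events_df = pd.DataFrame([{
        "type": e.type, "animal_id": e.animal_id, "day_label": e.day_label,
        "anchor_index": e.anchor_index,
    } for e in events])
    return {
        "segments": seg, "events": events_df, "counts": counts,
        "ventilation": vent, "deltas": deltas, "effects": effects_df,
    }
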