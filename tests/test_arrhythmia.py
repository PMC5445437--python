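from collections import Counter

import numpy as np
import pandas as pd
import pytest

from cardioauto import arrhythmia as arr, synthetic_data as sd
from conftest import make_regular_series

CAL = arr.PrCalibration(mean=45.0, sd=1.0)


def drop_qrs(series, i, on_time=True, pp_ratio=0.75, rr_fold=2.1,
             prior_prs=None, post_pr=45.0):
    """Rewrite a regular train so beat i is a non-conducted P with the given
    signature; later beats shift to realize rr_fold."""
    df = series.beats.copy()
    rr0 = 180.0
    if prior_prs is not None:
        for k, p in zip(range(i - 4, i), prior_prs):
            df.loc[k, "t_P"] = df.loc[k, "t_R"] - p
    prior_p = df["t_P"].iloc[:i].to_numpy()
    mean_pp = np.mean(np.diff(prior_p[-5:]))
    df.loc[i, "t_P"] = prior_p[-1] + (mean_pp if on_time else pp_ratio * mean_pp)
    for col in ("t_R", "t_S", "t_Tpeak", "t_Tend"):
        df.loc[i, col] = np.nan
    df.loc[i, "conducted"] = False
    extra = (rr_fold - 2.0) * rr0
    cols = ["t_P", "t_R", "t_S", "t_Tpeak", "t_Tend"]
    df.loc[i + 1:, cols] = df.loc[i + 1:, cols] + extra
    df.loc[i + 1, "t_P"] = df.loc[i + 1, "t_R"] - post_pr
    out = series
    out.beats = df
    return out


class TestDetectApb:
    def test_hand_example_apb(self):
        s = make_regular_series(rr=182.0)
        df = s.beats
        # shorten RR at beat 10 to 148 ms, PR stays 45
        shift = 182.0 - 148.0
        cols = ["t_P", "t_R", "t_S", "t_Tpeak", "t_Tend"]
        df.loc[10, cols] = df.loc[10, cols] - shift
        df.loc[11, "t_P"] = df.loc[11, "t_R"] - 45.0
        events = arr.detect_apb(s, CAL)
        assert [e.anchor_index for e in events] == [10]
        assert events[0].evidence["rr_ms"] == pytest.approx(148.0)

    def test_prolonged_pr_blocks_apb(self):
        s = make_regular_series(rr=182.0)
        df = s.beats
        cols = ["t_P", "t_R", "t_S", "t_Tpeak", "t_Tend"]
        df.loc[10, cols] = df.loc[10, cols] - 34.0
        df.loc[10, "t_P"] = df.loc[10, "t_R"] - 55.0  # PR well outside band
        assert arr.detect_apb(s, CAL) == []

    def test_missing_pr_skipped_with_audit(self):
        s = make_regular_series(rr=182.0)
        df = s.beats
        cols = ["t_P", "t_R", "t_S", "t_Tpeak", "t_Tend"]
        df.loc[10, cols] = df.loc[10, cols] - 34.0
        df.loc[10, "t_P"] = np.nan
        audit = []
        assert arr.detect_apb(s, CAL, audit=audit) == []
        assert audit and "PR missing" in audit[0][1]

    def test_clean_stream_no_events(self, rng):
        cfg = sd.SynthConfig(seed=3, day_minutes=3.0)
        s = sd.generate_beats(cfg, rng)
        cal = arr.calibrate_pr(s)
        events, _ = arr.detect_events(s, cal)
        assert events == []


class TestClassifyNonconductedP:
    def test_mobitz_ii(self):
        s = drop_qrs(make_regular_series(), 20, prior_prs=[45, 45, 46, 45],
                     post_pr=45.0, rr_fold=2.1)
        ev = arr.classify_nonconducted_P(s, 20, CAL)
        assert ev.type == "MobitzII"
        assert ev.evidence["rr_fold"] == pytest.approx(2.1, rel=0.02)

    def test_mobitz_i_by_pr_trend(self):
        s = drop_qrs(make_regular_series(), 20, prior_prs=[45, 48, 52, 57],
                     post_pr=44.0, rr_fold=2.1)
        ev = arr.classify_nonconducted_P(s, 20, CAL)
        assert ev.type == "MobitzI"
        assert ev.evidence["pr_prolonged"]

    def test_mobitz_i_by_post_block_shortening_alone(self):
        s = drop_qrs(make_regular_series(), 20, prior_prs=[45, 45, 45, 45],
                     post_pr=40.0, rr_fold=2.2)
        ev = arr.classify_nonconducted_P(s, 20, CAL)
        assert ev.type == "MobitzI"
        assert ev.evidence["post_pr_shortened"] and not ev.evidence["pr_prolonged"]

    def test_advanced_av_block(self):
        s = drop_qrs(make_regular_series(), 20, prior_prs=[45, 45, 45, 45],
                     post_pr=45.0, rr_fold=3.4)
        ev = arr.classify_nonconducted_P(s, 20, CAL)
        assert ev.type == "AdvancedAVB"

    def test_premature_p_is_ncapb(self):
        s = drop_qrs(make_regular_series(), 20, on_time=False, pp_ratio=0.75)
        ev = arr.classify_nonconducted_P(s, 20, CAL)
        assert ev.type == "ncAPB"
        assert ev.evidence["pp_ratio"] == pytest.approx(0.75, rel=0.02)

    def test_small_rr_increase_unclassifiable(self):
        s = drop_qrs(make_regular_series(), 20, prior_prs=[45, 45, 45, 45],
                     post_pr=45.0, rr_fold=1.5)
        audit = []
        assert arr.classify_nonconducted_P(s, 20, CAL, audit=audit) is None
        assert "RR across block" in audit[0][1]

    def test_insufficient_context_unclassifiable(self):
        s = drop_qrs(make_regular_series(), 3)
        audit = []
        assert arr.classify_nonconducted_P(s, 3, CAL, audit=audit) is None
        assert audit

    def test_conducted_beat_rejected(self, regular_series):
        with pytest.raises(ValueError):
            arr.classify_nonconducted_P(regular_series, 5, CAL)


class TestMutualExclusivityAndAccuracy:
    def _inject_all(self, seed, n_each=20):
        cfg = sd.SynthConfig(seed=seed, day_minutes=10.0, rr_noise_sd=0.5)
        rng = np.random.default_rng(seed)
        base = sd.generate_beats(cfg, rng, day_label="baseline")
        cal = arr.calibrate_pr(base)
        truth = sd.TruthLog()
        s = sd.generate_beats(cfg, rng, day_label="1")
        s = sd.inject_events(s, rng, {t: n_each for t in arr.EVENT_TYPES},
                             truth=truth, config=cfg)
        events, _ = arr.detect_events(s, cal)
        return truth, events

    def test_confusion_matrix_is_diagonal(self):
        truth, events = self._inject_all(seed=2)
        assert Counter(e.type for e in events) == Counter(e["type"] for e in truth.events)
        assert {(e.anchor_index, e.type) for e in events} == \
               {(e["row"], e["type"]) for e in truth.events}

    def test_one_label_per_nonconducted_p(self):
        truth, events = self._inject_all(seed=7)
        anchors = [e.anchor_index for e in events]
        assert len(anchors) == len(set(anchors))

    def test_evidence_records_every_rule_term(self):
        _, events = self._inject_all(seed=2, n_each=3)
        for e in events:
            if e.type == "APB":
                assert {"rr_ms", "neighbor_mean_rr_ms", "rr_ratio", "pr_ms"} <= e.evidence.keys()
            else:
                assert "pp_ratio" in e.evidence
            if e.type in ("MobitzI", "MobitzII", "AdvancedAVB"):
                assert {"rr_fold", "prior_prs_ms", "post_pr_ms", "pr_prolonged"} <= e.evidence.keys()


class TestCountEvents:
    def _events(self, spec):
        return [arr.ArrhythmiaEvent(t, i, a, d)
                for (t, i, a, d) in spec]

    def test_simple_daily_count(self):
        design = pd.DataFrame({"animal_id": ["a"], "day_label": ["3"]})
        events = self._events([("MobitzII", i, "a", "3") for i in range(7)])
        counts = arr.count_events(events, design)
        assert counts.loc[0, "MobitzII"] == 7

    def test_apb_restricted_to_audit_days(self):
        design = pd.DataFrame({"animal_id": ["a", "a"], "day_label": ["2", "4"]})
        events = self._events([("APB", 1, "a", "2"), ("APB", 2, "a", "4")])
        counts = arr.count_events(events, design).set_index("day_label")
        assert np.isnan(counts.loc["2", "APB"])  # day 2 is not audited
        assert counts.loc["4", "APB"] == 1

    def test_missing_days_absent_not_zero(self):
        design = pd.DataFrame({"animal_id": ["a"], "day_label": ["1"]})
        counts = arr.count_events([], design)
        assert list(counts["day_label"]) == ["1"]
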