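import math

import numpy as np
import pytest

from cardioauto import hrv_core as hc, synthetic_data as sd


# --- independent brute-force oracles (plain loops, no numpy reductions) ---

def oracle_time_domain(x):
    n = len(x)
    mean = sum(x) / n
    sdnn = math.sqrt(sum((v - mean) ** 2 for v in x) / (n - 1))
    diffs = [x[i + 1] - x[i] for i in range(n - 1)]
    rmssd = math.sqrt(sum(d * d for d in diffs) / len(diffs))
    pnn15 = sum(1 for d in diffs if abs(d) > 15.0) / len(diffs)
    return rmssd, sdnn, sdnn / mean, pnn15


def make_nn(x):
    x = np.asarray(x, dtype=float)
    return hc.NNSeries(intervals=x, times=np.cumsum(x))


class TestFilterEctopic:
    def test_shortened_interval_removed(self):
        nn = hc.filter_ectopic([150, 150, 150, 120, 150, 150, 150])
        assert nn.n_removed == 1
        assert 120 not in nn.intervals
        assert nn.removal_reasons[0][0] == 3

    def test_borderline_interval_kept(self):
        nn = hc.filter_ectopic([150, 150, 150, 125, 150, 150, 150])
        assert nn.n_removed == 0

    def test_exact_threshold_not_removed(self):
        # 0.82 * 150 = 123 exactly: strict inequality keeps it
        nn = hc.filter_ectopic([150, 150, 150, 123, 150, 150, 150])
        assert nn.n_removed == 0

    def test_order_preserved_and_counts(self):
        x = [150, 150, 150, 110, 150, 150, 150, 100, 150, 150, 150]
        nn = hc.filter_ectopic(x)
        assert nn.n_removed == 2
        assert list(nn.intervals) == [v for v in x if v >= 123]

    def test_injected_apbs_exactly_removed(self, rng):
        cfg = sd.SynthConfig(seed=5, day_minutes=5.0, rr_noise_sd=0.5)
        truth = sd.TruthLog()
        s = sd.generate_beats(cfg, rng, day_label="1")
        s = sd.inject_events(s, rng, {"APB": 20}, truth=truth, config=cfg)
        nn = hc.filter_ectopic(s.rr_intervals(), times=s.rr_times())
        removed = {i for i, _ in nn.removal_reasons}
        expected = {e["row"] - 1 for e in truth.events}  # interval ending at the shifted beat
        assert removed == expected

    def test_idempotent_on_generator_output(self, rng):
        cfg = sd.SynthConfig(seed=6, day_minutes=2.0)
        truth = sd.TruthLog()
        s = sd.generate_beats(cfg, rng, day_label="1")
        s = sd.inject_events(s, rng, {"APB": 5}, truth=truth, config=cfg)
        once = hc.filter_ectopic(s.rr_intervals(), times=s.rr_times())
        twice = hc.filter_ectopic(once.intervals, times=once.times)
        assert twice.n_removed == 0
        np.testing.assert_array_equal(once.intervals, twice.intervals)

    def test_all_removed_flag(self):
        # alternating extreme: everything removable collapses to empty + flag
        nn = hc.filter_ectopic([100, 100, 1, 1, 1, 100, 100])
        assert not nn.all_removed  # partial removal is not the flag case
        assert hc.filter_ectopic([1] * 0).n_removed == 0


class TestTimeDomain:
    def test_rmssd_example(self):
        res = hc.time_domain(make_nn([100, 110, 100, 110]))
        assert res.RMSSD == pytest.approx(10.0)

    def test_constant_series_degenerate(self):
        res = hc.time_domain(make_nn([180.0] * 300))
        assert res.SDNN == 0.0 and res.CV == 0.0 and res.pNN15 == 0.0
        assert res.HR == pytest.approx(60000.0 / 180.0)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(50):
            x = rng.uniform(120, 260, size=300)
            res = hc.time_domain(make_nn(x))
            rmssd, sdnn, cv, pnn15 = oracle_time_domain(list(x))
            assert res.RMSSD == pytest.approx(rmssd, rel=1e-9)
            assert res.SDNN == pytest.approx(sdnn, rel=1e-9)
            assert res.CV == pytest.approx(cv, rel=1e-9)
            assert res.pNN15 == pytest.approx(pnn15, abs=1e-12)

    def test_shift_invariance(self, rng):
        x = rng.uniform(150, 210, size=200)
        a, b = hc.time_domain(make_nn(x)), hc.time_domain(make_nn(x + 50.0))
        assert a.RMSSD == pytest.approx(b.RMSSD, rel=1e-9)
        assert a.SDNN == pytest.approx(b.SDNN, rel=1e-9)
        assert a.CV != pytest.approx(b.CV, rel=1e-3)

    def test_below_minimum_counts_flagged(self):
        res = hc.time_domain(make_nn([180.0]))
        assert np.isnan(res.SDNN) and np.isnan(res.RMSSD)
        res2 = hc.time_domain(make_nn([180.0, 181.0]))
        assert not np.isnan(res2.SDNN) and np.isnan(res2.RMSSD)

    def test_hr_identity(self, rng):
        x = rng.uniform(150, 210, size=100)
        res = hc.time_domain(make_nn(x))
        assert res.HR == pytest.approx(60000.0 / res.mean_RR, rel=1e-12)


class TestFrequencyDomain:
    def _sinusoid(self, freq_hz, amp=5.0, n=1500, rr0=180.0):
        rr, t = [], 0.0
        for _ in range(n):
            v = rr0 + amp * np.sin(2 * np.pi * freq_hz * t / 1000.0)
            t += v
            rr.append(v)
        return make_nn(rr)

    def test_sinusoid_power_lands_in_hf(self):
        res = hc.frequency_domain(self._sinusoid(1.2))
        assert res.HF / (res.LF + res.HF) >= 0.95
        # Parseval-style calibration: band power ~ A^2/2 in ms^2
        assert res.HF == pytest.approx(12.5, rel=0.05)

    def test_sinusoid_in_lf_band(self):
        res = hc.frequency_domain(self._sinusoid(0.4))
        assert res.LF / (res.LF + res.HF) >= 0.95

    def test_white_noise_band_ratio(self, rng):
        lo_lf, hi_lf = hc.DEFAULT_BANDS["lf"]
        lo_hf, hi_hf = hc.DEFAULT_BANDS["hf"]
        expect = (hi_lf - lo_lf) / (hi_hf - lo_hf)
        ratios = []
        for _ in range(200):
            x = 180 + rng.normal(0, 5, 400)
            res = hc.frequency_domain(make_nn(x))
            ratios.append(res.LF_HF)
        assert 0.5 * expect <= np.mean(ratios) <= 2.0 * expect

    def test_constant_intervals_zero_power(self):
        res = hc.frequency_domain(make_nn([180.0] * 600))
        assert res.LF == 0.0 and res.HF == 0.0
        assert np.isnan(res.LF_HF)

    def test_excess_removal_flagged_low_confidence(self, rng):
        x = rng.uniform(150, 210, 400)
        nn = make_nn(x)
        nn.n_removed = 200  # 33% of original
        res = hc.frequency_domain(nn)
        assert res.low_confidence

    def test_interp_method_agrees_on_band_location(self):
        res = hc.frequency_domain(self._sinusoid(1.2), method="interp")
        assert res.HF / (res.LF + res.HF) >= 0.95

    def test_unknown_method_raises(self):
        with pytest.raises(ValueError):
            hc.frequency_domain(make_nn([180.0] * 200), method="welch3")


def test_pulse_mode_agrees_with_ecg_mode(rng):
    """Systolic peaks at a fixed offset from the QRS reference give the same
    intervals, so time-domain HRV agrees to well under 2%."""
    cfg = sd.SynthConfig(seed=9, day_minutes=3.0)
    s = sd.with_pulse_channel(sd.generate_beats(cfg, rng))
    from dataclasses import replace
    ecg = hc.time_domain(hc.filter_ectopic(s.rr_intervals()))
    pulse_series = replace(s, source="pulse")
    pulse = hc.time_domain(hc.filter_ectopic(pulse_series.rr_intervals(), source="pulse"))
    assert pulse.RMSSD == pytest.approx(ecg.RMSSD, rel=0.02)
    assert pulse.SDNN == pytest.approx(ecg.SDNN, rel=0.02)
    assert pulse.CV == pytest.approx(ecg.CV, rel=0.02)
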