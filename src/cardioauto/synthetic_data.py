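"""Ground-truth generator for telemetry-style study inputs.

Generates beat-annotated series with baroreflex-coupled SBP→interval
dynamics, respiratory sinus arrhythmia, injectable arrhythmia signatures,
template waveform chunks with analytic morphology, breath tables with
disturbance episodes, and endpoint-level study simulators for the
statistics layer.  Every injected quantity is recorded in a
:class:`TruthLog` so any estimator can be scored against known truth.

Fidelity level is beat-domain: the downstream analyses consume fiducials
and per-beat pressures, so beats (not full waveforms) are the primary
product; waveform chunks are template-based and only produced where the
morphology operations need them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .beat_io import BeatSeries


@dataclass
class SynthConfig:
    """Knobs for the study generator.  Identical config + seed reproduces
    identical output."""

    seed: int = 0
    n_per_group: int = 6
    n_days: int = 12                 # exposure days; a baseline day is added
    day_minutes: float = 15.0        # per-day recorded minutes (5-h day = 300)
    # beat dynamics
    rr0: float = 180.0               # ms
    sbp0: float = 125.0              # mmHg
    pulse_amp: float = 40.0          # mmHg (SBP - DBP)
    brs_gain: float = 1.65           # ms/mmHg
    coupling_prob: float = 1.0       # per-beat baroreflex engagement
    slow_freq: float = 0.10          # Hz (Mayer-band analog)
    slow_amp: float = 3.0            # mmHg
    resp_freq: float = 1.5           # Hz
    resp_amp: float = 1.0            # mmHg
    rsa_amp: float = 1.0             # ms
    rr_noise_sd: float = 1.0         # ms
    sbp_noise_sd: float = 0.5        # mmHg
    # fiducial offsets (ms)
    pr_ms: float = 45.0
    pr_jitter_sd: float = 1.0
    qrs_ms: float = 15.0
    qt_peak_ms: float = 45.0
    qt_ms: float = 60.0
    # group effects (exposed - control) on endpoint deltas
    effects: dict = field(default_factory=dict)   # e.g. {"RMSSD": -1.31}
    # arrhythmia injections: {type: events per day} for exposed animals
    injections: dict = field(default_factory=dict)
    # breaths
    t_i_ms: float = 200.0
    t_e_ms: float = 250.0
    breath_jitter_sd: float = 5.0
    pause_s: float = 0.05
    disturbance_coupling: float = 0.0  # fraction of events preceded by a disturbance

    def validate(self) -> None:
        if self.qt_ms >= self.rr0:
            raise ValueError("infeasible timing: QT >= RR")
        if any(v < 0 for v in self.injections.values()):
            raise ValueError("injection rates must be >= 0")


@dataclass
class TruthLog:
    """Everything the generator injected, sufficient to score any output."""

    events: list = field(default_factory=list)       # dicts: type, animal, day, row, t_event
    effects: dict = field(default_factory=dict)      # endpoint -> injected effect
    brs_gain: float = np.nan
    couplings: dict = field(default_factory=dict)    # e.g. {"brs_rmssd": 0.71}
    disturbances: list = field(default_factory=list) # dicts: animal, day, kind, t_ms


# ---------------------------------------------------------------------------
# beat-level generation


def generate_beats(
    config: SynthConfig,
    rng: np.random.Generator,
    duration_ms: float | None = None,
    animal_id: str = "r01",
    day_label: str = "baseline",
    group: str = "control",
    brs_gain: float | None = None,
) -> BeatSeries:
    """One animal-day beat series with baroreflex-coupled dynamics.

    SBP carries a slow (Mayer-band analog) and a respiratory oscillation
    plus noise; the interval following beat *i* responds to that beat's SBP
    deviation with gain G (per-beat Bernoulli engagement), plus respiratory
    sinus arrhythmia and noise.  Fiducials sit at configured offsets from
    the QRS reference.
    """
    config.validate()
    g = config.brs_gain if brs_gain is None else brs_gain
    if duration_ms is None:
        duration_ms = config.day_minutes * 60_000.0
    n = max(int(duration_ms / config.rr0), 8)
    t_nom = np.arange(n) * config.rr0 / 1000.0  # s, for oscillator phases
    ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
    sbp_fluct = (
        config.slow_amp * np.sin(2 * np.pi * config.slow_freq * t_nom + ph1)
        + config.resp_amp * np.sin(2 * np.pi * config.resp_freq * t_nom + ph2)
        + rng.normal(0, config.sbp_noise_sd, n)
    )
    sbp = config.sbp0 + sbp_fluct
    coupled = rng.random(n) < config.coupling_prob
    rr = np.empty(n)
    rr[0] = config.rr0
    rr[1:] = (
        config.rr0
        + g * sbp_fluct[:-1] * coupled[:-1]
        + config.rsa_amp * np.sin(2 * np.pi * config.resp_freq * t_nom[1:] + ph2)
        + rng.normal(0, config.rr_noise_sd, n - 1)
    )
    t_r = np.cumsum(rr)
    pr = config.pr_ms + rng.normal(0, config.pr_jitter_sd, n)
    df = pd.DataFrame({
        "t_P": t_r - pr,
        "t_R": t_r,
        "t_S": t_r + config.qrs_ms,
        "t_Tpeak": t_r + config.qt_peak_ms,
        "t_Tend": t_r + config.qt_ms,
        "conducted": True,
        "SBP": sbp,
        "DBP": sbp - config.pulse_amp,
    })
    return BeatSeries(beats=df, animal_id=animal_id, day_label=day_label, group=group)


def with_pulse_channel(series: BeatSeries, offset_ms: float = 30.0) -> BeatSeries:
    """Add a systolic-peak time channel at a fixed offset from the QRS
    reference, for pulse-interval input mode."""
    df = series.beats.copy()
    df["t_sys"] = df["t_R"] + offset_ms
    return replace(series, beats=df)


# ---------------------------------------------------------------------------
# arrhythmia signature injection


def _pick_slots(rng, n_beats: int, n_events: int, margin: int = 12, spacing: int = 14) -> np.ndarray:
    """Well-separated beat rows away from the series edges."""
    candidates = np.arange(margin, n_beats - margin)
    rng.shuffle(candidates)
    chosen: list[int] = []
    for c in candidates:
        if all(abs(c - k) >= spacing for k in chosen):
            chosen.append(int(c))
        if len(chosen) == n_events:
            break
    if len(chosen) < n_events:
        raise ValueError("series too short for requested injections")
    return np.array(sorted(chosen))


def inject_apb(series: BeatSeries, rng, rows, shorten_frac: float = 0.30,
               truth: TruthLog | None = None, config: SynthConfig | None = None) -> BeatSeries:
    """Shift each chosen beat earlier by ``shorten_frac``·RR0: its RR
    shortens, the next lengthens (compensatory); PR stays normal."""
    cfg = config or SynthConfig()
    df = series.beats.copy()
    delta = shorten_frac * cfg.rr0
    for i in rows:
        for col in ("t_P", "t_R", "t_S", "t_Tpeak", "t_Tend"):
            df.loc[i, col] -= delta
        # pin PR to the calibration mean so the "normal PR" conjunct is
        # unambiguous regardless of the jitter draw
        df.loc[i, "t_P"] = df.loc[i, "t_R"] - cfg.pr_ms
        if truth is not None:
            truth.events.append({
                "type": "APB", "animal_id": series.animal_id,
                "day_label": series.day_label, "row": int(i),
                "t_event": float(df.loc[i, "t_R"]),
            })
    return replace(series, beats=df)


def inject_ncapb(series: BeatSeries, rng, rows, prematurity: float = 0.75,
                 truth: TruthLog | None = None) -> BeatSeries:
    """Insert a premature non-conducted P wave after each chosen beat."""
    df = series.beats.copy()
    inserts = []
    for i in rows:
        pp = df["t_P"].iloc[i] - df["t_P"].iloc[i - 1]
        t_p_new = df["t_P"].iloc[i] + prematurity * pp
        inserts.append((i, {
            "t_P": t_p_new, "t_R": np.nan, "t_S": np.nan,
            "t_Tpeak": np.nan, "t_Tend": np.nan, "conducted": False,
            "SBP": np.nan, "DBP": np.nan,
        }))
    out = []
    prev = 0
    new_rows = {}
    for i, rec in inserts:
        out.append(df.iloc[prev:i + 1])
        out.append(pd.DataFrame([rec]))
        prev = i + 1
    out.append(df.iloc[prev:])
    new_df = pd.concat(out, ignore_index=True)
    if truth is not None:
        # insertions shift the rows of events logged earlier for this series
        for e in truth.events:
            if e["animal_id"] == series.animal_id and e["day_label"] == series.day_label:
                e["row"] += sum(1 for i, _ in inserts if i < e["row"])
        for k, (i, rec) in enumerate(inserts):
            truth.events.append({
                "type": "ncAPB", "animal_id": series.animal_id,
                "day_label": series.day_label, "row": int(i + 1 + k),
                "t_event": float(rec["t_P"]),
            })
    return replace(series, beats=new_df)


def inject_av_block(series: BeatSeries, rng, rows, kind: str,
                    truth: TruthLog | None = None,
                    config: SynthConfig | None = None) -> BeatSeries:
    """Turn each chosen beat into a non-conducted on-time P with the PR/RR
    signature of the requested block type.

    Mobitz I: PR ramp over the prior 4 conducted beats and a shortened
    first post-block PR, RR across the block ≈ 2.3× baseline.  Mobitz II:
    flat prior PRs, normal post PR, RR ≈ 2.5×.  Advanced: Mobitz II pattern
    with RR ≈ 3.5×.
    """
    cfg = config or SynthConfig()
    fold = {"MobitzI": 2.3, "MobitzII": 2.5, "AdvancedAVB": 3.5}[kind]
    df = series.beats.copy()
    pr0 = cfg.pr_ms
    step = 3.0 * max(cfg.pr_jitter_sd, 1.0)
    shift_cols = ("t_P", "t_R", "t_S", "t_Tpeak", "t_Tend")
    for i in sorted(int(r) for r in rows):
        if kind == "MobitzI":
            for k, off in zip(range(i - 4, i), (0.0, step, 2 * step, 3 * step)):
                df.loc[k, "t_P"] = df.loc[k, "t_R"] - (pr0 + off)
            df.loc[i + 1, "t_P"] = df.loc[i + 1, "t_R"] - (pr0 - step)
        else:
            for k in range(i - 4, i):
                df.loc[k, "t_P"] = df.loc[k, "t_R"] - pr0
            df.loc[i + 1, "t_P"] = df.loc[i + 1, "t_R"] - pr0
        # on-time P for the blocked beat
        prior_p = df["t_P"].iloc[:i].dropna().to_numpy()
        mean_pp = float(np.mean(np.diff(prior_p[-5:])))
        df.loc[i, "t_P"] = prior_p[-1] + mean_pp
        for col in ("t_R", "t_S", "t_Tpeak", "t_Tend"):
            df.loc[i, col] = np.nan
        df.loc[i, "conducted"] = False
        # lengthen the pause: push all later beats back
        extra = (fold - 2.0) * cfg.rr0
        df.loc[i + 1:, shift_cols] = df.loc[i + 1:, shift_cols] + extra
        if truth is not None:
            truth.events.append({
                "type": kind, "animal_id": series.animal_id,
                "day_label": series.day_label, "row": int(i),
                "t_event": float(df.loc[i, "t_P"]),
            })
    return replace(series, beats=df)


def inject_events(series: BeatSeries, rng, spec: dict, truth: TruthLog | None = None,
                  config: SynthConfig | None = None) -> BeatSeries:
    """Inject ``spec = {type: count}`` signatures at well-separated rows.

    ncAPB insertions run last so earlier row choices stay valid.
    """
    order = [t for t in ("APB", "MobitzI", "MobitzII", "AdvancedAVB", "ncAPB") if spec.get(t)]
    n_total = sum(spec[t] for t in order)
    if n_total == 0:
        return series
    slots = _pick_slots(rng, len(series), n_total)
    rng.shuffle(slots)
    cursor = 0
    for t in order:
        rows = np.sort(slots[cursor:cursor + spec[t]])
        cursor += spec[t]
        if t == "APB":
            series = inject_apb(series, rng, rows, truth=truth, config=config)
        elif t == "ncAPB":
            series = inject_ncapb(series, rng, rows, truth=truth)
        else:
            series = inject_av_block(series, rng, rows, t, truth=truth, config=config)
    return series


# ---------------------------------------------------------------------------
# waveform templates


def pressure_pulse(amplitude: float = 40.0, period_ms: float = 40.0,
                   dbp: float = 85.0, dt: float = 0.5):
    """Half-sine pressure pulse spanning ``period_ms``; analytic
    dP/dt_max = π·A/T."""
    from .waveform_features import WaveformChunk

    t = np.arange(0.0, period_ms + dt / 2, dt)
    samples = dbp + amplitude * np.sin(np.pi * t / period_ms)
    truth = np.pi * amplitude / (period_ms / 1000.0)
    return WaveformChunk("pressure", 0.0, dt, samples), truth


def ecg_st_template(t_s: float = 20.0, dt: float = 0.25, duration_ms: float = 40.0,
                    shape: str = "flat", level_mv: float = 0.1, slope_mv_ms: float = 0.02,
                    cubic_coeffs: tuple[float, float, float, float] = (0.0, 0.01, -0.004, 0.0003)):
    """ECG chunk with an analytic ST segment after the S point.

    Shapes: ``flat`` (constant ``level_mv``), ``ramp`` (``slope_mv_ms`` per
    ms), or ``cubic`` (polynomial in ms after S).  Returns the chunk and a
    dict of closed-form S-min-slope / ST-amp truths.
    """
    from .waveform_features import WaveformChunk

    t = np.arange(0.0, duration_ms + dt / 2, dt)
    u = t - t_s
    if shape == "flat":
        post = np.full_like(u, level_mv)
        truth = {"S_min_slope": 0.0, "ST_amp": level_mv}
    elif shape == "ramp":
        post = slope_mv_ms * u
        truth = {"S_min_slope": slope_mv_ms, "ST_amp": slope_mv_ms * 3.0}
    elif shape == "cubic":
        a0, a1, a2, a3 = cubic_coeffs
        post = a0 + a1 * u + a2 * u ** 2 + a3 * u ** 3
        du = np.linspace(0, 1.5, 2001)
        dv = a1 + 2 * a2 * du + 3 * a3 * du ** 2
        amps = np.linspace(2.0, 4.0, 2001)
        vals = a0 + a1 * amps + a2 * amps ** 2 + a3 * amps ** 3
        truth = {"S_min_slope": float(dv.min()), "ST_amp": float(vals.mean())}
    else:
        raise ValueError(f"unknown ST shape {shape!r}")
    samples = np.where(u >= 0, post, 0.0)
    return WaveformChunk("ecg", 0.0, dt, samples), truth


def generate_waveforms(config: SynthConfig, n_beats: int = 3, dt: float = 0.5):
    """Template pressure pulses (one per beat) for dP/dt_max checks."""
    if dt > 0.5:
        raise ValueError("waveform sampling must be <= 0.5 ms for ST metrics")
    chunks, truths = [], []
    for _ in range(n_beats):
        c, truth = pressure_pulse(config.pulse_amp, 40.0, config.sbp0 - config.pulse_amp, dt)
        chunks.append(c)
        truths.append(truth)
    return chunks, truths


# ---------------------------------------------------------------------------
# breath generation


def generate_breaths(
    config: SynthConfig,
    rng: np.random.Generator,
    duration_ms: float | None = None,
    animal_id: str = "r01",
    day_label: str = "baseline",
    t_e_shift: float = 0.0,
    disturbance_times: list[tuple[str, float]] | None = None,
    truth: TruthLog | None = None,
) -> pd.DataFrame:
    """Breath train for one animal-day.

    ``t_e_shift`` adds to every expiratory time (group-effect injection).
    ``disturbance_times`` is a list of (kind, t_ms) episodes — ``apnea``
    (a gap of 2.5 expected breaths), ``braking`` (one breath with 2.5×
    T_E), ``tachypnea`` (three breaths at 40% duration) — placed so the
    episode ends at t_ms.
    """
    if duration_ms is None:
        duration_ms = config.day_minutes * 60_000.0
    t_i0 = config.t_i_ms
    t_e0 = config.t_e_ms + t_e_shift
    t_t0 = t_i0 + t_e0
    episodes = sorted(disturbance_times or [], key=lambda kv: kv[1])
    rows = []
    t = 0.0
    ep_idx = 0
    while t < duration_ms:
        next_lead = 3.5 if (ep_idx < len(episodes) and episodes[ep_idx][0] == "apnea") else 2.0
        if ep_idx < len(episodes) and t >= episodes[ep_idx][1] - next_lead * t_t0:
            kind, t_ep = episodes[ep_idx]
            ep_idx += 1
            if t_ep <= t:
                continue  # too late to honor this episode; drop it
            if kind == "apnea":
                t = t_ep  # breathless gap up to the event time
                if truth is not None:
                    truth.disturbances.append({"animal_id": animal_id, "day_label": day_label,
                                               "kind": kind, "t_ms": t_ep})
                continue
            if kind == "braking":
                te = 2.5 * t_e0
                rows.append((t, t + t_i0, t + t_i0 + te))
                t = rows[-1][2]
            elif kind == "tachypnea":
                for _ in range(3):
                    rows.append((t, t + 0.4 * t_i0, t + 0.4 * t_t0))
                    t = rows[-1][2]
            if truth is not None:
                truth.disturbances.append({"animal_id": animal_id, "day_label": day_label,
                                           "kind": kind, "t_ms": t_ep})
            continue
        ti = max(t_i0 + rng.normal(0, config.breath_jitter_sd), 20.0)
        te = max(t_e0 + rng.normal(0, config.breath_jitter_sd), 20.0)
        rows.append((t, t + ti, t + ti + te))
        t = rows[-1][2]
    df = pd.DataFrame(rows, columns=["t_start", "t_insp_end", "t_end"])
    df["pause"] = np.maximum(config.pause_s + rng.normal(0, 0.01, len(df)), 0.0)
    df["animal_id"] = animal_id
    df["day_label"] = day_label
    return df


# ---------------------------------------------------------------------------
# endpoint-level study simulators (fast substrate for the inference layer)


def simulate_delta_study(
    rng: np.random.Generator,
    effect: float,
    n_per_group: int = 6,
    n_days: int = 12,
    animal_sd: float = 0.5,
    day_sd: float = 0.3,
    resid_sd: float = 1.0,
    endpoint: str = "RMSSD",
) -> pd.DataFrame:
    """Delta table with an injected overall exposed-vs-control effect:
    delta = effect·exposed + animal intercept + day effect + noise."""
    rows = []
    day_eff = rng.normal(0, day_sd, n_days)
    for gi, grp in enumerate(("control", "exposed")):
        for a in range(n_per_group):
            animal = f"{grp[0]}{a:02d}"
            a_eff = rng.normal(0, animal_sd)
            for d in range(n_days):
                rows.append({
                    "animal_id": animal, "group": grp, "day_label": f"{d + 1:02d}",
                    "endpoint": endpoint,
                    "delta": effect * gi + a_eff + day_eff[d] + rng.normal(0, resid_sd),
                })
    return pd.DataFrame(rows)


def simulate_count_study(
    rng: np.random.Generator,
    base_rate: float = 2.0,
    day_rate_ratios: dict[str, float] | None = None,
    n_per_group: int = 6,
    n_days: int = 12,
    animal_sd: float = 0.0,
    endpoint: str = "MobitzII",
) -> pd.DataFrame:
    """Per-animal-day Poisson counts (plus a baseline day) with injected
    exposed-vs-control rate ratios on selected days."""
    rrs = day_rate_ratios or {}
    rows = []
    for grp in ("control", "exposed"):
        for a in range(n_per_group):
            animal = f"{grp[0]}{a:02d}"
            frailty = np.exp(rng.normal(0, animal_sd)) if animal_sd else 1.0
            rows.append({"animal_id": animal, "group": grp, "day_label": "baseline",
                         endpoint: int(rng.poisson(base_rate * frailty))})
            for d in range(1, n_days + 1):
                lam = base_rate * frailty
                if grp == "exposed":
                    lam *= rrs.get(str(d), 1.0)
                rows.append({"animal_id": animal, "group": grp, "day_label": f"{d:02d}",
                             endpoint: int(rng.poisson(lam))})
    return pd.DataFrame(rows)


def simulate_coupled_endpoints(
    rng: np.random.Generator,
    r: float,
    n: int,
    confound_by_group: bool = False,
    group_shift: float = 3.0,
) -> pd.DataFrame:
    """Paired endpoint observations with Pearson coupling ``r`` (within
    group).  With ``confound_by_group`` the within-group coupling is zero
    but both endpoints shift between groups, creating a pooled association
    that partial correlation should remove."""
    half = n // 2
    groups = np.r_[np.zeros(half), np.ones(n - half)]
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    if confound_by_group:
        x = z1 + group_shift * groups
        y = z2 + group_shift * groups
    else:
        x = z1
        y = r * z1 + np.sqrt(max(0.0, 1 - r ** 2)) * z2
    return pd.DataFrame({
        "x": x, "y": y,
        "group": np.where(groups > 0, "exposed", "control"),
    })


# ---------------------------------------------------------------------------
# full-study generation


def day_labels(n_days: int) -> list[str]:
    return ["baseline"] + [str(d) for d in range(1, n_days + 1)]


def generate_study(config: SynthConfig) -> dict:
    """Full synthetic study: beats + breaths + design + truth log.

    Two groups (control / exposed) × ``n_per_group`` animals × baseline +
    ``n_days`` exposure days.  Group effects from ``config.effects`` are
    applied on exposure days for exposed animals (currently: ``brs_gain``
    additive on G, ``T_E`` additive in ms); arrhythmia signatures from
    ``config.injections`` are injected into exposed animals' exposure days.
    Deterministic for a fixed config.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = TruthLog(effects=dict(config.effects), brs_gain=config.brs_gain)
    beats, breaths, design = [], [], []
    for grp in ("control", "exposed"):
        for a in range(config.n_per_group):
            animal = f"{grp[0]}{a:02d}"
            for day in day_labels(config.n_days):
                exposed_day = grp == "exposed" and day != "baseline"
                gain = config.brs_gain + (config.effects.get("brs_gain", 0.0) if exposed_day else 0.0)
                series = generate_beats(config, rng, animal_id=animal, day_label=day,
                                        group=grp, brs_gain=gain)
                if exposed_day and config.injections:
                    series = inject_events(series, rng, config.injections, truth=truth,
                                           config=config)
                beats.append(series)
                ev_times = [e["t_event"] for e in truth.events
                            if e["animal_id"] == animal and e["day_label"] == day]
                coupled = [("braking", t) for t in ev_times
                           if rng.random() < config.disturbance_coupling]
                breaths.append(generate_breaths(
                    config, rng, animal_id=animal, day_label=day,
                    t_e_shift=config.effects.get("T_E", 0.0) if exposed_day else 0.0,
                    disturbance_times=coupled, truth=truth,
                ))
                design.append({"animal_id": animal, "group": grp, "day_label": day})
    return {
        "beats": beats,
        "breaths": pd.concat(breaths, ignore_index=True),
        "design": pd.DataFrame(design),
        "truth": truth,
        "config": asdict(config),
    }
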