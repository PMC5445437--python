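# cardioauto

Cardiovascular-autonomic analysis of beat-annotated telemetry from small
animals: beat-series cleaning, heart rate variability (HRV), spontaneous
baroreflex sensitivity (sequence method), rule-based arrhythmia
classification, ECG/hemodynamic morphology, ventilatory timing, and a
delta-from-baseline statistical inference layer — plus a synthetic-data
generator with a complete ground-truth log so every estimator can be
validated by parameter recovery.

## Modules

| Module | Role |
| --- | --- |
| `cardioauto.beat_io` | beats/breaths CSV I/O, validation, 5-min / 10-min windowing |
| `cardioauto.hrv_core` | ectopic-interval filter (>18% shortening rule), RMSSD/SDNN/CV/pNN15, Lomb–Scargle LF/HF |
| `cardioauto.baroreflex` | sequence-method BRS (≥3-beat ramps, ≥0.50 mmHg, ≥0.30 ms, r ≥ 0.50) |
| `cardioauto.arrhythmia` | APB rule and the non-conducted-P cascade (ncAPB / Mobitz I / Mobitz II / advanced AVB), daily counts |
| `cardioauto.waveform_features` | QT correction (Fridericia/Bazett), ST amplitude & minimum ST slope, dP/dt_max, segment hemodynamics |
| `cardioauto.ventilation` | T_I/T_E/T_T/f/pause window & daily averages, pre-arrhythmia disturbance screen |
| `cardioauto.study_stats` | delta tables, linear mixed models (AIC structure selection, REML inference), Poisson GEE, (partial) correlation |
| `cardioauto.synthetic_data` | study generator: baroreflex-coupled beats, arrhythmia signature injection, waveform templates, breath trains, truth log |

## CLI

```bash
# generate a synthetic study with known truth
cardioauto synth --config synth.yaml --seed 1 --out study/

# validate/store externally produced tables
cardioauto ingest --beats beats.csv --design design.csv --breaths breaths.csv --out store/

# per-segment analyses
cardioauto hrv --store study/                 # -> hrv_results.csv
cardioauto brs --store study/                 # -> brs_results.csv
cardioauto arrhythmia --store study/          # -> events.csv, daily_counts.csv
cardioauto morph --store study/ --rr-ref 150  # -> morphology.csv
cardioauto vent --store study/                # -> ventilation_daily.csv
cardioauto vent-screen --store study/ --events study/events.csv

# inference on deltas from baseline
cardioauto stats --store study/ --endpoints RMSSD,BRS,PP
```

`beats.csv` columns: `animal_id, group, day_label, segment_id, t_P, t_R,
t_S, t_Tpeak, t_Tend, conducted, SBP, DBP` (times in ms from recording
start; empty cell = missing). Pulse-interval mode (`--pulse-mode`) accepts a
`t_sys` systolic-peak-time column instead of ECG fiducials. `breaths.csv`
columns: `animal_id, day_label, t_start, t_insp_end, t_end, pause`.

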