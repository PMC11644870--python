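# semgfog

Surface-EMG processing and freezing-of-gait (FOG) precursor detection for
wearable lower-limb sEMG, exercised end to end on a synthetic signal
generator.

## The problem

In advanced Parkinson's disease, freezing of gait — a sudden inability to
step forward — causes falls and injuries. Wearable sEMG garments record
thigh-muscle activity (quadriceps, hamstrings) while the patient walks;
shortly before a freeze, the sEMG envelope collapses from its normal scale
(activity oscillating around ±3 mV) to roughly ±1 mV, a near 3-fold drop
that begins 3–4.5 s before the episode and persists for more than 3 s.
Detecting that sustained drop in real time would give the patient a few
seconds of warning. This package implements the full offline analysis
chain behind such an alert:

1. **Conditioning** — 15–450 Hz Butterworth bandpass (zero-phase or
   causal), optional 60 Hz notch.
2. **Envelope features** — sliding-window RMS/MAV/peak-to-peak (200 ms
   window, 10–50 ms step) and a threshold-normalized training load.
3. **Fatigue** — per-window median frequency (MDF), the frequency f*
   splitting the in-band power spectrum into equal halves
   (∫₀^f* P df = ½∫P df), with an OLS trend test; declining MDF indicates
   emerging fatigue.
4. **Precursor detection** — causal rolling-median baseline b(t) with
   in-drop exclusion; an event opens when the smoothed RMS falls below
   0.5·b, closes above 0.6·b, and must persist ≥ 3 s; onsets are
   backtracked to the last normal-amplitude burst; events co-occurring on
   both thigh channels fuse into session-level alerts that are matched to
   annotated FOG onsets (lead time = onset − event start; fold drop =
   reference RMS / in-event RMS).
5. **Statistics** — one-way ANOVA between activity states
   (active vs pause, normal vs pre-FOG).

Because clinical recordings of this kind are confidential, the
`semgfog.synth` module is a first-class, tested component: seeded
band-limited-noise sEMG with gait-cycle burst modulation, calibrated
amplitude (95th percentile of |signal| = 3 mV), embedded FOG precursors,
powerline/drift interference, spectral fatigue compression, and the
bicep-curl benchmarking protocol (10 s pause / 30 s curls / 30 s pause /
30 s curls). A fixed three-session cohort embeds 8 FOG episodes in total.
See `docs/methods.md` for the model and its limits.

## Worked example

```python
import semgfog as sf

# one synthetic walking session: a FOG episode at t = 25 s whose envelope
# drop (3 mV -> 1 mV) begins 4 s earlier
spec = sf.SessionSpec(duration_s=40.0,
                      episodes=[sf.FogEpisodeSpec(fog_onset_s=25.0,
                                                  precursor_lead_s=4.0)],
                      seed=3)
rec, ann = sf.generate_session(spec)

res = sf.analyze_session(rec, ann)   # bandpass -> envelope -> detect -> match
ev = res.events[0]
print(f"alert at {ev.start_s:.2f} s, lead {ev.lead_s:.2f} s, "
      f"fold drop {res.folds[0]:.2f}")
print(f"sensitivity {res.report.sensitivity}, "
      f"false alarms/min {res.report.false_alarms_per_min}")
```

prints

```
alert at 20.22 s, lead 4.78 s, fold drop 2.97
sensitivity 1.0, false alarms/min 0.0
```

The detector raised a single alert 4.78 s before the annotated freeze
(the true drop began 4 s before it; the onset convention is deliberately
slightly early), measured a 2.97-fold envelope drop relative to normal
walking, found every annotated onset and raised no spurious alerts.

The same chain is scriptable from the shell:

```sh
semgfog simulate --seed 3 --out session/
semgfog preprocess session/recording.csv --out filtered.csv
semgfog features filtered.csv --out env.csv
semgfog detect env.csv --annotations session/annotations.csv --report report.json
semgfog run --config run.yaml            # full pipeline from a YAML config
```

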