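# Methods

This note documents the models, estimators and numerical choices behind
`semgfog`: a toolchain for surface-EMG (sEMG) conditioning, envelope
feature extraction, muscle-fatigue trending, and the detection of the
sustained amplitude drop that precedes freezing-of-gait (FOG) episodes in
Parkinson's disease, evaluated end to end on synthetic sessions.

## Signal model of the synthetic generator

Real lower-limb sEMG from FOG patients is not publicly available, so the
package ships a seeded generator (`semgfog.synth`) that reproduces the
signal *structure* the analysis relies on:

- **Carrier.** Zero-mean Gaussian noise shaped to a 20–400 Hz band
  (4th-order Butterworth, zero-phase), the standard surrogate for
  interference-pattern sEMG. The band sits inside the 15–450 Hz analysis
  bandpass.
- **Gait modulation.** Each channel is amplitude-modulated by a
  stride-periodic envelope: one Hann-shaped burst per gait cycle (default
  period 1.1 s, duty 0.4) on a small tonic floor (5% of burst peak,
  standing muscle tone). Left-side channels are phase-shifted by half a
  cycle.
- **Amplitude calibration.** The signal is scaled so the 95th percentile
  of |signal| over normal walking equals `normal_amplitude_mv` (default
  3.0 mV): "oscillating around ±3 mV" is read as an envelope scale, not a
  hard clip, because physiological amplitudes exceed nominal bounds and a
  percentile is testable.
- **FOG precursors.** Each episode multiplies the envelope by an
  attenuation factor over `[onset − lead, onset + duration]` — the drop
  *precedes* the freeze and persists through it. Defaults encode the
  reported regime: attenuation 1/3 (3 mV → 1 mV) and leads of 3–4.5 s.
  Whether activity rebounds during the freeze itself is not established;
  keeping the attenuation through the episode is a modeling choice.
- **Interference.** Additive 60 Hz powerline (default 0.05 mV) and slow
  0.3 Hz baseline drift (0.2 mV; removed by the bandpass).
- **Fatigue.** Spectral compression with an exponentially decaying
  low-pass corner, `f_c(t) = 400 · exp(−r·t)` Hz, realized by overlap-add
  of Hann-windowed 2-s segments each filtered to its instantaneous band.
  The default curl-protocol rate r = 0.01 s⁻¹ roughly halves the corner
  over a 100-s session — a strong but plausible fatigue progression.

The **demonstration cohort** is three fixed-seed walking sessions carrying
4, 2 and 2 episodes (8 total; one "patient" with four episodes, the
remainder split evenly), attenuation 1/3, episode duration 5 s, lead times
drawn once per session from U(3.0, 4.5) s with the fixed seeds. The
**curl protocol** is 10 s pause, 30 s of curls, 30 s pause, 30 s of curls,
one biceps channel, bursts only inside the sets.

What the generator does *not* emulate: motor-unit discharge structure,
electrode-contact artifacts and dropout, movement artifacts below 15 Hz
with broadband content, inter-stride variability of cycle length, and
cross-channel physiological delays. Passing tests therefore demonstrate
the correctness and calibration of the *pipeline* under the assumed signal
structure, not clinical performance on patient recordings.

## Conditioning and envelope features

Raw signals pass a 15–450 Hz Butterworth bandpass (design order 4,
`sosfiltfilt` for the zero-phase default; a causal mode exists for
simulated real-time replay). An optional 60 Hz notch (Q = 30) is off by
default since the canonical chain lists only the bandpass.

Envelope features are computed per sliding window: RMS, mean absolute
value, and peak-to-peak, with a 200 ms window and 10 ms step (the fine end
of the supported 10–50 ms range, chosen for lead-time resolution; 50 ms
suits constrained hardware). The first window starts at `t0`, window
*centers* are reported, and a trailing partial window is dropped — this
alignment fixes the window count: a 10 s recording at 1 kHz yields
⌊(10 − 0.2)/0.01⌋ + 1 = 981 windows.

`training_load` is this package's operationalization of
threshold-normalized effort: step × Σ(window RMS)/threshold over windows
whose *start times* fall in active intervals, i.e. activity-seconds in
units of the isometric threshold. A contraction held exactly at threshold
for 30 s scores 30.0. The start-time membership convention makes that
identity exact. No published formula exists for the corresponding app
readout; this definition is dimensionally sensible and monotone in effort.

## Median frequency and fatigue trend

MDF uses a single-taper Hann periodogram per window, restricted to the
15–450 Hz band, and returns the frequency where cumulative power first
reaches half the in-band total, linearly interpolated within the crossing
bin. When the half-power level falls on a plateau (e.g. two equal spectral
lines), the plateau midpoint is returned, so a 50 + 150 Hz equal-power
pair yields ≈100 Hz. All-zero windows return NaN ("no power") and are
excluded from trends. MDF windows default to 1 s — decoupled from the
200 ms envelope window because 200 ms gives 5 Hz bins, too coarse near
typical 80–120 Hz values.

`fatigue_trend` fits an OLS line to (time, MDF) over an interval and flags
fatigue when the slope is negative with p < 0.05 (two-sided slope test).
Amplitude scaling leaves MDF invariant to numerical precision (decimal
scaling perturbs the periodogram in the last ulp, so invariance is exact
to ~1e−9 Hz rather than bitwise).

One interaction worth knowing: in windows where the muscle is nearly
silent, the additive 60 Hz powerline line dominates the spectrum and pulls
MDF toward 60 Hz. This modulates window MDF with the burst cycle; trend
controls in the tests therefore run with the powerline term off.

## Precursor detection

Detection operates on the per-channel RMS track:

1. **Smoothing.** A centered moving average spanning 2.2 s ≈ two nominal
   gait cycles. An averaging window equal to an integer number of cycles
   cancels stride-periodic ripple exactly, leaving only stochastic
   fluctuation (a few percent), while a multi-second drop passes through.
2. **Baseline.** A causal rolling median of the smoothed track over the
   trailing 10 s, *excluding* windows already inside a candidate drop, so
   the drop cannot drag its own baseline down; the first 10 s are seeded
   with the global active-period median, and a drop outlasting the buffer
   freezes the last valid baseline.
3. **Hysteresis thresholding.** A candidate opens below 0.5 × baseline
   and closes above 0.6 × baseline. The 0.5 default places the decision
   boundary between normal variation and the reported 1/3 drop; the 0.1
   hysteresis gap prevents chattering.
4. **Persistence and refractoriness.** Candidates closer than 2 s merge;
   only candidates persisting ≥ 3 s survive, matching the observed
   persistence of the pre-FOG drop and suppressing stride-scale dips.
5. **Onset refinement.** The smoothed crossing lags the true drop edge by
   construction, so the start is backtracked to the end of the last
   normal-amplitude stretch: the in-event burst peaks define the
   attenuated scale (their 90th percentile), and on a lightly smoothed
   (0.3 s) RMS track the onset is placed just after the last excursion
   above 1.3 × that scale — a level between the attenuated and normal
   burst-peak scales. A drop beginning between two strides is unobservable
   until the next burst, so any unbiased estimator is late about half the
   time; this last-normal-evidence convention is instead deliberately
   early (≤ ~one stride, late by at most ~one analysis window), the right
   bias for an alerting application. The alternative convention —
   measuring to the trough of the drop — would add the smoothing delay and
   is not used.
6. **Channel fusion.** Per-channel events overlapping on ≥ 2 thigh
   channels (quadriceps + hamstring, the consistent signature; calf
   channels are less reliable) merge into one session-level event spanning
   their union. Single-channel operation is available.

Matching assigns each event the earliest unclaimed annotated FOG onset
within (start, start + 10 s]; contested onsets go to the earlier event.
Lead time is onset − event start. `fold_change` is the ratio of mean RMS
over reference windows (active intervals minus *all* detected precursor
spans and annotated FOG intervals) to mean RMS inside the event; windows
straddling interval boundaries are excluded. Because the detected event
includes a short normal-amplitude sliver before the drop and the episode
itself, the recovered fold slightly underestimates 1/attenuation
(≈ 2.8–3.1 for a true 3).

## Statistics

`one_way_anova` computes the classical fixed-effects table from explicit
sums of squares (F = MS_between/MS_within, p from F(k−1, N−k)); scipy and
statsmodels serve as independent oracles in the tests. If every group has
zero internal variance the result is flagged degenerate with p = 0 (p = 1
when the means also coincide). `state_comparison` assigns envelope windows
to activity states (active/pause/set/walk/fog/precursor/normal) by
annotation intervals, excludes boundary-straddling windows, and reports
the ANOVA plus the ratio of group means. Two sampling units are offered,
because the appropriate n is ambiguous when windows are autocorrelated:
`window` (every window a sample; anticonservative under autocorrelation)
and `episode` (one mean per interval; conservative when interval lengths
differ, since longer reference segments have lower-variance means —
null-calibration tests therefore length-match the compared spans). No
claim is made to reproduce any particular p-value on real data.

## Reproducibility and problem sizes

Everything is deterministic given the spec seeds: same spec, same bytes.
The pipeline stamps outputs with a config hash and removes partial outputs
on failure. Test and acceptance problem sizes — a 110 s + 2 × 70 s cohort
at 1 kHz, 20-seed Monte-Carlo batteries, a 10,000-replicate ANOVA null —
were chosen so the full battery completes in well under a minute per
suite stage while keeping Monte-Carlo error far below the tested margins.

## Known limitations

- The detector assumes burst-modulated activity with a roughly stable
  stride period near 1 s; strongly irregular gait would widen the smoothed
  ripple and erode the 0.5-threshold margin.
- Onset refinement presumes the attenuated and normal burst-peak scales
  are separated (attenuation ≲ 0.6 at default settings); weaker drops are
  detected but with less accurate onsets.
- The causal baseline needs ~10 s of walking before the first episode.
- Fold-change and lead estimates are validated against the generator's
  ground truth, not against clinical annotations.
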