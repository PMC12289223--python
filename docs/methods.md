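# Methods

## The quantity being estimated

Baroreflex sensitivity (BRS) is the gain of the reflex that adjusts heart
period in response to arterial pressure: when transmural pressure at the
baroreceptors rises, the heart slows. In the frequency domain the reflex
shows up as coupled oscillations of systolic blood pressure (SBP) and RR
interval in the low-frequency (LF) band, 0.04–0.15 Hz, where the ~0.1 Hz
Mayer waves live. The nonparametric transfer-function estimate of BRS is

    H(f) = Pxy(f) / Pxx(f)

with x the per-beat pressure feature (SBP from an arterial line or volume
clamp, or a PPG surrogate) and y the RR series; the BRS index is the mean
|H| over the LF band, in ms/mmHg when the input is a pressure.

Because a finger PPG measures volume, not pressure, the package also
estimates BRS from pressure *surrogates* carried by the PPG: pulse arrival
time (PAT, the R-peak → pulse-upstroke delay, which shortens as pressure
stiffens the arteries) and the rise/decay-time ratio (RDRatio, the 10→70%
systolic rise time over the 70→10% diastolic decay time). Both couple
inversely to SBP, so the gain magnitude |H| keeps their BRS indices
positive; the phase is retained for inspection. A PAT-based index is in
ms per ms, an RDRatio-based one in ms per (dimensionless) RDRatio unit —
absolute values across surrogates are not comparable, correlations and
within-participant changes are.

## Processing chain

1. **Conditioning** — 4th-order Butterworth low-pass at 10 Hz, applied
   forward–backward (zero phase), followed by a central-difference first
   derivative in signal-units/s. The filter order is configurable; the
   double pass squares the magnitude response, which the tests verify
   against the closed-form bilinear-warped Butterworth response.
2. **ECG R peaks** — derivative-energy detection (band-limit 5–20 Hz,
   differentiate, square, 150 ms integration), adaptive threshold at 30%
   of the 99th percentile, 200 ms refractory, apex refinement with
   parabolic (sub-sample) interpolation. Peaks within 0.1 s of a record
   edge are suppressed: a truncated QRS cannot be confirmed.
3. **Pulse fiducials** — the upstroke is the per-beat maximum of the
   derivative. Candidate derivative peaks compete against the upper-half
   median of candidate heights within ±10 s, so an amplitude burst (motion
   artifact) cannot raise the bar for the rest of the record; the fraction
   (default 0.3) is configurable. The foot is found by walking back from
   the upstroke until the derivative falls below 20% of the upstroke
   slope; peak, dicrotic notch and secondary peak come from the
   derivative's sign changes after the upstroke; a shoulder is a local
   derivative maximum between peak and notch. Points absent from the
   morphology are reported absent (NaN), never fabricated. All time
   fiducials are invariant to amplitude scaling; the upstroke slope is
   homogeneous of degree one.
4. **Features** — RR_i = (R_{i+1} − R_i)·1000 ms. PAT pairs each R peak
   with the first upstroke inside 80% of the current RR (and never past
   the next R), which prevents cross-beat pairing; unpaired beats are
   missing with a reason code. PeakAmp is foot-referenced for PPG (the AC
   component; PPG baselines are arbitrary) and the absolute systolic value
   for pressure channels, where it *is* SBP. RDRatio threshold crossings
   use linear interpolation between samples — at 240 Hz the sub-sample
   correction changes RDRatio by several percent. Both limbs reference the
   same foot-to-peak amplitude.

## Spectral estimation

Beat series are linearly interpolated onto a uniform 4 Hz grid (beats at
R-peak times), linearly detrended, and Welch-averaged over 120-sample
Hann-tapered segments with 50% overlap, density scaling, segment-mean
removal. At this resolution (Δf = 1/30 Hz) the LF band contains three
bins (0.067, 0.100, 0.133 Hz). Gaps from disqualified beats are bridged
by the interpolation when ≤ 5 s; longer gaps reject the window. Windows
shorter than one segment after resampling are rejected as too short.

Coherence is computed from the averaged spectra and qualifies the whole
window when its LF mean reaches 0.14 — the conventional 95%-confidence
floor for this segmentation, kept as a configuration constant because it
depends on the (variable) number of averaged segments. Bin-wise coherence
masking is deliberately not the default: the interventional analysis
qualifies windows, not bins. The Welch path is validated against a direct
DFT oracle (raw segment periodograms, averaged) to 1e-10 relative error,
and the magnitude-squared coherence is clipped into [0, 1] against
floating-point excursions.

HRV band powers integrate the RR auto-spectrum over the LF and HF
(0.15–0.40 Hz) bands, in ms²; a pure tone of amplitude A recovers A²/2.

## Study pipelines

**Interventional.** Per participant × session × intervention a BRS index
is computed per feature/modality; the participant's value is the median
over the (three) sessions — the outlier-robust choice; the mean is
available as an option. Intra-participant precision is the sample SD
(n−1 throughout) of the pooled deviations from each participant's median,
expressed as a percent of the mean of the per-participant medians;
inter-participant variation is the sample SD of those medians over the
same mean. Note the definitional asymmetry: these percentages are
invariant to scaling but not to shifts. Index agreement is quantified
with Pearson correlation (Spearman computed and stored alongside, since
BRS indices need not be normal; both are reported in the output tables).

**Ambulatory.** BRS over 4-minute windows hopping 60 s (75% overlap);
windows starting on whole hops from the record start, the grid ending at
the nominal record end (a 24-h record at a 1-min hop yields 1437
windows). A window must hold ≥ 60 usable beats spanning ≥ 75% of the
window, else it is rejected with a reason. One-hour spans centred on a
15-minute grid take the median BRS over the coherence-qualified windows
inside them, the standard error over those same windows (the source
material computes the error bars over 15-minute segments but the medians
over 1-hour spans; this package computes both over the qualified windows
of the span and documents the choice here), their median coherence, and
the qualified-window percentage. HRV indices and heart rate are averaged
over the same spans. Cuff pressure readings are carried as reference
context only; no BRS is derived from them.

## Qualification criteria

Five criteria produce per-beat masks with machine-readable reasons; masks
only remove beats, merge by union, are idempotent, and criteria 1–4
commute (the epoch criterion integrates them and runs last):

1. **Cuff blanking** — beats within [start − 15 s, start + 60 s] of a cuff
   inflation (occlusion and its hemodynamic shadow).
2. **Template SNR** — each beat, resampled to 100 points foot-to-foot and
   offset/amplitude-normalised, is compared to the pointwise median of the
   5 consecutive beats centred on it; SNR = 10·log10(template power /
   residual power). The median tolerates up to two outliers per window, so
   isolated artifacts flag only themselves. The default threshold of 5 dB
   sits between the measured populations: clean rendered beats score above
   ~17 dB, uncorrelated noise below ~5 dB. This is an open
   reimplementation of the idea behind proprietary wearable quality
   indices, not a bit-faithful copy of any of them.
3. **PAT range** — with a fixed path length (default 0.8 m) and pulse-wave
   velocities limited to 2–10 m/s, valid PAT is 80–400 ms.
4. **Variability** — beat-to-beat relative jumps of RR or PAT above 25%
   (configurable) flag the beat; the first beat has no predecessor and is
   never flagged.
5. **Epoch** — per 1-minute epoch, the ECG beat count defines the expected
   cycles; if fewer than 50% (inclusive: exactly half qualifies) have a
   qualified pulse beat, the whole epoch is disqualified.

Amplitude normalisation in criterion 2 is a deliberate choice: pulse
amplitude varies physiologically with pressure, and morphology — not
amplitude — is the noise signature of interest.

## The synthetic-data generator

The generator is open loop so the true transfer gain is known
analytically: SBP carries an LF sine (default 3 mmHg at 0.1 Hz), an HF
respiratory sine (1.5 mmHg at 0.25 Hz; paced breathing moves this
frequency, legitimately into the LF band at 7 breaths/min), beat-to-beat
noise (1 mmHg), and a piecewise circadian baseline; RR responds to the
pressure deviation one beat later with the configured gain (default
8 ms/mmHg, a healthy mid-life value) plus 10 ms of noise. PAT and
RDRatio couple linearly and inversely to SBP (−1 ms/mmHg and
−0.005/mmHg); their noise levels (1.2 ms, 0.016) are calibrated so the
beat-level correlations with SBP are ≈ −0.90 and ≈ −0.62, the magnitudes
reported for real ambulatory data. With zero noise the least-squares
slope of RR on lagged SBP equals the configured gain exactly, and the LF
transfer gain equals it for reflex delays of a beat or two (delay only
rotates the phase).

Waveform rendering places a narrow Gaussian R spike (plus a small T wave)
at each beat time, and an asymmetric two-Gaussian pulse — rise and decay
half-widths chosen so the 10→70%/70→10% crossing-time ratio *equals* the
true RDRatio, plus a small late dicrotic bump — with its maximum-slope
point exactly at R + PAT. PAT is defined at the upstroke because that is
where it is measured; anchoring the foot there instead would offset every
recovered PAT by the foot-to-upstroke time. Pressure channels ride on an
80 mmHg diastolic baseline with the absolute peak equal to true SBP; the
PPG amplitude is proportional to SBP in arbitrary units. The first beat
is placed at 0.4 s and a 1.2 s tail is appended so no beat is
edge-truncated. Motion artifacts are broadband noise bursts on the PPG;
cuff inflations flatten it.

Scenarios: a 28-participant cohort (×3 sessions ×3 interventions, true
gains uniform in 4–12 ms/mmHg, paced breathing +11% gain with respiration
at 0.117 Hz, handgrip −22% gain with +8% pressure — the intervention
effect sizes observed interventionally); and a 24-h free-living day
(night 00:00–08:00 with doubled gain and 90-min alternating ±15%
sleep-cycle oscillations, two walks with gain ×0.6, raised heart rate
and pressure plus artifact bursts, cuff inflations every 30 min at night
and 15 min by day — 80 events).

### What the generator does and does not emulate

It reproduces the statistical structure the estimator relies on: LF/HF
pressure oscillations driving RR through a known gain, inverse PAT and
RDRatio couplings, day/night gain shifts, artifacts and cuff dropouts.
It does **not** close the reflex loop (a closed loop has no analytic
gain target to recover), does not model respiratory sinus arrhythmia
beyond the additive HF term, pre-ejection-period variation, realistic
ECG morphology beyond R-peak detectability, or non-Gaussian artifact
statistics. Passing the recovery tests therefore demonstrates estimator
correctness under the assumed generating model, not clinical validity on
real recordings.

## Numerical and design notes

- Sampling: rendering at 240 Hz by default (configurable, ≥ 60 Hz for
  pulse morphology; ambulatory prototypes may run lower). Time is seconds
  from record start.
- Problem sizes in the validation runs are chosen for desk-scale
  reproducibility: 300 s trials for gain recovery (50 seeds), 120 s rest
  trials in the cohort, beat-level (unrendered) series for the 24-h
  profile — the ambulatory pipeline consumes a beat table, so waveform
  rendering is only exercised on short segments where the fiducial chain
  itself is under test.
- The interventional and ambulatory estimators share the same spectral
  core, so on identical data they agree identically by construction.
- Degenerate inputs: flat ECG yields an empty peak list with a warning
  (not an exception); fewer than 5 beats flags all beats for SNR; a zero
  grand-mean BRS makes the precision percentages undefined and raises;
  zero variance makes correlations NaN with a degenerate flag.
- EDF records are read through `mne` when installed; the native format is
  a documented CSV dialect (one column per channel, YAML sidecar with
  sampling rate, units, roles) with lossless round-trip. WFDB is not
  supported in this build.

## Known limitations

- The 0.14 coherence floor is a configuration constant, not derived at
  run time from the realised segment count.
- The SNR criterion's threshold is an empirical package default; vendor
  thresholds are unpublished and no bit-level faithfulness is claimed.
- Open-loop simulation means closed-loop phenomena (causality in both
  directions between pressure and RR) are out of scope, as are the
  sequence (time-domain) BRS method and phase-rectified signal averaging.
- PAT recovered from rendered waveforms carries a ~2.5 ms systematic
  offset from the 10 Hz low-pass acting on the asymmetric pulse; it stays
  below one sample at 240 Hz and cancels in the (slope-based) BRS.
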