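# Methods

`neoqeeg` re-implements, as a tested pipeline, the electrophysiological and
histological analysis used in preclinical neuroprotection studies of
neonatal hypoxic–ischemic encephalopathy (HIE) in newborn piglets: 48 h of
multi-channel EEG after a 20 min asphyxic insult, flash visual evoked
potentials (VEPs), and neuropathology scoring, compared across three arms —
untreated normothermia (A-NT), inhaled molecular hydrogen (A-H2), and
therapeutic hypothermia (A-TH, 33.5 °C). Because raw recordings from such
studies are rarely deposited, the package pairs every analysis stage with a
synthetic cohort generator that reproduces the statistical structure the
analysis assumes, so each stage is exercisable and testable end to end.

## Synthetic cohort generator

### Background EEG

Background activity is amplitude-modulated Gaussian noise with a
1/f^α spectrum band-limited to the 1–30 Hz analysis range. The RMS envelope
follows the canonical post-asphyxia course:

- baseline amplitude (default 30 µV RMS) before the insult,
- exponential collapse to an isoelectric floor (1.5 µV) during the 20 min
  asphyxia (time constant 2 min),
- a flat isoelectric interval (default 2 h), then
- exponential recovery toward baseline with a per-arm time constant
  (12 h untreated, 10 h hydrogen, 16 h hypothermia).

The spectral exponent α is the per-arm knob that shapes the recovered
signal's complexity: 1.8 (A-NT), 1.4 (A-H2), 2.2 (A-TH). A flatter spectrum
(smaller α) yields higher spectral edge frequency and entropy, which is how
the generator encodes the published group ordering (H2 highest, TH lowest)
without hand-setting the markers themselves. Burst suppression is not
modelled; the envelope is the only non-stationarity.

### Timeline compression

A full cohort at true scale (22 animals × 48 h × 8 ch × 256 Hz) is far too
large for routine testing. The generator therefore accepts a
`timeline_compression` factor C (default 240): one actual second of signal
stands for C nominal seconds. Durations (envelope time constants, seizure
episodes, onsets) are compressed; spectral content (the 10 Hz discharge
rate, the 1/f shape, the 256 Hz sampling) is **not**. Every algorithm runs
unchanged on the actual signal; burden and onset summaries are rescaled
back to nominal hours using the factor carried on the recording. At C = 240
each animal is a 740 s record (≈ 1.5 M samples/channel cohort-wide), and
the full pipeline runs in well under a minute per arm.

### Seizures

Seizing is arm-structured: probability of any seizure 5/6 (A-NT, matching
one seizure-free untreated animal), 1.0 (A-H2), 0.0 (A-TH). A seizing
animal draws

- an onset uniform in the arm's window — 24–32 h (A-NT) vs 30–38 h
  (A-H2), encoding the delayed hydrogen onset;
- a total burden from a gamma distribution with mean 3.4 h (A-NT) or
  3.1 h (A-H2) and shape 4 (coefficient of variation 0.5, a realistic
  spread against the published SEMs);
- an episode count 1 + Poisson(1.5), with the burden split by a
  Dirichlet(4) weight vector and episodes spaced by Dirichlet-partitioned
  gaps between onset and the end of observation (so episodes never overlap
  and always fit).

Episodes are generalized spike-and-wave trains added to all channels: one
period of the kernel is a biphasic 20 ms spike followed by a positive slow
wave filling the rest of the discharge cycle, unit-RMS normalized, tiled at
the discharge rate (default 10 Hz) and scaled to `amplitude_gain` (default
6) times the local background RMS. Annotations record each injected
interval exactly; the signal outside is bit-identical.

### VEPs, schedules, pathology

VEP trials follow the standard flash protocol — 10 trains of 10 flashes at
1 Hz with 10 s between trains, i.e. 100 trials per grand average. Each
trial is a deterministic template (a P100-dominated positive peak, 12 ms
Gaussian width, preceded by a small N70 trough) plus independent white
noise (default 5 µV on a 10 µV peak). Arm templates differ only in latency:
105 ms (A-NT), 102 ms (A-H2), 90 ms (A-TH); amplitudes are equal by
construction so the amplitude comparison is a true null.

Temperature schedules are piecewise linear: normothermic arms hold
38.5 °C; the cooled arm reaches 33.5 °C 47.5 min after reventilation, holds
until hour 37, rewarms at 0.5 °C/h for 10 h and holds the setpoint for the
final hour.

Pathology has two data types. Count regions (CA1, CA3, caudate, putamen,
thalamus) draw damaged ~ Binomial(200, p) per animal with arm-specific p:
thalamus 0.92 untreated vs 0.15 under either treatment (near-complete
injury, strongly protected); other regions 0.08–0.12 everywhere (low
injury, no protection signal). Neocortical regions (frontal, parietal,
temporal, occipital) draw 40 field severities per region from a
Dirichlet-categorical: per animal/region class probabilities ~
Dirichlet(60 × [0.72, 0.22, 0.05, 0.01]) over
none/scattered/grouped-laminar/panlaminar, identical across arms.

All randomness flows from a single `numpy` SeedSequence; identical
(spec, seed) gives byte-identical written cohorts.

## Preprocessing and spectral markers

Broadband filtering is a zero-phase (forward–backward) 4th-order
Butterworth bandpass at 1–30 Hz; the double pass gives > 40 dB attenuation
one octave beyond either edge while preserving evoked-potential latencies.
Band decomposition (delta 1–4, theta 4–8, alpha 8–13, beta 13–30 Hz) uses a
zero-phase spectral partition (complementary brick-wall masks) rather than
an IIR filterbank: the masks tile the analysis band exactly, so the four
band powers are additive and sum to the broadband power — a property a
twice-applied IIR bank misses by ~12% at the crossovers.

PSDs are Welch estimates with a Gaussian taper. The taper's kernel size k
(window length over standard deviation) defaults to 4, in the conventional
3–5 range; segments default to 4 s with 50% overlap inside a 30 s analysis
window (at compression, windows of ≥ 2–4 s of actual signal are used
instead — the 1 Hz grid, not the nominal epoch, is what matters).

Two scalar markers per channel and epoch:

- **SEF95** — the smallest grid frequency f with cumulative power
  ≥ 0.95 × total over 1–30 Hz, evaluated on the discrete grid without
  interpolation (reproducible and directly oracle-checkable).
- **Instantaneous spectral entropy** — Shannon entropy of the normalized
  bin powers divided by log N (N grid bins), hence unitless in [0, 1],
  base-invariant: 0 for a pure rhythm, 1 for a flat spectrum.

Epochs with RMS below 2 µV are flagged suppressed (isoelectric) and carry
NaN sentinels; they are excluded from all group summaries. Group values
default to the **terminal** reading (last non-suppressed epoch per channel,
averaged over channels then animals), matching end-of-observation
reporting; a whole-record mean mode is also provided.

Baseline normalization divides each band-power series by its mean over a
pre-asphyxia baseline interval (the generator provides a 1 h baseline
segment); zero baseline power is an explicit error.

## Seizure detection

Detection runs on a finer epoch grid than the qEEG markers: 2 s epochs,
half-overlapped, with half-epoch Welch segments (1 Hz resolution, three
averaged periodograms — enough to stabilize the entropy feature).
Features per channel and epoch: spectral entropy, RMS amplitude, and line
length (mean absolute first difference).

Flagging is a two-pass robust scheme against a trailing background window
(10 nominal minutes, floored at 120 actual seconds under compression so a
single compressed episode cannot dominate its own reference):

1. provisional pass — epochs with RMS ≥ `a_thr` (3.0) times the trailing
   30th percentile of epoch RMS are marked; a low quantile stays unbiased
   even when discharges fill much of the window;
2. final pass — with provisional epochs excluded, the trailing median/MAD
   of entropy and the trailing median RMS are re-estimated, and a channel
   flags an epoch when its entropy z-score ≤ −`z_thr` (2.0) **and**
   RMS ≥ `a_thr` × median. Suppressed epochs never flag, so no event can
   appear inside an isoelectric span.

Epochs flagged on ≥ 25% of channels form candidate runs; runs merged over
gaps ≤ 10 nominal seconds and lasting ≥ 10 nominal seconds (floored at one
epoch plus one hop) become events. An event is "generalized" when ≥ 75% of
channels co-flag; its dominant frequency is the argmax of the mean Welch
PSD over the event interval (1 Hz bins), and its peak amplitude the maximum
absolute sample. Summaries rescale to nominal hours: per-animal total
burden, onset latency (undefined when seizure-free) and event count, plus a
per-arm incidence/onset/burden table.

On generator defaults the detector recovers injected burden within a few
percent (the tested invariant is < 15% averaged over 20 records) and emits
zero events on 20 seizure-free hypothermia records.

## Evoked potentials

Trials are baseline-corrected (mean over −50–0 ms subtracted per trial)
and averaged pointwise; with independent noise the residual noise RMS
scales as 1/√n. The P100 is the maximal positive deflection in a 70–150 ms
search window; latency is its time, amplitude its height above the
(already-zeroed) baseline. A waveform with no positive deflection in the
window returns an explicit absent-response flag rather than a number.
Group comparison reports mean ± SEM per arm and a one-way ANOVA with Tukey
HSD for latency and amplitude (a single terminal time point; the two-way
treatment × time machinery in `stats` is available when multiple time
points exist).

## Neuropathology scoring

Count regions report percent damaged = 100 × damaged/total (total > 0
enforced). Neocortical regions are scored 0–9 from the 40 field severities
by a severity-by-frequency rule: with worst observed severity rank
s ∈ {1 scattered, 2 grouped/laminar, 3 panlaminar} and t the tertile of the
number of fields at that severity (≤ 13 → 1, ≤ 26 → 2, else 3),

    score = 0 if all fields intact, else 3·(s − 1) + t.

The mapping is monotone in both worst severity and its frequency,
permutation-invariant in field order, and replaceable by a user-supplied
lookup (the published scale is ordinal; this concrete table is the
package's documented choice). Per-animal cortical sums are taken over the
four lobar regions (range 0–36).

## Statistics

Normality (Shapiro–Wilk) and variance homogeneity (Levene, mean-centred)
delegate to scipy. One-way ANOVA uses scipy with Tukey HSD (plus pooled-t
unadjusted p-values for reference); two-way between-measurements ANOVA
(treatment × time) uses statsmodels with Type II sums of squares — the
design may be unbalanced, and repeated-measures modelling is deliberately
out of scope. Kruskal–Wallis (tie-corrected) is followed by Dunn's
pairwise z on mean ranks with the tie term Σ(t³ − t)/(12(N − 1));
family-wise correction is none by default (matching common "Dunn's multiple
comparisons" reporting), with Bonferroni and Holm options. A Welch t test
from summary statistics (means, SEMs, group sizes, Welch–Satterthwaite df)
is provided for checking published group summaries when raw data are
unavailable. All tests are calibrated: under their nulls the rejection rate
at α = 0.05 over 2000 simulations sits within [0.035, 0.065] in the test
suite.

## Problem sizes and numerical choices

- Test and acceptance runs use compression 240 (one animal = 740 s of
  8-channel 256 Hz signal); burden-recovery checks average ≥ 10 (tests)
  or 20 (acceptance script) independently seeded single-arm cohorts.
- SEF is grid-valued (no interpolation); entropy uses natural logs
  normalized by log N; suppression threshold 2 µV RMS; MAD is floored at
  1e-12 to avoid division by zero on constant features.
- EDF output is 16-bit with per-channel symmetric physical ranges, so
  round-trip error is at most one quantization step; a trailing partial
  record is zero-padded on disk and trimmed on read via a reserved-field
  sample count. Annotations travel in a plain-text sidecar CSV.
- Welch-vs-permutation and ANOVA-vs-brute-force agreements are asserted at
  the tolerances stated in the tests (e.g. Dunn within 0.02 of the
  exhaustive permutation null for three groups of five).

## What the synthetic data does and does not show

The generator reproduces the *statistical structure* the analysis assumes:
suppression and recovery envelopes, arm-specific spectral shape, clustered
late generalized discharges with configured burden/onset distributions,
template-plus-noise VEPs, binomial/Dirichlet pathology with a strong
thalamic treatment effect. It does not emulate real-world recording
artifacts (movement, electrode drift, mains pickup), focal or evolving
seizure morphologies, burst suppression, rescue-medication truncation of
episodes (the published burdens reflect treated seizures, so burden
comparisons are distribution-level only), or biological coupling between
EEG recovery and histology. Passing tests therefore demonstrate that the
algorithms are correct and well-calibrated on data satisfying their
assumptions — not that the detector or markers would achieve the same
accuracy on raw clinical recordings.

Other deliberate scope limits: no artifact rejection or re-referencing
(records are treated as already referenced), no amplitude-integrated EEG or
connectivity metrics, no N70/N145 or steady-state VEP components, no image
segmentation (pathology starts at counts/categories), and no modelling of
blood chemistry or drug pharmacokinetics.
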