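# Methods

## Overview

The package quantifies stress-induced sympathetic arousal from
multi-wavelength wrist photoplethysmography (PPG). Sympathetic activation
constricts cutaneous vessels, which lowers the pulsatile (AC) component of
the PPG and makes its beat-to-beat variation more regular. The analysis
chain is:

1. estimate the mean inter-beat interval (IBI) spectrally;
2. filter the raw trace with IBI-adaptive windows and detect the systolic
   peak and pre-systolic onset of every beat;
3. form the per-beat AC series `AC_k = |signal[peak_k] − signal[onset_k]|`
   and filter it for outliers;
4. cut each stressor epoch into four phase windows — 2-min baseline,
   1st stressor minute, 2nd stressor minute, 2-min recovery — and compute
   eight features per window;
5. compare phases across subjects with two-sided Mann–Whitney U tests and
   the AUC `U/(n₁n₂)`.

Because the package is exercised entirely on synthetic cohorts, every
stage is scored against exact generator ground truth.

## Fiducial detection

The mean IBI is `1/f₀` where `f₀` is the periodogram argmax in 0.8–3 Hz
(48–180 beats/min). Filtering is three-stage and IBI-adaptive:

* **w1** — centred median filter then centred moving average, both with an
  odd window of `round(0.2·IBI·fs)` samples (edges by reflection);
* **w2** — third-order low-pass Butterworth at `1.5·f₀` Hz applied
  forward–backward. The cutoff is read as 1.5 × the spectral peak
  *frequency*: a cutoff proportional to the IBI in seconds would fall
  below the pulse fundamental for heart rates under 90 bpm. Zero-phase
  application keeps fiducial timing unbiased; the effective attenuation is
  the squared magnitude response (verified in tests against the
  closed-form response of the bilinear design).
* **baseline** — centred moving average of w2 over `round(1.5·IBI·fs)`
  samples; subtracted wherever a drift-free signal is needed.

Peak candidates are the per-tile argmax of `w2 − baseline`, one tile per
IBI. A candidate is rejected when its height falls below 30% of the
running median height of the last 10 accepted peaks, or lies closer than
0.5 IBI to the previous accepted peak (the taller of the pair is kept).
Two recovery passes follow. First, any inter-peak gap longer than 1.5
estimated IBIs is re-searched (the fixed tiling merges beats whenever the
instantaneous IBI is shorter than the estimate); because these search
windows start at least 0.5 IBI away from accepted peaks — outside dicrotic
territory — the height test there uses a lower 15% threshold against the
10 nearest accepted peaks, which keeps genuinely small beats in fast runs.
Second, every accepted peak is re-checked against its local neighbourhood
(removing edge artefacts that predate the running median) and relocated to
the maximum of `w1 − baseline` within a quarter IBI, undoing the smoothing
shift of the heavy low-pass.

Onsets are the minima of `w1 − baseline` strictly between consecutive
peaks (earliest sample on ties), refined to the minimum of a 5-sample
centre average of the raw trace within ±12 samples. The refinement uses
the raw signal *without* baseline correction: the window is already
anchored by the detrended minimum, and the baseline's local slope tilts a
shallow diastolic valley by several samples. On noise-free input this
makes the onset exact; under noise the onset of a flat valley is
intrinsically jittery (tens of ms), which is why the noisy-regime accuracy
targets apply to peaks.

AC amplitudes are measured on w2 (the filtered pulsatile trace). Beats
whose AC falls outside median ± 3 scaled MAD of the recording are masked
out, and masked beats never enter the feature windows.

## Features

For a window `X = {x₁ … x_N}` of AC amplitudes (≈140 beats for 2-min
windows, ≈70 for 1-min windows at 70 bpm):

* **mean, sd** — population form (divisor N).
* **Katz** — `log(S/M)/log(d/M)` on the planar curve `(i, x_i)` with unit
  abscissa step; `S`/`M` are the total/mean successive-point distances and
  `d` the largest distance from the first point. The embedding (unit index
  step) is a documented convention.
* **Petrosian** — binarize at the window mean, count sign changes `N_Δ`,
  return `log₁₀n / (log₁₀n + log₁₀(n/(n + 0.4·N_Δ)))`.
* **Higuchi** — least-squares slope of `log⟨L(k)⟩` on `log(1/k)` for
  `k = 1…k_max`, `k_max = 8` (windows must hold ≥ 2·k_max beats);
  `L_m(k)` uses the standard `(N−1)/(⌊(N−m)/k⌋·k²)` normalization.
* **SampEn** — `ln(B/A)` with Chebyshev template distance, embedding
  `m = 2`, tolerance `r = 0.15·sd`, self-matches excluded; both the m- and
  (m+1)-dimension embeddings use `N−m` templates. When either match count
  is zero the value is undefined and propagates as an explicit missing
  value — never a numeric placeholder — and group statistics use defined
  values only.
* **Entropy profile, TotalSampEn, AvgSampEn** — SampEn evaluated over the
  data-driven tolerance grid: the distinct positive m-template distances
  after quantization to an amplitude resolution of 0.001 signal units
  (grids above 1000 points are uniformly subsampled). Grid points with a
  zero match count are excluded; `q` is the number retained. TotalSampEn
  is the sum and AvgSampEn the mean over the profile, so
  `TotalSampEn = q · AvgSampEn` holds exactly.

The quantization step deserves emphasis. For continuous-valued data every
pairwise distance is distinct, so the raw number of grid points would be
`(N−m)(N−m−1)/2` regardless of the signal's regularity. Real acquisition
chains resolve amplitude finitely, producing heavy distance ties; `q` then
scales with the window's spread and becomes the regularity-sensitive
quantity that drives the profile features: vasoconstriction shrinks the
spread, `q` roughly halves, TotalSampEn falls with it, while AvgSampEn
(dominated by the shorter 1-minute stressor windows and the irregularity
floor described below) rises. The default resolution of 0.001 units
(≈ 0.1% of the green-channel AC mean, a 10–12-bit-ADC scale) gives profile
sizes of a few hundred points per window.

SampEn(r) along the profile is a strongly decreasing but not strictly
monotone function of r: each grid step changes integer match counts, and
`ln(B/A)` ticks upward wherever B gains a pair and A does not. Tests
therefore assert the exact monotonicity of the counts and a strong
decreasing trend (Spearman < −0.9) rather than strict monotonicity.

## Phase windows and statistics

Windows are half-open time intervals `[start, end)`; a beat exactly on a
boundary belongs to the later window, so the two stressor minutes
partition the epoch and no beat is counted twice. Windows are time-based
(fixed 60/120-s spans, variable beat counts). A recovery window running
past the record end is truncated and flagged.

Contrasts are A = baseline vs 1st minute (onset), B = 1st vs 2nd minute,
C = 2nd minute vs recovery (offset). The Mann–Whitney test is two-sided
and unpaired — the phases are treated as independent samples, which is the
test named, although a paired-by-subject alternative exists; no
multiple-testing correction is applied, and significance is reported in
tiers (p < 0.05, p < 0.01). Both groups ≤ 8 observations: the p-value is
computed by full enumeration of all `C(n₁+n₂, n₁)` labelings with
tie-aware U (0.5 per tied pair), which equals the exact rank distribution
when ties are absent; larger samples use the normal approximation with tie
and continuity corrections. AUC is reported as computed for the
first-named phase (no orientation flip), rounded half-away-from-zero to
one decimal in the summary table, with values ≥ 0.8 flagged. Reported
AUCs in comparable real-data studies appear orientation-free (all ≥ 0.5);
here the contrast order (baseline, min1) already puts the vasoconstriction
effect above 0.5 for TotalSampEn.

## Synthetic cohort generator

Each subject is a pulse train rendered at 100 Hz for the protocol
10 min baseline + 2-min stressor + 5-min recovery + 2-min stressor +
5-min recovery (24 min); the two stressors (Cold Pressor, Hand Grip) are
delivered in seeded random order and the schedule is emitted explicitly.

* **Pulse shape** — two wrapped-Gaussian (von Mises) lobes in beat phase:
  a broad systolic lobe (κ = 0.8 at phase 0.30) and a smaller dicrotic
  lobe (weight 0.15, κ = 4, phase 0.62), normalized to [0, 1].
  Broad lobes give the diastolic valley real curvature, which is what
  makes the onset a well-conditioned fiducial; narrow-lobed templates have
  near-flat valleys whose minima are unstable to any tilt.
* **IBI dynamics** — AR(1) around the subject mean (coefficient 0.4),
  beat-to-beat sd 4 bpm (≈ 50 ms, a typical short-term HRV magnitude),
  clipped to 50–180 bpm; subject means vary with sd 6 bpm around 70 bpm.
  Heart-rate parameters outside 50–180 bpm are rejected.
* **AC dynamics** — per-beat amplitude AR(1) (coefficient 0.6, mean 1.3,
  sd 0.30 before channel gain, subject-level log-normal scale cv 0.15)
  plus white beat-level jitter (sd 0.12). During a stressor epoch the AR
  mean is multiplied by `1 − stressor_ac_drop` (default 0.2) and the AR
  innovation sd by `1 − stressor_regularity_gain` (default 0.5); the white
  jitter is *not* damped — it models residual micro-vasomotor and
  measurement variability that vasoconstriction does not suppress, and it
  is what keeps stressor windows relatively irregular at small scales (the
  behaviour real AC series show, where AvgSampEn rises under stress even
  as the overall spread falls). Amplitudes are floored at 50% of the
  regime mean: clean recordings do not show near-zero beats, and the floor
  keeps every true beat above the detector's height criterion even after
  low-pass attenuation of short-IBI beats.
* **Channels** — gains green 1.0, blue 0.75, ir 0.52, red 0.52 (ordering
  chosen to mirror typical reflective-PPG AC magnitudes per wavelength),
  additive white noise sd ≈ 0.05 per channel, a common 0.5-amplitude
  0.05 Hz baseline wander per channel with random phase, and a constant
  DC level. No optical tissue model, motion artefacts or respiration
  modulation are simulated.
* **Ground truth** — peak/onset times are the extrema of the rendered
  noise-free pulsatile signal itself, the AC truth is peak-minus-onset on
  that signal, and truth validation (alternation, positivity) runs on
  every subject. Per-subject seeding is counter-based
  (`SeedSequence(seed, spawn_key=(subject,))`), so enlarging a cohort
  never changes earlier subjects.

What the generator does *not* emulate — motion artefacts, respiratory
modulation, optical wavelength physics, slow autonomic recovery dynamics —
bounds what passing tests show: they demonstrate that the pipeline
recovers known beat structure and known effect directions under
physiologically scaled variability, not that it is robust to real-world
artefact regimes.

## Problem sizes and numerical choices

The shipped analyses use 32-subject cohorts (≈ 1700 beats/subject, four
wavelengths), eight-subject sets for fiducial scoring, 2000 simulated
comparisons for null calibration of the 0.05 tier, and five independent
cohorts for the effect-direction check; these sizes give stable estimates
while keeping a full run in minutes on one core. Matching tolerance for
fiducial scoring is ±3 samples (30 ms at 100 Hz), inclusive. Feature
preconditions (window length, non-degeneracy) convert to missing values at
the table level and to errors at the function level. All file outputs are
plain CSV written with a fixed float format, so a rerun with the same
configuration is byte-identical.

## Known limitations

* Onset timing under noise is limited by diastolic valley flatness; at
  20 dB SNR about 80–90% of onsets land within 30 ms (peaks: > 99.9%).
* The Mann–Whitney test treats phases as independent samples; with
  paired-by-subject data a paired test would be more powerful.
* The entropy-profile grid depends on the amplitude resolution parameter;
  analyses of data with a very different dynamic range should set
  `r_resolution` to their instrument's resolution.
* The exact enumeration path for the rank test is O(C(n₁+n₂, n₁)) and is
  capped at group sizes of 8.
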