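# ppgstress

Quantifying stress-induced sympathetic arousal from multi-wavelength
photoplethysmography (PPG).

When a physical stressor (a cold-pressor test, a sustained hand grip)
activates the sympathetic nervous system, cutaneous vasoconstriction
reduces the pulsatile blood-volume signal a wrist PPG sensor sees. This
package implements the full analysis chain for detecting that response in
the beat-to-beat **AC amplitude** series of green, blue, infrared and red
PPG channels, and a synthetic cohort generator with exact beat-level
ground truth so the whole chain is testable without device data. It is
aimed at researchers prototyping wearable stress-detection pipelines.

## Method core

Per channel, the mean inter-beat interval is the reciprocal of the
periodogram argmax in 0.8–3 Hz; IBI-adaptive filters (centred median +
moving average, zero-phase 3rd-order Butterworth at 1.5·f₀, slow
moving-average baseline) prepare the trace; systolic peaks and
pre-systolic onsets are detected with height/spacing false-peak criteria,
and each beat contributes `AC_k = |x[peak_k] − x[onset_k]|`.

Eight features summarise each stressor-phase window (2-min baseline,
1st and 2nd stressor minute, 2-min recovery) of the AC series
`X = {x_1..x_N}`: mean and population s.d.; Katz, Petrosian and Higuchi
fractal dimensions; sample entropy

    SampEn(m, r) = ln( B(r) / A(r) ),   m = 2,  r = 0.15·sd,

with B and A the m- and (m+1)-template Chebyshev match counts
(self-matches excluded); and the entropy-profile features

    TotalSampEn = Σ_{r ∈ R} SampEn(r),   AvgSampEn = TotalSampEn / q,

where R is the data-driven set of q distinct template distances (after
quantization at the amplitude resolution) — the tolerances at which the
match counts change. Phase contrasts are scored with two-sided
Mann–Whitney U tests (exact enumeration for small groups, tie/continuity
corrected normal approximation otherwise) and the AUC `U/(n₁n₂)`.

## Worked example

Run the numbered analyses (each is a thin driver over the library):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_detect_fiducials.py
python analysis/03_extract_features.py
python analysis/04_group_statistics.py
```

`04_group_statistics.py` prints, for the default 32-subject cohort
(seed 1):

```
TotalSampEn onset detection (contrast A) AUC by cell:
stressor      CP    HG
wavelength
blue        1.00  1.00
green       1.00  1.00
ir          0.98  0.99
red         0.99  0.99
flagged (AUC >= 0.8): 8/8 cells

AvgSampEn cohort means by phase:
phase       baseline   min1   min2  recovery
blue           0.423  0.442  0.461     0.430
green          0.439  0.460  0.481     0.438
ir             0.407  0.423  0.434     0.405
red            0.404  0.423  0.439     0.405

TotalSampEn cohort means by phase:
phase       baseline   min1   min2  recovery
blue           301.0  174.6  181.9     302.7
green          385.5  222.2  230.2     386.9
ir             210.0  132.1  134.9     211.3
red            211.7  131.6  135.4     211.6
```

Reading this: during the stressor the AC series becomes smaller and more
regular, so the number of distinct profile tolerances q roughly halves and
**TotalSampEn collapses** (e.g. green 385 → 222), recovering fully
afterwards — separating baseline from the first stressor minute with
AUC ≈ 1 in every wavelength × stressor cell. **AvgSampEn moves the
opposite way** (0.44 → 0.46 → 0.48 on green), because the stressor
minutes are shorter windows with fewer tolerances and a retained
small-scale irregularity floor. Mean and s.d. of the raw AC separate the
phases far less well — the entropy-profile features are the sensitive
ones.

The same pipeline is scriptable from the shell:

```bash
ppgstress simulate --n-subjects 4 --seed 7 --out data/
ppgstress fiducials --in data/ppg_s000.csv --channel ir --out fiducials.csv
ppgstress features --ppg-dir data/ --out features.csv
ppgstress analyze --features features.csv --out report/
ppgstress run-all --n-subjects 32 --seed 1 --out report/
```

Input records are plain CSV with columns `time,green,blue,ir,red`
(100 Hz); the event schedule is `stressor,onset_s,end_s`.

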