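# Methods

## The measurement model

An ICG fluorescence recording of one ROI is a sampled curve *I(t)*, 120 s
long. The pipeline derives, per measurement:

1. **Injection onset.** The first five samples are treated as guaranteed
   pre-injection. Onset is the first time the intensity strictly exceeds
   `background_mean + 3·background_sd` for at least three consecutive
   samples; the background statistics are then recomputed over all samples
   strictly before that onset and the scan repeated once. The 3-SD /
   3-sample rule makes detection robust to single-frame noise at 5 Hz
   sampling. If the curve never crosses, the measurement is flagged
   `no-signal` (onset placed at the recording end).
2. **First-passage window.** The analysis sequence is 60 s from onset,
   ended early at the recording end (flagged `truncated-window`) or at the
   first local minimum after the in-window global maximum — the trough that
   separates the first passage from recirculating dye. Trough detection
   runs on the smoothed curve and requires a prominence of at least 2% of
   the in-window intensity range, so sample-level noise ripples do not
   truncate the window.
3. **BSFI** = (maximum raw intensity inside the window) − background mean,
   floored at 0. Flooring matters only for no-signal curves, where noise
   could otherwise produce a meaningless negative perfusion value.
4. **SFI** = maximum centered finite difference
   `(I[k+1] − I[k−1]) / (t[k+1] − t[k−1])` of the smoothed curve inside the
   window, restricted to samples at or before the smoothed in-window peak
   (the rising limb; post-peak rebounds are not "the increase"), floored
   at 0. Smoothing is a centered moving average, default window 1.0 s,
   truncated symmetrically at the curve ends.
5. **Ratios.** Each measurement is normalised against the *same animal and
   ROI* at baseline (T0): `bsfi_ratio = BSFI / BSFI_T0`, likewise SFI.
   Ratios are per-measurement, never ratios of group means (a ratio of
   means is not a mean of ratios). A baseline with zero or flagged
   BSFI/SFI raises an explicit error instead of emitting infinity, because
   downstream summaries are log-scale.

Whether the 60-s sequence should start at injection or at dye arrival is
ambiguous in the field; this implementation starts it at the detected
arrival, which is also the only choice available when the injection time is
not logged. SFI is computed on the smoothed curve by declared convention —
raw 5-Hz finite differences are dominated by noise.

Invariances that follow from these definitions (and are enforced by
tests): adding a constant to the whole curve changes neither BSFI nor SFI;
multiplying the curve by a gain g scales both by exactly g; ratios are
invariant to a gain applied to both measurement and baseline; a
measurement's self-ratio is exactly 1.

## Viability scoring

The macroscopic score sums four component grades (color, peristalsis,
edema formation, mesenteric hemorrhage), each 1 (normal) to 4 (worst), so
totals span 4–16; categories are none/mild (< 6), moderate (6–9, both
boundaries inclusive), severe (> 9). The 1–4 component scale is the
minimal one consistent with a healthy floor of exactly 4 and a ceiling of
16; per-component anchors (what earns a 2 vs a 3 for "color") are
rater conventions and are not encoded.

The Chiu grade is assigned as the highest grade whose defining features
are all present: 5 — lamina propria disintegration + hemorrhage +
ulceration; 4 — lamina propria denuded + dilated capillaries exposed; 3 —
massive epithelial lifting + denuded villus tips; 2 — extended
subepithelial space + at least moderate lifting; 1 — any subepithelial
(Gruenhagen) space; 0 — normal mucosa. Grades 1–2 follow the canonical
Chiu rubric. The ordinal features use "at least" semantics (e.g. an
extended subepithelial space satisfies the grade-1 criterion) so that the
grade is monotone: adding a deeper-injury feature can never lower it. The
only hard consistency constraint on descriptors is that disintegration of
the lamina propria implies the lamina propria is denuded; shallower
features are not force-implied, so partial assessments remain
representable.

## The synthetic-data generator

### Curve model

A standard single-tissue indicator-dilution form:

    S(t) = b + drift·t + F·[(1−L)·(AIF ⊛ e^{−w t}) + L·(AIF ⊛ 1)] + ε(t)

with gamma-variate arterial input function
`AIF(t) = A·((t−d)/s)^k · e^{−(t−d)/s}` for t ≥ d (else 0) plus a single
recirculation echo `r·AIF(t − t_r)`, and i.i.d. Gaussian camera noise
ε. Convolutions are evaluated by the trapezoidal rule on the sampling
grid; the leak term `AIF ⊛ 1` is the running integral of the AIF. The leak
fraction L is the mechanistic stand-in for capillary damage: that portion
of delivered dye extravasates and pools with no washout, which is what
produces post-reperfusion hyperintensity in damaged tissue.

Defaults (all configurable): baseline offset b = 5 a.u.; AIF delay 5 s,
shape 3, scale 3 s, amplitude 1; recirculation fraction 0.15 at 30 s;
washout rate 0.12 /s; camera noise SD 0.4 a.u.; drift 0. Recording length
120 s at dt = 0.2 s (5 Hz) — a convention, not a claim about any
particular camera; it resolves the 5–15-s first-passage upslope with ≥ 25
samples. The inflow rate at baseline flow is F = 2.27 /s, calibrated
(once, numerically) so that control-tissue BSFI at baseline is ≈ 16 a.u.,
placing simulated magnitudes in the range typical of in-vivo baseline
measurements without claiming to reproduce any specific table; the implied
baseline SFI is ≈ 2 a.u./s.

### Design defaults

Regional inflow scales linearly with relative blood flow
(69.7 ml/min = 1.0):

| cell | relative inflow | leak L |
|---|---|---|
| all ROIs, baseline T0 | 1.0 | 0 |
| D1 (ischemic), occlusion T1 | 0 (complete clamp) | 0 |
| D3 (control), T1 | 1.3 (flow redistribution) | 0 |
| D2 (transitional), any phase | 0.5·D1 + 0.5·D3 | 0.5·L(D1) |
| D1, reperfusion | group hyperemia factor g | I: 0, II: 0.35, III: 0.30 |
| D3, reperfusion | max(1.15, g) | 0 |

with g = (60.7, 97.1, 142.5)/69.7 for 3/6/10 h of ischemia, held stable
over the post-reperfusion hour. The transitional zone as an even mixture
of its neighbours is the simplest defensible model of a zone defined only
by its position. Leak is restricted to D1/D2 after ≥ 6 h of ischemia —
capillary integrity survives 3 h. A small in-vivo residual signal is
sometimes seen over fully occluded tissue (scatter or collateral trickle —
the mechanism is not established); the generator exposes a `scatter_drift`
term for it but defaults it to 0 so that a clamped ROI is exactly flat and
zero-flow ground truth stays unambiguous.

Flow traces draw a per-phase mean from a normal truncated at zero
(baseline 69.7 ± 16.5 ml/min for every group; reperfusion 60.7 ± 48.4 /
97.1 ± 31.0 / 142.5 ± 60.0 by group) with a 5% pulsatile ripple at 1.5 Hz
and 1 ml/min sample noise; occlusion traces are exactly zero. Whole-study
simulation (default 7/7/4 animals → 378 curve measurements) adds a
lognormal between-animal inflow multiplier (SD of the log 0.20) shared
across each animal's measurements — so it cancels in within-animal
ratios — plus an independent per-measurement jitter (SD 0.08). Macroscopic
component grades are generated from a per-cell severity level with ±1
integer jitter (healthy tissue pinned at the exact 4-point floor);
histology descriptors place the ischemic zone at Chiu grade 3/4/5 for
3/6/10 h and the transitional/control zones at grades ≤ 2.

### What the simulator does and does not emulate

It reproduces the *structure* the analysis assumes: graded perfusion
deficits, zero-flow occlusion, group-wise hyperemia, leak-driven
hyperintensity, recirculation, camera noise, and realistic
between-animal spread. It does not model photon physics or tissue optics,
photobleaching, breathing/peristalsis motion, venous congestion distinct
from arterial occlusion, rater disagreement, or the no-reflow
phenomenon after very long ischemia (simulated 10-h reperfusion inflow
follows measured arterial hyperemia, even though real necrotic
microvasculature may not transmit it). Passing tests therefore demonstrate
that the pipeline recovers known kinetics from curves with this structure
— not that it is robust to motion artefacts or optical confounds of real
recordings.

## Statistical summaries

Fluorescence metrics and ratios are ln-transformed before averaging
(right-skew, variance growing with the mean). Cells of the group × ROI ×
timepoint design are summarised as the mean of ln-values with the
t-distribution 95% CI (`mean ± t₀.₀₂₅,ₙ₋₁·sd/√n`) and the back-transformed
geometric mean; single-observation cells carry an explicit undefined-CI
flag. Zero-valued (flagged no-signal) records cannot be log-transformed
and are excluded with a logged count rather than offset by a
pseudo-constant, which would silently distort ratios; fully occluded cells
may therefore be absent from BSFI/SFI summaries while present for other
variables. Mixed-model inference for the repeated-measures design is
deliberately not reimplemented: the package emits tidy long-format tables
that external tools (e.g. R `lme4`/`nlme`) consume directly.

## Numerical choices and problem sizes

- Trapezoidal convolution on the 0.2-s grid keeps the simulated curve
  within 0.1% of a 10×-finer quadrature; the pipeline's BSFI and SFI agree
  with a fine-grid analytic oracle within 1% and 2% respectively on
  noiseless parameter draws (enforced in tests).
- The moving-average slope estimator attenuates the true maximal slope by
  O(window²/rise-time²) — well under 2% for the default 1-s window and
  ≥ 2-s AIF time scales.
- Ties in peak location resolve to the earliest sample (`argmax`).
- Replicate-based behavioural tests use 100 seeded full-study replicates
  and 10,000 simulated cells for CI coverage; both sizes keep the whole
  suite under a minute on a laptop-class core while leaving Monte-Carlo
  error far below the asserted margins.

## Known limitations

- ROI masks are serialized as axis-aligned rectangles (arbitrary boolean
  masks are accepted programmatically).
- No motion correction, registration or vignetting correction.
- The onset detector assumes ≥ 5 pre-injection frames; recordings started
  after injection will mis-estimate background.
- Time-to-peak, ingress/egress asymmetry and other perfusion-index
  variants from the wider ICG literature are out of scope.
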