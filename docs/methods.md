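# Methods

## Problem and pipeline

Consumer single-lead ECG recorders (Kardia-class devices, ECG-capable
watches) export a printed chart — a PDF or image of the trace on a
millimetre grid — rather than raw samples. `afscreen` turns such a chart
back into numbers and screens the rhythm for atrial fibrillation (AF):

1. **Digitization** — chart image → uniformly sampled waveform (mV);
2. **Signal processing** — smoothing, R-peak detection, RR intervals;
3. **Calibration** (optional) — an affine map aligning a low-cost
   device's RR measurements to a 12-lead reference;
4. **Classification** — symbolic recurrence + distribution covariates
   per RR window, logistic regression, ROC-derived threshold.

## Symbolic recurrence quantification analysis

Given RR intervals {x_t}, each delay-1 m-history
x̄_t = (x_t, …, x_{t+m−1}) (default m = 3) is mapped to its ordinal
pattern: the permutation of time offsets sorting the values ascending,
ties broken by time order (the standard ordinal-pattern convention,
which makes the map total). Two histories are recurrent when their
patterns coincide; the symbolic recurrence plot (SRP) is the N×N matrix
holding the shared symbol's id (1..m!) at recurrent pairs and 0
elsewhere. It is symmetric with a fully recurrent main diagonal.

Covariates per window (default 9, in fixed order):

| name | meaning | default |
| --- | --- | --- |
| `det` | fraction of off-diagonal recurrent points on diagonal runs ≥ l_min | l_min = 2 |
| `lam` | same for vertical runs ≥ v_min | v_min = 2 |
| `l_max` | longest diagonal run | — |
| `l_mean` | mean diagonal run length among runs ≥ l_min | — |
| `symbol_entropy` | Shannon entropy (nats) of the per-symbol recurrence-rate distribution | ∈ [0, log m!] |
| `rr_mean`, `rr_median` | plain location stats (s) | — |
| `rr_cv` | sample sd (n−1) / mean | — |
| `rr_cv_med` | median absolute deviation / median | — |

The line of identity is excluded from rates, DET and LAM, as is standard
in recurrence quantification: self-recurrence is uninformative and would
saturate the rates. Two consequences worth knowing: for a fully
recurrent matrix the corner diagonal and the two identity-adjacent
column remnants are length-1 runs, so DET and LAM of a constant-symbol
series are (N(N−1)/2 − 1)/(N(N−1)/2) and (N(N−1) − 2)/(N(N−1)), just
below 1; and because overlapping m-histories share m−1 values, even an
i.i.d. series has DET ≈ 0.57 at m = 3 — the NS/AF contrast in any single
line measure is modest, and discrimination is carried by the nine
covariates jointly.

**Monotonic invariance.** Ordinal patterns depend only on order, so any
strictly increasing transform of the series — in particular an affine
calibration with positive slope — leaves the symbol sequence, the SRP
and every symbolic covariate bit-identical. Only the distribution group
moves (and `rr_cv` is itself invariant under pure rescaling). This is
why the classifier works equally well on raw and calibrated input: in
the synthetic benchmark the cross-validated accuracy shift after
calibration is 0.

## Classification

Features are z-scored with training statistics and fitted by logistic
regression with a tiny L2 penalty (ridge = 1e−6, i.e. C = 1e6) that
keeps the MLE finite under complete separation; set ridge = 0 for the
pure MLE. The operating threshold τ is chosen on the *training* ROC
curve as the point minimizing √(FPR² + (1−Se)²), ties broken toward the
largest threshold (fewest false AF alarms); a window is called AF when
its predicted probability strictly exceeds τ. Validation uses stratified
k-fold (default k = 10, seeded shuffle) with τ re-selected inside each
training fold; aggregate Se/Sp/ACC pool the test-fold confusion counts.
Recording-level output is a majority vote over windows.

## Digitization

Stages: rasterize (600 dpi reference), crop, grid removal (RGB box →
white), darkness binarization (min(R,G,B) < threshold, strict), area
opening (8-connected components < 1260 px at 600 dpi removed, area
scaled by (dpi/600)²), morphological thinning (2 iterations; the
"shrink 2.5" of the source procedure is not meaningful for integer
iterations), and a left-to-right vertical scan collecting each column's
ink span.

Span reduction uses the modal stroke thickness μ (mode of
bottom − top): a column within μ keeps its bottom row, which also
updates the running reference λ; a thicker column is a steep QRS flank
and keeps the edge farthest from λ. λ is updated to the stored row in
both branches so a flank's column chain stays anchored. Missing columns
are filled by linear interpolation (edges by nearest value). Rows become
mV via the chart geometry (25.4/(dpi·gain) mm per row) about the median
trace row — a robust baseline whose only effect is a constant offset,
immaterial to RR intervals and to every ordinal feature. Columns become
seconds via 25.4/(dpi·paper_speed), resampled to 300 Hz by default
(Kardia-class bandwidth ≈ 150 Hz; configurable). When a column holds
several disjoint ink runs (residual grid), the run nearest the previous
column's span is kept.

PDF input requires the optional `pypdfium2` dependency (`afscreen[pdf]`);
PNG/JPEG are handled natively, and chart rendering can *write* both PNG
and single-page PDF.

## Signal processing

The smoother is the 5-tap moving average (b = [0.2]*5, a = [1]): a
fourth-order FIR with unit DC gain, applied causally with zero initial
conditions. Its 2-sample group delay is constant and cancels in RR
differences, so no compensation is applied. R peaks are local maxima
with topographic prominence ≥ 0.4 × (p99 − median) — offset-invariant by
construction — and refractory spacing ≥ 0.25 s (~240 bpm upper bound);
the higher peak wins conflicts. Windows default to 102 beats,
non-overlapping.

## Synthetic study conditions

The generator provides the two rhythm regimes the method assumes, not a
full cardiac simulator:

- **NS**: RR_t = 0.8 + 0.05·sin(2πt/6) + ε_t, ε ~ N(0, (0.01·0.8)²),
  clipped ≥ 0.2 s. The 0.05 s / 6-beat modulation mimics respiratory
  sinus arrhythmia at 75 bpm and ~12.5 breaths/min; the 8 ms jitter is
  residual short-term variability. The modulation dominating the jitter
  gives the structured, periodically repeating ordinal patterns NS is
  known for.
- **AF**: i.i.d. gamma intervals, mean 0.7 s, CV 0.25, clipped to
  [0.2, 2.0] s — high variability with no serial structure (lag-1
  autocorrelation ≈ 0). The generator enforces CV ≥ 0.15 for the AF
  regime and ≤ 0.15 for NS.
- **Waveform**: each beat is a sum of gaussian bumps (P 0.15 mV at
  −0.25 beat, σ 25 ms; Q −0.10 at −0.07, σ 12 ms; R 1.2 at 0, σ 20 ms;
  S −0.25 at +0.07, σ 12 ms; T 0.30 at +0.38, σ 45 ms), sampled at
  300 Hz; n intervals yield n+1 beats with ground-truth R indices.
- **Chart**: 25 mm/s, 10 mm/mV, 1 mm fine / 5 mm bold pink grid, 1 px
  black trace with inter-column spans filled (so steep flanks are solid
  vertical runs, as on real printouts), optional salt-and-pepper specks.

Not emulated: ectopic beats, f-waves, baseline wander, electrode noise,
multi-lead layouts, printed metadata. Passing tests therefore show the
pipeline's correctness on clean charts and the regime contrast the
covariates target — not clinical performance on scanned hospital paper.

## Numerical choices and degenerate inputs

- Binarization and area opening use strict `<`; an exactly-1260 px
  component survives.
- μ uses `scipy.stats.mode` (smallest value on ties).
- A flat signal yields no peaks (robust range 0); fewer than 2 peaks is
  an error for RR computation.
- Calibrated intervals that come out non-positive are clipped to 1 ms
  with a warning rather than erroring, so batch runs survive extreme
  inputs.
- ROC sentinels 0 and 1 guarantee both corners; the strict `>` rule
  makes "call nothing" and "call everything except prob-0" reachable.
- Constant features standardize to 0 (sd forced to 1).

## Problem sizes

The shipped benchmark uses 100 NS + 100 AF windows of 102 beats
(SRP 100×100 per window) and a 10-interval strip at 600 dpi
(~945×5100 px) for the digitization round trip; both complete in
seconds and are regenerated from seeds at run time rather than stored.

## Known limitations

- The digitizer assumes one trace per strip; overlapping leads or
  annotations inside the crop will corrupt the scan.
- Grid removal needs a colour box separating grid from trace; grey
  grids under a grey trace are not separable.
- The 9-covariate set is this package's documented default; feature
  selection is configurable per window.
- The logistic model is per-window; the recording-level majority vote
  is a pragmatic default, not a calibrated aggregate probability.
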