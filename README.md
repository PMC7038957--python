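# afscreen

Atrial-fibrillation screening from low-cost, single-lead ECG recorders
whose only output is a printed chart.

Consumer ECG devices (Kardia-class recorders, ECG watches) typically
export a PDF/PNG picture of the trace on a millimetre grid instead of
raw samples. `afscreen` closes that gap for practitioners and
researchers prototyping arrhythmia screening on such hardware: it
digitizes the chart back into a waveform, extracts RR intervals
(inter-beat times), optionally calibrates them against a gold-standard
device, and classifies each window of beats as normal sinus rhythm (NS)
or atrial fibrillation (AF).

## Method

Each 102-beat RR window {x_t} is delay-embedded into m-histories
x̄_t = (x_t, …, x_{t+m−1}) (m = 3) and symbolized by ordinal patterns:
x̄_t ↦ π, the permutation of time offsets sorting the values ascending
(e.g. (0.55, 0.65, 0.60) ↦ (0, 2, 1)). The symbolic recurrence plot
SRP_{ts} = k if S(x̄_t) = S(x̄_s) = π_k, else 0, records which pairs of
histories visit the same pattern. From it the window gets nine
covariates — determinism (DET), laminarity (LAM), longest/mean diagonal
line, symbol entropy, plus the RR mean, median, Pearson CV and robust
CV — feeding a logistic regression. The decision threshold τ is the
point of the training ROC curve closest to the ideal corner,
τ = argmin √(FPR² + (1 − Se)²), and a window with probability > τ is
called AF.

Because ordinal patterns see only the *order* of the values, every
symbolic covariate is exactly invariant under strictly increasing
transforms of the RR series — so an affine device calibration
(rr_gold = a + b·rr_lowcost, fitted by OLS) changes nothing about the
symbolic features and the classifier performs identically on raw and
calibrated data.

See `docs/methods.md` for the full model description and numerical
conventions.

## Worked example

```python
from afscreen import synthetic as syn
from afscreen import srqa

rr = syn.generate_rr_ns(102, seed=1)   # normal-sinus window, 102 beats
fv = srqa.feature_vector(rr)
for name, value in fv.items():
    print(f"{name:>15}: {value:.4f}")
```

prints

```
            det: 0.5983
            lam: 0.7381
          l_max: 19.0000
         l_mean: 3.4211
 symbol_entropy: 1.0933
        rr_mean: 0.7994
      rr_median: 0.8002
          rr_cv: 0.0449
      rr_cv_med: 0.0478
```

A quasi-periodic NS window shows long diagonal lines (`l_max` 19) and a
low RR coefficient of variation (0.045); the same call on an AF window
(`syn.generate_rr_af(102, seed=1)`) gives `rr_cv` 0.2363 — the
irregularly irregular rhythm — with no comparable line structure. A
logistic model on 100 + 100 such windows separates the two regimes at
~0.99 cross-validated accuracy (`afscreen.classifier.cross_validate`).

From a shell, the same pipeline runs end to end:

```bash
afscreen synth chart --n 10 --seed 7 --out strip.png   # synthetic strip
afscreen digitize strip.png --out signal.csv
afscreen rr signal.csv --out rr.csv
afscreen features rr.csv --out features.json --window 8
```

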