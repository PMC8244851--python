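# phantomt1

Quantitative MRI of the longitudinal relaxation time T1 promises scanner-
independent tissue measurements, but in practice a T1 threshold calibrated
on one scanner does not transfer to another: vendor product sequences differ
in calibration, and the popular fast method (variable flip angle, VFA) is
exquisitely sensitive to transmit-field (B1) errors.  `phantomt1` is a
tested, fully synthetic re-implementation of a multi-site phantom T1
analysis pipeline built around the ISMRM/NIST system phantom's NiCl2 array:
14 spheres of NMR-traceable reference T1 spanning ~20-2000 ms.  It is aimed
at people validating T1 mapping pipelines, studying B1-driven bias, or
teaching quantitative-MRI quality control — every stage can be checked
against exact ground truth without any scanner data.

The package covers:

* **Simulation** (`phantomt1.phantom`) — coronal magnitude image series of
  the 14-sphere array, indexed by inversion time (IR) or flip angle (VFA),
  with Rician noise, flip-angle miscalibration fields, per-series gain
  factors, and partial-volume boundary pixels.
* **Segmentation** (`phantomt1.segmentation`) — gradient-filter edge
  detection, rigid template registration, per-sphere center refinement, and
  4 mm ROIs (~52 pixels at 0.98 mm resolution).
* **Fitting** (`phantomt1.fitting`) — grid-search + damped Gauss-Newton
  estimators for both protocols.
* **Statistics** (`phantomt1.stats`) — normalized errors, group summaries
  with t-based 95% CIs, two-way ANOVA (vendor x field), per-sphere
  Tukey-Kramer pairwise vendor comparisons, and bias propagation onto
  clinical tissue T1 ranges.
* **I/O and orchestration** (`phantomt1.io`, `phantomt1.pipeline`,
  `phantomt1.cli`) — NIfTI + JSON sidecar round trips, DICOM import,
  Philips-style per-series intensity rescaling, and an end-to-end
  multi-vendor synthetic study.

## Models

Inversion recovery measures the magnitude signal at inversion times TI_k,

    y_k = | M0 (1 - cos(th180) e^(-TR/T1) - (1 - cos(th180)) e^(-TI_k/T1))
            / (1 - cos(th180) cos(th90) e^(-TR/T1)) |,

fit in the reduced three-parameter form |A + B e^(-TI_k/T1)|.  Because the
modulus is non-differentiable near the null crossing, the estimator
minimizes the smoothed objective

    min_{T1,A,B}  sum_k ( y_k^2 - (A + B e^(-TI_k/T1))^2 )^2,

by a dense grid search followed by Newton (damped Gauss-Newton) refinement.

VFA measures the spoiled gradient-echo signal at flip angles a_m,

    z_m = M0 sin(a_m) (1 - E) / (1 - E cos(a_m)),    E = e^(-TR/T1),

fit by ordinary nonlinear least squares over (T1, M0), same grid + Newton
scheme.  A multiplicative flip-angle error k biases the fitted VFA T1 to
about k^2 T1 — the relative T1 error is roughly twice the relative
flip-angle error — while the IR fit is immune because A and B absorb the
imperfect inversion.

Accuracy is reported as the normalized error against the sphere's reference
value,  dT1 = 100 (T1 - T1_NMR) / T1_NMR (%),  compared across vendor
groups per sphere with one-way ANOVA and Tukey-Kramer HSD at alpha = 0.05.

## Worked example

```python
import numpy as np
from phantomt1 import (build_layout, ir_protocol, render_series,
                       segment_series, fit_ir, flip_angle_sensitivity)

layout = build_layout(3.0)                      # 14 spheres, 3 T reference T1
series = render_series(layout, ir_protocol(noise_sigma=0.01, rng_seed=7))
rois = segment_series(series, layout)           # edges -> rigid fit -> refine -> 4 mm ROIs
for i in (0, 6, 13):
    fit = fit_ir(series.series_values, rois.mean_signals[i])
    print(f"sphere {i+1:2d}: T1 = {fit.t1_ms:7.1f} ms "
          f"(reference {layout.reference_t1_ms[i]:.0f} ms)")
```

prints

```
sphere  1: T1 =  2037.3 ms (reference 2033 ms)
sphere  7: T1 =   259.3 ms (reference 260 ms)
sphere 14: T1 =    22.8 ms (reference 23 ms)
```

i.e. the full segment-and-fit chain recovers T1 within a fraction of a
percent at SNR ~100 across two orders of magnitude of T1.  The flip-angle
sensitivity of the VFA estimator:

```python
print(flip_angle_sensitivity(2000.0, 6.6, [2, 5, 10, 20, 25, 30],
                             [0.9, 1.0, 1.1])[["k", "t1_fit_ms", "ratio"]])
```

```
  k   t1_fit_ms     ratio
0.9 1615.796429  1.921018
1.0 2000.000000       NaN
1.1 2425.743370  2.128717
```

A 10% under-rotation makes a 2000 ms T1 read as ~1616 ms (about 20% low);
the error ratio is the factor-of-two rule of thumb.

The full synthetic multi-vendor study (three vendors, six scanners each,
one vendor with a 10% flip-angle under-calibration) runs with

```sh
phantomt1 run --seed 7 --out results/study
```

and reproduces the characteristic signature: a large negative VFA bias and
significant per-sphere vendor differences for the miscalibrated vendor,
with near-zero IR bias for everyone.

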