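# orgpet

Amplitude-based **optimal respiratory gating (ORG)** for PET quantification,
end to end: respiratory-motion phantom simulation, the optimal-amplitude-window
gating algorithm, isocontour tumor delineation, a 35-feature radiomic panel,
and the survival statistics used to relate those features to outcome.

## The problem

PET quantification of lesions near the diaphragm — pancreatic tumors in
particular — is degraded by respiratory motion: several-minute acquisitions
smear the lesion along the cranio-caudal axis, inflating the measured
metabolic tumor volume (MTV) and deflating uptake values (SUVmax, SUVmean)
and texture measures of intra-tumoral heterogeneity. Amplitude-based optimal
respiratory gating reconstructs only the data acquired inside the *narrowest*
respiratory-amplitude window that still contains a prescribed fraction (the
**duty cycle**, 35% by default) of the acquisition: for each candidate lower
limit L, the upper limit U is the smallest value such that [L, U] holds the
prescribed fraction of amplitude samples, and the optimal window minimizes
W = U − L. Because breathing dwells at end-expiration, the optimal window is
narrow and sits at the bottom of the amplitude range, so the retained data
are nearly motion-free.

Patient scan pairs are not shareable, so this package drives the entire
analysis with a digital phantom: a heterogeneous hot lesion (Gaussian
profile, necrotic core, correlated intra-lesional texture) on a warm
background, moved rigidly along the cranio-caudal axis by a cos²ⁿ breathing
waveform, rendered at 4.07 mm voxels with a 3.0 mm Gaussian PSF and optional
Poisson count noise. Ground truth is known exactly, so the directional
effects of gating can be tested rather than eyeballed.

What the package computes downstream of gating:

* **Segmentation** — the 40% SUVmax isocontour VOI inside an annotated seed
  region (26-connected component of the maximum voxel), with manual-exclusion
  support; MTV in ml.
* **Features** — SUVmax/min/mean/diff and MTV, first-order histogram
  statistics, and GLCM / GLRLM / GLSZM texture features (255 fixed bins,
  13 directions at distance 1, 26-connected zones); 35 named features total.
* **Survival** — paired Wilcoxon signed-rank comparison of ungated vs gated
  features; univariate Cox proportional-hazards models (HR per 1 SD,
  Efron ties, in-package Newton solver); Kaplan–Meier curves with two-group
  log-rank tests; maximally selected log-rank cutoffs; and a synthetic
  survival generator whose hazard depends on chosen standardized features.

## Worked example

```python
import numpy as np
import orgpet as op

spec = op.default_phantom_spec(seed=1)           # heterogeneous hot lesion
truth = op.make_phantom(spec)
trace = op.lujan_waveform(period_s=4.0, amplitude_mm=15.0, exponent_n=2,
                          duration_s=60.0, dt_s=0.4, jitter=0.05, seed=1)
stack = op.simulate_acquisition(truth, trace, background_suv=1.0)

window = op.optimal_amplitude_window(trace, duty=0.35)
print(f"window: L={window.lower_L_mm:.2f} mm, U={window.upper_U_mm:.2f} mm, "
      f"W={window.width_W_mm:.2f} mm, duty={window.achieved_duty:.3f}")

ungated = op.sum_frames(stack, np.arange(len(stack)))
gated = op.gated_image(stack, duty=0.35)

seed_mask = op.seed_mask_from_truth(truth, 1.0, motion_axis=2, max_shift_mm=15.0)
for name, img in [("non-ORG", ungated), ("ORG", gated)]:
    voi = op.isocontour_voi(img, seed_mask, fraction=0.40)
    fv = op.extract_all(img, voi, n_bins=255)
    print(f"{name:8s} SUVmax={fv['SUVmax']:.2f}  SUVmean={fv['SUVmean']:.2f}  "
          f"MTV={fv['MTV']:.1f} ml  STD={fv['STD']:.3f}")
```

prints

```
window: L=0.13 mm, U=1.84 mm, W=1.71 mm, duty=0.353
non-ORG  SUVmax=5.65  SUVmean=3.28  MTV=13.6 ml  STD=0.841
ORG      SUVmax=7.15  SUVmean=4.02  MTV=8.9 ml  STD=1.003
```

The 35% duty cycle is captured by a 1.7 mm amplitude window at
end-expiration (the full excursion is 15 mm). Gating recovers peak uptake
smeared by motion (SUVmax 5.65 → 7.15, against a motion-free truth of 7.68),
raises SUVmean, shrinks the apparent metabolic volume by a third, and
increases the in-VOI intensity dispersion — the expected directional effects
of respiratory-motion correction.

A full synthetic cohort (features, paired Wilcoxon table, per-feature Cox
hazard ratios and optimal cutoffs, manifest) is one call or one command:

```bash
orgpet pipeline --seed 7 --subjects 20 --out run/
```

The CLI also exposes the individual stages: `orgpet simulate`, `gate`,
`segment`, `features`, `survive` (see `orgpet --help`).

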