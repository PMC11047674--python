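# mwppg — multi-wavelength PPG fusion for cuffless blood-pressure estimation

Fingertip photoplethysmography (PPG) measures blood-volume pulsation
optically; recording it at several LED wavelengths simultaneously
(660/730/850/940 nm) probes different tissue depths, and fusing those
channels improves cuffless blood-pressure (BP) estimation over any single
wavelength.  `mwppg` implements that pipeline end to end for researchers in
physiological monitoring:

1. **Preprocess** — 0.5–8 Hz Butterworth band-pass (order 2, zero-phase),
   per-channel z-scoring, simultaneous four-channel segmentation into 5 s
   windows sliding by 1 s, rule-based rejection of abnormal windows.
2. **Scalogram fusion** — each window is transformed with the continuous
   wavelet transform (CWT), WT_x(a,b) = |a|^{−1/2} ∫ x(t) ψ*((t−b)/a) dt,
   using the complex Gaussian wavelet "cgau1"; each wavelength's magnitude
   scalogram becomes an RGB image, and the four images are stacked
   depth-wise into one H × W × 12 tensor.
3. **Regression** — an attention CNN–BiLSTM: per block, conv → batch norm
   → SELU → squeeze-and-excitation channel attention → 2×2 pooling; the
   feature map's width axis is read as a time sequence into a two-layer
   bidirectional LSTM, and two dense layers emit (SBP, DBP) jointly.
   Training uses Adam (lr 0.001), MAE loss, an 80/20 split with 10-fold
   cross-validation on the training portion.
4. **Evaluation** — ME, SD, MAE, RMSE, R²; the AAMI accuracy criterion
   (|ME| < 5 mmHg and SD < 8 mmHg); BHS grading from cumulative
   percentages of |error| ≤ 5/10/15 mmHg; Bland–Altman limits of
   agreement ME ± 1.96·SD.

Because real four-wavelength recordings cannot ship with the package, a
first-class synthetic generator (`mwppg.synthetic`) emulates the
acquisition protocol — 200 Hz, 60 s, four channels with a wavelength-
dependent dicrotic-prominence gradient, and BP labels deterministically
linked to the beat morphology — so the whole pipeline runs and is tested
at desk scale on one CPU.  See `docs/methods.md` for the model, the
generator's label link, and every numerical convention.

## Worked example

```python
import numpy as np
from mwppg import SimConfig, simulate_cohort, build_image_dataset, train_model
from mwppg.training import desk_scale_model, desk_scale_train

records, labels = simulate_cohort(SimConfig(n_subjects=24, seed=11, label_noise_sd=0.0))
data = build_image_dataset(records, kind="fused", image_size=(32, 32),
                           windows_per_subject=10)
res = train_model(data, desk_scale_model("fused12"),
                  desk_scale_train(seed=0, epochs=40), run_cv=False)
r = res.test_reports["sbp"]
print(f"held-out SBP: MAE {r.mae:.2f} RMSE {r.rmse:.2f} mmHg, R2 {r.r2:.2f}, "
      f"AAMI {'Yes' if r.aami_pass else 'No'}, BHS {r.bhs.grade}")
```

prints (exact numbers are seed-dependent):

```
held-out SBP: MAE 4.82 RMSE 6.14 mmHg, R2 0.77, AAMI Yes, BHS A
```

i.e. on a noise-free 24-subject synthetic cohort the fused 12-channel
model recovers systolic BP on held-out subjects to ≈5 mmHg — less than
half the ≈12 mmHg a mean predictor achieves — because the four channels
jointly identify the cross-channel dicrotic gradient that drives the
synthetic labels, which no single wavelength can resolve.  The same
pipeline is available from the shell:

```
mwppg simulate --n 24 --seed 11 --out-dir cohort/
mwppg train --trial 3 --in-dir cohort/ --labels cohort/labels.csv --out-dir run/
mwppg evaluate --pred preds.csv --truth cohort/labels.csv --out-dir report/
```

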