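# ppgfatigue

Detecting physical fatigue from single-channel photoplethysmography (PPG).

Wearable optical sensors record a quasi-periodic blood-volume pulse whose
shape and rhythm carry autonomic state: inter-beat-interval (IBI)
variability is a standard proxy for sympathovagal balance, and the dicrotic
wave on the descending limb reflects vascular tone. This package implements
a complete, reproducible pipeline that classifies 10-second PPG windows as
*fatigue* vs *non-fatigue* and aggregates window decisions into a
per-subject verdict. It is aimed at researchers in physiological signal
processing and digital health who need a tested reference implementation of
the whole chain — from raw contaminated waveforms to subject-wise
cross-validated metrics — and a seeded synthetic cohort generator to
exercise it with.

The pipeline has five stages:

1. **Synthetic cohort generation** (`ppgfatigue.synth`) — seeded two-class
   cohorts. Each beat is a systolic plus delayed dicrotic Gaussian kernel
   strung along positive-truncated-normal IBIs; classes differ in IBI
   spread and dicrotic amplitude. Recordings are contaminated with baseline
   wander, a mains-like interference tone and white noise, and each subject
   carries Karolinska Sleepiness Scale (KSS) and Psychomotor Vigilance Test
   (PVT) metadata drawn from a published 12-subject reference table.
2. **Wavelet-shrinkage denoising** (`ppgfatigue.wavelet`) — k-level DWT,
   per-band thresholding (universal γ = σ√(2 ln n), hybrid SURE, or
   minimax; hard or soft shrinkage, σ = median(|cD₁|)/0.6745), inverse DWT.
3. **Windowing and labelling** (`ppgfatigue.dataset`) — KSS ≥ 4 ⇒ fatigue;
   fixed-length windows inherit the record label; derived heart-rate and
   breathing channels; subject-disjoint k-fold and leave-one-subject-out
   (LOSO) fold plans.
4. **Classification** (`ppgfatigue.models`, `ppgfatigue.nnops`) — 1-D
   residual (ResNet-style) and depthwise-separable (Xception-style)
   convolutional extractors feeding a bidirectional LSTM and a β-scaled
   softmax head, trained with SGD with momentum and decoupled weight decay
   on cross-entropy:

   ΔW(t+1) = −(η·λ/r)·W − (η/b)·∂C/∂W + m·ΔW(t)

   Everything is plain numpy with exact manual backprop, verified against
   finite differences. At the reference configurations the extractors emit
   the contracted feature maps: 15×132 (36-layer residual) and 64×132
   (37-layer separable) on a 1056-sample window.
5. **Evaluation** (`ppgfatigue.evaluate`) — confusion matrices, accuracy /
   precision / recall / F1, rank-based ROC-AUC with tie correction,
   MAE/MSE/RMSE, per-subject majority voting (ties → fatigue), a
   cross-validation runner, architecture sweeps, and a quality gate that
   requires AUC, F1, precision and accuracy all above 0.825.

## Worked example

A one-minute desk demo: simulate a small cohort, denoise, window, and run
subject-wise leave-one-subject-out cross-validation.

```python
from dataclasses import replace
from ppgfatigue import (
    SynthConfig, simulate_cohort, denoise, WaveletConfig, segment,
    make_folds, run_cv, ModelConfig, cohort_stats, reference_cohort,
)

print(cohort_stats(reference_cohort()).to_frame().to_string(index=False))

records = simulate_cohort(6, SynthConfig(duration_s=110.0, seed=0))
windows = []
for rec in records:
    clean = denoise(rec.samples, WaveletConfig())
    windows.extend(segment(replace(rec, samples=clean), window_s=10.56, max_windows=10))
plan = make_folds(sorted({w.subject_id for w in windows}), "leave_one_subject_out")
report = run_cv(windows, ModelConfig(epochs=10, seed=0), plan)
print(report.summary())
```

prints

```
  condition       kss       pvt_ms
    fatigue 7.4 ± 0.6 469.4 ± 90.7
non_fatigue 2.8 ± 0.4 356.2 ± 28.7

Subject-wise cross-validation
==============================================
folds                                        6
pooled windows                             120
pooled accuracy                         0.7750
pooled precision                        0.7037
pooled recall                           0.9500
pooled f1                               0.8085
pooled auc                              0.9056
pooled mae                              0.4860
pooled mse                              0.2364
pooled rmse                             0.4862
subject vote accuracy                   0.8333
gate (all > 0.825)                       False
```

The cohort table reproduces the reference per-condition means (fatigue KSS
7.4, PVT 469.4 ms; non-fatigue KSS 2.8, PVT ≈ 356 ms). The small demo
cohort (6 subjects, 10 windows each, 10 epochs) is deliberately starved;
at the package's benchmark scale — 12 subjects, 40 windows per subject, 20
epochs — the same LOSO protocol trains each fold on 440 windows, tests on
the held-out subject's 40, and reaches pooled accuracies of 0.95–1.00
(seeds 0–2), clearing the 0.825 gate on all four metrics.

The same pipeline is scriptable from the shell:

```sh
ppgfatigue simulate --subjects 12 --duration 600 --seed 0 --out cohort/
ppgfatigue denoise --in cohort/S01_fatigue.csv --out S01_clean.csv
ppgfatigue run --out demo_run/          # end-to-end with the default config
```

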