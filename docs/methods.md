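# Methods

This note documents the models implemented in `ppgfatigue`, the parameter
choices that matter, and what the synthetic benchmarks do and do not show.

## Synthetic PPG generator

**Beat template.** One beat on phase φ ∈ [0, 1) is the sum of two Gaussian
kernels: a systolic bump of unit amplitude centred at φ = 0.18 (width
0.07) and a dicrotic bump delayed by 0.35 of the beat period (width 0.10)
scaled by `dicrotic_amp_rel`. The kernels are well separated, so the
systolic peak stays normalised at 1 and a nonzero dicrotic amplitude
produces a distinct secondary maximum, the morphological feature wave
reflection produces in real PPG.

**Rhythm.** Inter-beat intervals are drawn i.i.d. from a normal
(`mean_ibi_s`, `ibi_sd_s`) truncated to positive values by rejection (the
validated parameter ranges guarantee ≥ 50 % acceptance; an iteration cap
still guards the sampler). Beats are concatenated and the template is
evaluated at each sample's phase within its beat. True beat onsets and the
uncontaminated pulse train are kept on the record (`beat_times`, `clean`)
so downstream stages can be scored against the generator rather than
against themselves.

**Contamination.** Three additive components, each with a seeded phase:
baseline wander (default 0.1 Hz sinusoid, amplitude 0.3 of the systolic
peak), a mains-like interference tone, and white Gaussian noise (default
sd 0.05). At the default 100 Hz sampling rate a true 50 Hz mains tone sits
exactly at Nyquist, so the default interference frequency is 45 Hz — it
lands in the same finest wavelet band a mains tone would; set a higher
`fs_hz` to simulate literal 50/60 Hz pickup.

**Classes and metadata.** The fatigue class is generated with lower IBI
spread (gap 0.035 s at separation 1) and a flatter dicrotic wave (gap
0.22). The direction is a simulator convention: it gives the classifier
two realistic, physiologically motivated axes to find, not a claim about
the sign of autonomic change in any particular population. The
`separation` knob scales both gaps linearly, with per-subject jitter drawn
once per subject so the gap is monotone in the knob by construction. KSS
scores are categorical on the observed per-condition frequencies of the
12-subject reference table (fatigue: 7 with 8/12, 8 with 3/12, 9 with
1/12; non-fatigue: 2 with 2/12, 3 with 10/12); PVT latencies are
positive-truncated normals centred on the per-condition table means
(469.4 / 356.25 ms).

**What the generator does not emulate.** Motion artifacts, sensor
saturation, skin-tone and contact-pressure effects, non-stationary heart
rate trends, and any within-record label change. Passing the end-to-end
benchmarks therefore demonstrates that the pipeline is implemented
correctly and can recover a class signal of plausible shape and size from
contaminated waveforms — not that the trained networks would transfer to
any particular real recording.

## Wavelet denoising

Three steps: k-level DWT (PyWavelets filter bank), detail-band shrinkage,
inverse DWT. Boundary handling is symmetric extension by default, which
minimises edge artifacts but adds redundant boundary coefficients (energy
conservation is then approximate; a `periodization` mode keeps the
transform exactly orthonormal and is what the Parseval test uses). The
original length is stored so reconstruction is exact for odd lengths.

The noise scale is estimated once from the finest detail band,
σ = median(|cD₁|)/0.6745: under white noise every band shares σ, and the
finest band is the one nearly free of signal. Estimating σ per band
(available via `sigma_per_level=True`, appropriate for strongly coloured
noise) inflates σ in signal-bearing coarse bands and measurably degrades
denoising. Thresholds are per band, γᵢ from the configured rule at that
band's coefficient count: universal γ = σ√(2 ln n); minimax (0 for
n ≤ 32, else σ(0.3936 + 0.1829 log₂ n)); or SURE, minimised by brute
force over the sorted coefficient magnitudes with the standard hybrid
fallback — when the band looks noise-dominated by the usual sparsity
criterion the universal threshold is used, and the SURE choice is capped
at the universal value. Hard shrinkage zeroes |c| ≤ γ; soft additionally
shrinks survivors by γ. The approximation band is never thresholded.

**Decomposition depth.** The default depth is 3 at the default 100 Hz
rate. The pulse template's spectrum is negligible above ~6 Hz, so levels
1–3 (≥ 6.25 Hz) can be thresholded without touching signal; level 4
(3.1–6.25 Hz) carries real harmonic energy, and shrinking it at the
universal threshold removes signal faster than noise (measured: median
SNR gain ~8 dB at depth 3 versus ~4.9 dB at depth 4 on the benchmark
below). The rule of thumb is to deepen the analysis with the sampling
rate so the coarsest thresholded band stays above the signal band.

**Benchmark conditions.** Denoising efficacy is measured on the
classifier's input unit: canonical 1056-sample (10.56 s) windows of clean
synthetic PPG plus white noise scaled to 5 dB input SNR (total-power
definition), 20 fixed instances, gain in dB against the generator's clean
signal, median reported. At the defaults the median gain is ~8 dB.

## Windowing, channels, folds

KSS ≥ 4 labels a session fatigue (≤ 3 non-fatigue); windows inherit the
parent record's label and subject id. The canonical window is 1056
samples (10.56 s at 100 Hz), the length at which the reference extractors
emit their contracted feature-map shapes; window length and overlap are
configurable, trailing partial windows are dropped.

Derived channels: systolic peaks are detected on a 0.5–8 Hz band-passed
copy by local maxima above 0.6× the rolling 2 s maximum with a 0.3 s
refractory period; inter-peak intervals become instantaneous heart rate
(beats/min) interpolated to a uniform 4 Hz grid. The breathing channel is
the 0.1–0.5 Hz modulation band (zero-phase Butterworth), also at 4 Hz;
`hr_br` stacks both as a two-channel window.

Fold plans are always subject-disjoint: `kfold_by_subject` shuffles
subjects with the seed into k near-equal groups; `leave_one_subject_out`
(LOSO) yields one fold per subject. At 12 subjects × 40 windows each,
every LOSO fold trains on 440 windows and tests on 40. Both schemes exist
because both subject-wise five-fold and leave-one-out protocols are in
common use; the package treats neither as privileged.

## Networks and training

All tensor arithmetic is float64 numpy with handwritten forward and
backward passes; the backward passes are verified against central finite
differences (directional derivatives per parameter tensor, 1e-4 relative)
on the full hybrid.

**Extractors.** `layers` counts weighted main-path layers: the entry
convolution, two convolutions per residual block (identity shortcuts;
1×1 projection on stride or channel change, not counted), depthwise and
pointwise convolutions of a separable block counted separately, and any
final 1×1 channel projection. The 36-layer residual reference is entry +
17 two-conv blocks + projection to 15 channels; the 37-layer separable
reference is entry + 18 depthwise-separable convolutions with the last
pointwise mapping to 64 channels. Temporal downsampling is by strided
convolutions distributed over the entry layer and the first blocks to the
configured power-of-two `total_stride`; at stride 8 a 1056-sample window
becomes 132 steps, realising the (15, 132) and (64, 132) shape contracts.

Every convolution is followed by a per-sample, per-channel normalisation
over time with learnable gain and shift — the batch-independent,
deterministic analogue of the batch normalisation standard residual and
separable stacks carry. Without it (and without gradient clipping, below)
desk-scale SGD at the default learning rate collectively kills the ReLU
stack for roughly a quarter of initialisation seeds, pinning the loss at
ln 2. ReLU is the block activation; the sigmoid unit is kept as a
primitive activation option.

**Sequence head.** The extractor's (channels × steps) map is transposed
to a feature sequence, layer-normalised, and read by a bidirectional
LSTM (standard cell; forward and backward passes concatenated, so the
output keeps the step count with 2×hidden channels). Mean pooling over
time and a dense layer produce two logits; the head is a β-scaled softmax
(β = 1 by default) with cross-entropy loss. Plain `resnet` / `xception`
families skip the BiLSTM; the `lstm` family reads a decimated raw window
directly.

**Optimiser.** SGD with momentum and decoupled weight decay on the
batch-summed cross-entropy: ΔW(t+1) = −(η·λ/r)·W − (η/b)·∂C/∂W + m·ΔW(t),
with r the training-set size and b the batch size; biases carry no decay.
The global gradient norm (per-sample scale) is clipped at `grad_clip`
(default 1.0) before the update — one oversized early step is the
dominant failure mode of an unnormalised ReLU stack. Inputs are
standardised per channel with constants fitted on the training set (not
per window, which would erase window-mean class information).

**Desk scale vs published scale.** The defaults are sized so a full LOSO
cross-validation of a 12-subject cohort runs in about 80 s on one CPU:
8 weighted layers, 8 feature maps, kernel 9, total stride 32 (33 BiLSTM
steps), hidden 16, learning rate 0.05, momentum 0.9, weight decay 1e-4,
20 epochs, batch 64. `ModelConfig.reference_resnet()` /
`reference_xception()` give the published-scale architectures (36/37
layers, stride 8), and `.published_scale()` the published optimiser regime
(learning rate 0.001, 500–2000 epochs). Problem sizes in the test suite
and the acceptance script use the desk scale throughout; the stated
benchmark numbers are desk-scale numbers.

## Evaluation

Fatigue is the positive class everywhere. The cross-validation runner
refits the classifier from scratch per fold (seed = config seed + fold
index), records per-fold confusion matrices and window scores, pools
windows across folds for the aggregate (micro-averaged) metrics, and also
reports per-fold macro rows. AUC uses the rank (Mann–Whitney) formulation
with average ranks for ties, which the tests pin against a
threshold-sweep trapezoidal oracle. MAE/MSE/RMSE are computed between the
predicted fatigue-class probability and the {0, 1} label. Each subject
receives the modal label of their windows' predictions, with exact ties
resolved to fatigue — the conservative direction for a fatigue screen.
The quality gate requires AUC, F1, precision and accuracy all strictly
above 0.825. Degenerate denominators (e.g. a fold with no positive
predictions) yield 0 with a warning rather than NaN, so pooled reports
stay well defined.

Cohort statistics report per-condition means and population standard
deviations (ddof = 0) of KSS and PVT; on the packaged reference table the
means are 7.4 / 469.4 ms (fatigue) and 2.8 / 356.25 ms (non-fatigue).

## Numerical and degenerate-input conventions

Thresholds at exactly γ are zeroed (|c| ≤ γ), making hard shrinkage
idempotent and soft shrinkage continuous. σ = 0 gives γ = 0 for every
rule. The softmax subtracts the row maximum before exponentiation.
Majority-vote ties go to fatigue. Fold construction with k greater than
the subject count, windows longer than their record, empty coefficient
arrays, single-class training sets and non-finite samples all raise
immediately with the offending quantity named.

## Known limitations

The synthetic cohort is the only data source packaged; all classification
results are on simulated waveforms whose class signal the generator
controls, and the gap between desk-scale and published-scale training
regimes is deliberate. The LSTM family at desk scale is a weak baseline
by construction (decimated raw input). SURE thresholds assume the soft
shrinkage risk; no wavelet-packet, stationary-wavelet or
translation-invariant variants are implemented. Peak detection is tuned
to the simulator's morphology and should be revalidated on real sensor
data before any physiological use.
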