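# Methods

## Model

The decoder is a compact four-block convolutional network whose inputs,
weights and activations are complex. A raw window `X ∈ R^{C×T}` is z-scored
per channel and mapped by the full two-sided DFT to `X̃ ∈ C^{C×F}`, F = T;
the conjugate-symmetric upper half is deliberately retained so that the
feature maps keep width T throughout and the published shape trace
(including the flatten width F2·(T/16) = 192) holds exactly. Bin f covers
f·fs/T Hz; no taper is applied.

Layer algebra follows the complex product. A complex convolution or dense
map is four real ones, `Y = (H_r∗W_r − H_i∗W_i) + i(H_r∗W_i + H_i∗W_r)`;
average pooling and the split ReLU act on the two parts independently;
complex logits are read out through the elementwise modulus. Because the
modulus is invariant to a global phase, the probability head cannot depend
on an overall rotation of the logits — the property the phase-coded
synthetic task (below) probes end to end.

Block structure for config (C, T, F1, D, F2) = (62, 200, 8, 2, 16):
spectral CConv (1×101, same padding 50) → CBN → CReLU; depthwise spatial
CConv (C×1, multiplier D) → CBN → CReLU → CAvgPool (1×4); depthwise
(1×101, same) + pointwise 1×1 → F2 → CBN → CReLU → CAvgPool (1×4); flatten →
CLinear 192→64 → CReLU → CLinear 64→K → modulus → softmax. The depth
multiplier D = 2 is forced by the architecture's own consistency: the
pointwise stage emits F2 = 16 maps and the flatten width 192 = 16·12
requires D·F1 = F2. Convolution and dense layers carry complex biases;
the activation order is conv → normalization → activation.

### Batch normalization

The complex batch norm standardizes the real and imaginary parts
separately, each by its own per-channel batch mean and variance
(ε = 1e-5), then applies a single complex affine transform
`γ·(ẑ_r + iẑ_i) + β` with complex per-channel γ (init 1+0i) and β (init 0).
This "split standardization + complex affine" form is the simplest joint
affine on the two parts and keeps the parameter budget at two complex
scalars per channel; a full 2×2 covariance whitening would couple the parts
during standardization as well, at the cost of a more expensive and less
transparent transform, and is not implemented. Running statistics use an
exponential moving average (momentum 0.1) of the unbiased batch variance;
training mode requires batch size ≥ 2.

### Probability head

The modulus yields non-negative class scores; they are normalized by
softmax by default (well-behaved gradients for cross-entropy), with plain
sum-normalization available as `prob_head="sum"`.

## Parameter and operation accounting

`count_parameters` counts each trainable complex scalar once (a complex
weight = one unit): 16,355 for the default model, 3,176,483 when the
spatial block is removed (the classifier is then fed the uncompressed
16×62×50 map), 53,331 when the separable block is removed.
`count_flops` uses the stated convention 1 complex MAC = 4 real multiplies
+ 4 real adds = 8 real ops, counting convolution/dense MACs only; under
this convention the default model costs 82.6 M real ops per window. More
aggressive conventions (e.g. three-multiplication complex products, or
counting a MAC as one operation) scale this by a constant factor.

## Numerical core

All layers are built on a small reverse-mode autodiff engine over numpy
arrays; real and imaginary parts are independent real tensors, so the
gradients are the partial derivatives with respect to each part (checked
against central finite differences at 1e-4 on every primitive).
Convolutions are cross-correlations. Stride-1 kernels that are 1-D along
the frequency axis (the 101-tap spectral and separable kernels) run through
a single complex FFT per pass: the (real, imag) pair is assembled into one
complex array, convolved by spectral multiplication, and the two backward
passes reuse the cached input spectrum (real gradients enter via half-size
rfft plus Hermitian extension). Height kernels (the 62×1 spatial stage) and
small/strided kernels use a direct sliding-window contraction. Both routes
agree to machine precision and with a scalar-arithmetic brute-force oracle.
Training runs in float32 by default; float64 is used wherever closed-form
tolerances are asserted. sqrt at exactly zero propagates a zero subgradient.
Average pooling uses floor semantics (trailing partial windows dropped),
which the 200 → 50 → 12 width trace requires.

## Training protocol

Subject-dependent, trial-level splits: a 15-trial three-class session
trains on trials 1–9 and tests on 10–15; a 24-trial four-class session
tests on the last two trials of each emotion in session order. Windows are
1 s with 0.5 s overlap and never straddle the split. Optimization is
minibatch Adam (defaults β = (0.9, 0.999), ε = 1e-8) at batch 64 for 120
epochs; the learning rate is constrained to the searched range
[0.001, 0.035] (default 0.002, chosen for stability at this batch size and
parameter count) unless explicitly overridden. No schedule, weight decay or
early stopping. A trailing batch of a single sample is skipped (batch
statistics are undefined on it). Runs are deterministic given the seed.
Evaluation is per-window; confusion matrices are accumulated as counts over
subject-sessions and row-normalized to percent only at reporting time, so
pooled matrices are segment-weighted.

## Synthetic data

`generate_session` emulates the statistical skeleton of trial-structured
emotion EEG: K classes × trials_per_class trials of C channels at fs Hz.
Each trial is a sum of band sinusoids (default theta 4–7, alpha 8–13, beta
14–30 Hz, each snapped to an integer frequency so 1 s windows see it on the
bin grid) plus 1/f^α noise (α = 1), scaled so the per-channel
oscillation-to-noise variance ratio equals `snr`. Class information enters
via (a) amplitude coding — class k doubles its own band's amplitude — and/or
(b) phase coding — the montage splits into two equal channel groups and the
second group's oscillation is shifted by a class-specific offset, so
single-channel power spectra are class-matched and only the relative phase
carries the label. What this generator does *not* emulate: non-stationarity
within trials, artifacts (blinks, EMG), volume-conduction mixing, 1/f slope
variation across channels, or inter-subject variability. Passing the
capability tests therefore shows that the architecture can extract
amplitude- and phase-coded spectral structure at realistic SNR — not that
it attains any particular accuracy on real recordings.

## Test problem sizes

The capability checks run at desk scale, sized to keep the full suite
fast while preserving the stated study conditions (600 windows, SNR 5,
batch 64, fixed seeds): a 16-channel montage for the phase-capability run
(120 epochs; the model then has 15.6 K complex parameters — the spatial
kernel is the only C-dependent term) and for the 20-epoch amplitude run;
an 8-channel montage for the ten-seed loss-descent check. The magnitude
baseline is a scikit-learn logistic regression on |X̃| features; "chance"
is tested as a ±3σ binomial band around 1/K on the test-set size.

## Known limitations

- The DFT front end assumes within-window stationarity; transient dynamics
  are smeared across bins (an analytic-signal front end would be the
  natural extension).
- Published parameter totals are matched within 1% but not to the last
  unit; the residual (≈25 complex units on the default model) is consistent
  with small bias/affine bookkeeping differences. The mean-pool spatial
  replacement and the single-block variants reproduce the corresponding
  published totals only approximately under the shape-trace rules used
  here; they are provided for structural experiments, with one exception
  (the spatial-only variant, which lands within 0.1%).
- Checkpoints store the flat parameter map plus a JSON config in a single
  `.npz`; cross-dtype loading casts to the target model's dtype.
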