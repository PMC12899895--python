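# cveegnet

Complex-valued convolutional networks for decoding emotion-related structure
from multichannel EEG spectra.

EEG is oscillatory: at every frequency each channel has an amplitude *and* a
phase, and task-relevant information can live in either — or in their joint
(amplitude–phase) structure across channels. Real-valued networks fed with
magnitude spectra discard phase outright; fed with raw samples, they must
rediscover spectral structure from scratch. `cveegnet` implements an
end-to-end alternative: the raw multichannel window is mapped by the DFT to a
complex spectrum `X ∈ C^{C×F}`, and every subsequent layer — convolution,
batch normalization, activation, pooling, dense — operates in the complex
domain, so the amplitude–phase coupling is preserved all the way to the
classifier.

## The model

For a window `X ∈ R^{C×T}` (C = 62 channels, T = 200 samples at 200 Hz by
default), each channel is z-scored and transformed,

    x̃_c(f) = Σ_t x_c(t) e^{−j2πft/T},  f = 0 … T−1  (full two-sided spectrum)

and the complex image `X̃ = X̃_r + iX̃_i` passes through four blocks:

| block | operation | output |
|---|---|---|
| spectral  | CConv (1×101, same), F1 = 8, CBN, CReLU | (8, 62, 200) |
| spatial   | depthwise CConv (62×1), D = 2, CBN, CReLU, CAvgPool (1×4) | (16, 1, 50) |
| separable | depthwise CConv (1×101, same) + pointwise 1×1 → F2 = 16, CBN, CReLU, CAvgPool (1×4) | (16, 1, 12) |
| classifier | flatten (192) → CLinear 64 → CReLU → CLinear K | (K,) |

A complex convolution obeys the complex product,
`Y = (H_r∗W_r − H_i∗W_i) + i(H_r∗W_i + H_i∗W_r)`; CReLU rectifies the real
and imaginary parts independently; the complex logits `y ∈ C^K` become class
probabilities through a modulus readout `ŷ_k = |y_k| = √(Re² + Im²)` followed
by a softmax, optimized with cross-entropy. The default model has **16,355
trainable complex parameters (16.36 K)** — each complex weight, bias and
normalization coefficient counted once.

Everything runs on a small reverse-mode autodiff engine over numpy arrays
(`cveegnet.autograd`) with FFT-accelerated 1-D convolutions, so the package
has no deep-learning-framework dependency.

## Worked example

Two synthetic classes whose per-channel amplitude spectra are *identical*;
the label is carried only by the relative phase between two channel groups
at 10 Hz (`examples/04_train_phase_task.py`):

```
130 training / 70 test windows
magnitude-spectrum logistic baseline: 51.4% (chance is 50%)
complex network: 100.0% (loss 0.685 -> 0.0001)
```

The baseline sees only magnitudes and cannot beat chance; the complex
network recovers the inter-channel phase difference and separates the
classes completely. The other scripts in `examples/` walk through the layer
primitives, the spectral front end, and the architecture/ablation
accounting, each printing the quantities it computes.

## Data and protocol

`cveegnet.data` reads and writes trial-structured recordings as HDF5
containers (one group per trial; key names configurable, since dataset
releases differ) and generates synthetic sessions: band-limited oscillations
(1–50 Hz) on 1/f noise with class information encoded in per-band amplitude,
in inter-channel-group phase, or both, at a configurable SNR.
`cveegnet.training` implements the subject-dependent, trial-level protocol
(9/6 trial split for 15-trial three-class sessions; last-2-trials-per-emotion
test sets for 24-trial four-class sessions), minibatch Adam training
(batch 64, 120 epochs, learning rate searched in [0.001, 0.035]; default
0.002), and reporting: per-subject-session accuracy tables and pooled
row-normalized confusion matrices.

A thin CLI wraps the library for shell use:

```bash
cveegnet synth  --spec spec.yaml --out data/
cveegnet train  --config cfg.yaml --data data/ --out runs/exp1
cveegnet ablate --variant no_spatial --config cfg.yaml --data data/ --out runs/abl
cveegnet report --runs runs/exp1
```

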