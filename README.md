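# emgvmd

Spectro-temporal feature extraction for myoelectric pattern recognition:
Variational Mode Decomposition (VMD) of multi-channel surface EMG followed by
per-window singular-value reduction, benchmarked against EMD-based and
time-domain baselines with a 10-fold cross-validated classification harness.

## Who this is for

Researchers and engineers building EMG-driven control for prostheses and
rehabilitation systems, who need feature sets that capture the
non-stationary, stochastic character of surface EMG and a reproducible way
to compare them across classifiers.

## The method

Surface EMG channels are band-pass filtered (4th-order Butterworth,
10–450 Hz) and notch filtered (2nd-order, 50 Hz). Each channel *s* is then
split into *K* band-limited modes *uₙ* with center frequencies *ωₙ* by
solving the variational problem

```
min_{uₙ, ωₙ}  Σₙ ‖ ∂ₜ[ (δ(t) + j/πt) ∗ uₙ(t) ] e^{−jωₙt} ‖²₂
s.t.          Σₙ uₙ = s
```

via ADMM in the frequency domain: each mode is updated by the Wiener filter

```
ûₙ(ω) ← ( f̂(ω) − Σ_{i≠n} ûᵢ(ω) + λ̂(ω)/2 ) / ( 1 + 2α(ω − ωₙ)² )
```

its center frequency by the power-weighted mean
`ωₙ ← ∫ω|ûₙ|²dω / ∫|ûₙ|²dω`, and the multiplier by dual ascent
`λ̂ ← λ̂ + τ(f̂ − Σûₙ)`. Every mode is segmented with a 250 ms window at
10 % overlap, and each window is reduced to its singular value (for a 1×L
window, its Euclidean norm), giving an N × M feature matrix with
M = channels × K. Baselines: the same reduction on EMD intrinsic mode
functions, and eight time-domain descriptors per channel
(MAV, ZC, WL, RMS, SE, STD, VAR, SNR) plus the compact LS4/LS9 sets.
Feature matrices are classified with SVM (Gaussian kernel, box constraint 1),
KNN (inner-CV neighbour search), a grid-tuned decision tree, or a 146-tree
random forest under stratified 10-fold cross-validation.

A seeded synthetic-EMG generator emulates the acquisition protocol
(3 channels at 2000 Hz, 4 motion classes, 8 repetitions of 5-s contractions
with 5-s rests) with class-distinct spectral coloring, so the whole pipeline
is testable without any recordings.

## Worked example

```python
import numpy as np
from emgvmd import (VmdConfig, vmd_decompose, make_triharmonic,
                    ProtocolSpec, make_synthetic_emg, bandpass_filter,
                    notch_filter, extract_vmd_svd, extract_td8,
                    ClassifierSpec, cross_validate)

# 1. decompose a noisy three-tone signal (10/60/200 Hz at 1 kHz)
x = make_triharmonic(fs=1000, duration_s=1.0, noise_sigma=0.1, seed=1)
res = vmd_decompose(x, VmdConfig(K=3, alpha=2000.0))
print(np.round(res.center_freqs_hz(1000), 2))   # [ 10.    59.99 200.01]

# 2. classify synthetic gestures from VMD-SVD features
protocol = ProtocolSpec(n_reps=2, contraction_s=2.0, rest_s=2.0, seed=1)
rec = notch_filter(bandpass_filter(make_synthetic_emg(protocol)))
feats = extract_vmd_svd(rec, K=6)                # 70 windows x 18 columns
cv = cross_validate(feats, ClassifierSpec("RF"), k=10, seed=0)
print(feats.values.shape, round(100 * cv.mean_accuracy, 1))  # (70, 18) 100.0
```

The recovered center frequencies sit within a few hundredths of a hertz of
the true tones despite the added noise, and the 18-column spectro-temporal
feature matrix separates the four synthetic motion classes perfectly under
10-fold cross-validation.

A CLI mirrors the library: `emgvmd simulate | decompose | extract |
classify | sweep` (see `emgvmd --help`).

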