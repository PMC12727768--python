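# Methods

## Signal model and preprocessing

Recordings are real-valued multi-channel matrices at a fixed sampling rate
(2000 Hz in the emulated protocol) with per-sample integer motion labels
(0 = rest). Preprocessing applies a 4th-order Butterworth band-pass between
10 and 450 Hz and a 2nd-order IIR notch at 50 Hz. The filter family and
phase handling are design choices: Butterworth is the standard choice for
the stated orders, and both filters are applied zero-phase
(forward–backward, doubling the effective order) by default so features are
not skewed by phase distortion; a causal single-pass mode
(`zero_phase=False`) exists for streaming parity. The notch is the scipy
biquad design; its width comes from a quality factor (default Q = 30, or
`bandwidth` in Hz via Q = f0/bandwidth).

Windowing uses a 250 ms window with 10 % overlap, read as: step =
round(window × 0.9), i.e. 500-sample windows advancing by 450 samples at
2000 Hz, trailing partial windows dropped. Spans are 0-based, half-open.
Each window takes the majority label of its samples and is discarded when
no class exceeds 50 % (boundary-straddling windows); rest windows (class 0)
are excluded from classification by default.

## Variational mode decomposition

The solver implements the constrained bandwidth-minimisation problem with a
quadratic penalty α and Lagrange multiplier λ, alternating per-mode Wiener
updates, power-weighted center-frequency updates over ω ≥ 0, and dual
ascent with step τ. Numerical choices:

* **Spectral representation.** The signal is mirror-extended by half its
  length at each end (odd lengths are edge-replicated by one sample first),
  transformed with a real FFT, and all updates operate on the one-sided
  spectrum; modes are inverse-transformed and cropped back. Mirroring
  suppresses the edge ringing of the periodic FFT model.
* **Defaults.** α = 2000, τ = 0, tol = 1e-7 on the summed relative change
  of mode spectra, max_iter = 500. τ = 0 is the noise-tolerant pure-penalty
  method; τ > 0 (e.g. 0.5) enforces exact reconstruction and is what the
  reconstruction checks use. α is exposed because its effect on EMG
  features is an open tuning question.
* **Initialisation.** Default `peaks`: the K strongest maxima of the
  moving-average-smoothed power spectrum, greedily selected with an
  exclusion radius of 1/(8K) cycles/sample, unfilled slots falling back to
  uniform spacing. Uniform, zero and seeded-random schemes are available,
  but each of them proved able to strand a mode on broadband noise in the
  noisy three-tone benchmark (the stranded mode's Wiener filter sees only
  the local noise floor, so its center frequency never migrates to the
  remaining tone). Peak seeding starts every mode inside a spectral mass
  basin and converged in a handful of iterations on all benchmarks.
* **Degenerate cases.** An all-zero mode spectrum keeps its previous center
  frequency (an explicit `DegenerateModeError` at the operation level); an
  all-zero signal returns all-zero modes with zero reconstruction error.
  A `dc` flag pins ω₁ = 0 for signals with a DC/trend component, which VMD
  cannot otherwise isolate; default off since inputs are band-passed.
* **Ordering.** Modes are returned sorted by ascending center frequency,
  so feature columns are comparable across runs.

## Empirical mode decomposition

Sifting subtracts the midline of cubic-spline envelopes through the local
maxima and minima. Extrema are strict sign changes of the first difference,
with plateaus counted once at their midpoint. Before spline fitting, up to
two extrema at each end are reflected across the first/last sample to
suppress end swings. A sift is accepted when the Cauchy criterion
Σ(p_prev − p)² / Σp_prev² < 0.2 (default) holds *and* the candidate
satisfies the IMF property (extrema and zero-crossing counts differing by
at most one), capped at 100 sifts. Decomposition stops at an unsiftable
residue (fewer than two maxima or minima) or the IMF cap. The residue is
re-derived as input minus the IMF sum, so reconstruction is exact to
floating-point round-off.

## Feature sets

* **VMD-SVD / EMD-SVD.** Every (window, channel, mode) triple contributes
  one scalar: the singular value of the 1×L window, which equals its
  Euclidean norm. This is forced by the N × (channels × modes)
  dimensionality of the feature matrix; a reshaped-matrix variant
  (r = ⌊√L⌋ rows, leading singular value) is available behind
  `svd_mode="matrix"` since the window-to-matrix convention is genuinely
  open. Columns are channel-major with modes ascending in frequency. EMD
  produces a data-dependent number of IMFs, so the matrix is built for a
  fixed `n_imfs` (default 8) with missing columns zero-filled, keeping
  shapes stable across trials.
* **TD8.** MAV, ZC, WL, RMS, SE, STD, VAR, SNR. Formulas not fixed by
  convention are documented choices: VAR is the n−1 sample variance,
  SE = STD/√n (standard error), SNR = MAV/STD with 0 returned for a
  constant window. ZC counts adjacent sign changes whose amplitude jump
  exceeds a threshold (default 0).
* **LS4 / LS9.** LS4 = MFL, MSR, WAMP, L-scale. MFL = log₁₀√Σ(Δx)², with
  0 returned for a flat window (the logarithm is otherwise undefined);
  WAMP uses a 0.05 signal-unit threshold by default; LS is the second
  L-moment (probability-weighted-moment estimator), the set's namesake in
  the open-source EMG feature-library convention. The nine-feature set is
  MAV, ZC, SSC, WL, RMS, IAV, DASDV, VAR plus the L-scale — the common
  listing of this set names only eight descriptors, so the L-scale is
  appended to honour both the name and the channels × 9 column count.
* Concatenated sets (`combine`) stack columns and keep provenance in the
  column names.

## Synthetic data

`make_synthetic_emg` emulates the acquisition protocol — default 3 channels
at 2000 Hz, 4 motion classes, 8 repetitions of 5-s contractions separated
by 5-s rests — as amplitude-modulated band-limited Gaussian noise: per
class and channel, white noise is band-pass shaped to the class's
(center, bandwidth), normalised to unit RMS, scaled by a per-channel gain
and a trapezoidal envelope (10 % ramps), and added to a broadband
background of σ = 0.05. Default class profiles spread band centers from 40
to 320 Hz with per-channel offsets and distinct gain patterns, which makes
classes separable by spectral content — the property the spectro-temporal
features exploit. All randomness flows from one seed.

What the surrogate does **not** model: motor-unit recruitment and firing
statistics, electrode-skin impedance drift, crosstalk, movement artefacts,
inter-subject variability, or amputee-specific signal changes. Passing
tests therefore demonstrate the pipeline's correctness and its ability to
recover known class structure, not field performance on real recordings.

## Evaluation harness

Stratified k-fold splitting (default k = 10, shuffled, seeded) with a
logged fall-back to unstratified folds when a class has fewer than k
members. Features are z-scored with statistics fit on the training folds
only. Classifiers: SVM (RBF kernel, C = 1), KNN with the neighbour count
chosen by 3-fold inner CV over {1, 3, 5, 7, 9, 11} (clipped to the inner
training-fold size), a decision tree tuned over a small deterministic
max-depth × min-split grid (a reproducible stand-in for black-box
hyperparameter search, whose choice does not affect the harness
contracts), and a 146-tree random forest. Accuracy is trace/total of the
pooled confusion matrix per fold, averaged across folds; the coefficient
of variation is the sample standard deviation over the mean in percent.
The mode-count sweep re-extracts features from the raw signal for each K
and reports K, M = channels × K, N, accuracy mean ± std and the extraction
wall time — timing is reported, never asserted. Cross-validation pools all
windows by default; per-subject runs are obtained by calling the harness
per recording and aggregating with the COV helper.

## Problem sizes used in the checks

The bundled checks run at reduced scale — 2 repetitions per class of 2-s
contractions with 2-s rests (about 70 windows, 3 channels) for the
classification pipeline with K = 6 modes, and a 1-repetition recording for
dimensionality checks up to K = 12 — chosen so the full suite exercises
every stage, including the K = 12 / 36-column configuration, on a single
CPU in well under a minute per stage. Accuracy at this scale is expected
at or near 100 % for the default well-separated profiles; identical
profiles across classes drive it to chance.

## Known limitations

* VMD assumes a fixed K; adaptive mode-count selection and multivariate
  VMD are out of scope.
* The EMD boundary treatment (two mirrored extrema) is the classic
  heuristic; long monotone stretches at the edges can still bend the
  outermost envelope sections.
* The surrogate generator's stationarity within a contraction makes
  window-level features nearly i.i.d. per class, which inflates absolute
  accuracies relative to real EMG; comparisons *between* feature sets at
  fixed conditions remain meaningful.
* Ensemble EMD variants, significance testing across subjects, and
  deep-learning comparators are intentionally not included.
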