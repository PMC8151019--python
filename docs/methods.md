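# Methods

## Signal model and preprocessing

A trial is a `(channels × time)` recording of one subject holding one
gesture at one nominal force level, sampled at `fs` (default 2000 Hz).
Trials are cut into overlapped rectangular windows (default 150 ms window,
50 ms overlap, i.e. a 100 ms stride) and each window is filtered per
channel by a causal cascade: 4th-order Butterworth high-pass at 20 Hz
(movement artefact), 4th-order Butterworth low-pass at 500 Hz
(high-frequency noise), and a second-order IIR notch at 50 Hz with quality
factor 30 (power line). Filter family, order and phase behaviour are our
choices — standard surface-EMG practice — since only the cutoffs are
conventionally fixed; the causal (single-pass) realisation matches a
real-time pipeline, at the cost of a start-up transient inside each window
that affects all feature sets identically. Filtering is applied per window
(window → filters → features), with no state carried between windows.
Windows are 0-based, start-inclusive/end-exclusive; for trial length `L`,
window `N` and step `S` the window count is `floor((L−N)/S) + 1`.

## The force-invariant feature set

Per channel: `MV`, `P0`, `P2`, `P4`, `P6`, `AC1`, `AC2` as defined in the
README, each mapped through `ln(max(v, 1e-12))` to give `f1..f7`. The
`1e-12` floor keeps silent windows finite and is configurable. Sums over
differenced signals run over the entries that exist (`N−1` terms for `Δx`,
`N−2` for `Δ²x`, `N−3` for `Δ³x`): the written range `0..N−1` cannot apply
to a shorter difference sequence, and only this convention satisfies the
Parseval cross-check (`P0` of `Δx` computed by FFT). Odd-order moments
vanish by symmetry and are rejected as arguments.

The correlation block is the Pearson coefficient of every unordered channel
pair, in lexicographic order `(1,2), (1,3), …, (n−1,n)`, computed on the
filtered, un-logged window samples (the correlation branch taps the signal
path in parallel with the seven amplitude features). A zero-variance
channel yields 0 with a warning. Vector layout is channel-major `f1..f7`
then the correlation block; the ordering is fixed so reduced-space results
are reproducible. No per-feature standardisation is applied before SRDA;
min–max normalisation appears only in the 2-D scatter/RES path.

Force-invariance mechanism, verifiable algebraically: a uniform gain `g`
on a channel adds `2 ln g` to the `P`-logs and `ln g` to the `MV`/`AC`
logs, and leaves every correlation entry exactly unchanged.

## Baseline feature sets

Six classical sets are provided for comparison (dimensions for 8 channels):
Hudgins TD (32), extended TDF (48), order-6 Burg AR + RMS (56), TDPSD (48),
TSD (252) and 5-level Symmlet-8 wavelet statistics (240). Zero-crossing and
slope-sign-change thresholds default to 0 and the Wilson-amplitude
threshold to 0.01 (normalised units); all are explicit parameters because
they materially change the counts. AR coefficients use Burg's method
(stable on short windows). TDPSD/TSD follow the published descriptor
definitions — root-squared spectral moments with power-law compression
(λ = 0.1), sparseness, irregularity factor, waveform-length ratio /
coefficient of variation / Teager–Kaiser energy, log magnitudes, and for
TDPSD the cosine-style orientation `−2ab/(a²+b²)` between the raw and
log-squared signal paths. These are re-derivations from the published
definitions, not ports of the original MATLAB releases, so individual
values may differ from those codebases; the hand-computable components are
pinned by unit tests. TSD's spatial part applies the seven descriptors to
every pairwise channel difference `Cx − Cy`. Wavelet statistics (energy,
variance, sd, waveform length, Shannon entropy of normalised squared
coefficients — the entropy definition is our documented choice) are taken
on the six subbands of a periodized 5-level decomposition, so subband
energies sum exactly to signal energy; windows shorter than `2^5` samples
are rejected, and boundary-effect warnings on short windows are accepted.

## Dimensionality reduction

SRDA fits `c − 1` discriminant directions by regression: class-indicator
vectors are orthogonalised against the constant vector (via QR), and each
response is fitted by ridge-regularised least squares on the centred
feature matrix (default `reg = 0.01`; no value is conventionally fixed, and
results are insensitive over several orders of magnitude on the synthetic
data). Zero-variance columns are tolerated by the ridge. Classification
fits SRDA on the training folds jointly; the scatter/RES path reduces each
force level separately, then min–max normalises the first two dimensions
over the pooled point set (a constant dimension maps to 0.5 with a
warning). "Normalised" is read as per-dimension min–max because the
resulting scatter axes are bounded in [0, 1].

## Classification protocol and metrics

Classifiers: discriminant analysis with a quadratic boundary (per-class
covariances; a pooled-covariance linear switch is provided), RBF-kernel SVM
(unit box constraint, kernel scale `1/n_features`), and 3-NN with Euclidean
distance, ties broken by the nearest neighbour's label. Cross-validation is
trial-wise and deterministic: fold `f` holds out trial `f` for every
gesture and force; training windows come from the scheme's training forces
of the remaining four trials, so no window of a held-out trial ever enters
training. The four force-level cases are: (1) train = test = one force,
(2) train one force / test all three, (3) train two / test three,
(4) train and test all three.

Metrics are one-vs-rest per gesture (TP/TN/FP/FN), converted to accuracy,
sensitivity, specificity, precision and F1, macro-averaged over gestures
and reported in percent; macro-averaging is our documented choice (the
multi-class aggregation is otherwise underdetermined, and specificity only
exists one-vs-rest). A zero denominator defines that term as 0 with a
warning. Method comparisons use pairwise one-way ANOVA of the reference
method's per-subject(-per-scheme) score vector against each baseline's,
Bonferroni-corrected by the family size (default: the number of
comparisons) and clipped at 1; a pair with zero within-group variance in
both groups is flagged degenerate rather than assigned a p-value.

## RES index and the window-length sweep

`RES = ED̄ / σ̄`, where `ED̄` averages the Euclidean distance between
gesture-cluster means over all unordered gesture pairs using the first two
feature dimensions, and `σ̄` averages the within-gesture sample standard
deviation (ddof = 1, pooling each gesture's points across force levels)
over dimensions and gestures. The dispersion uses the same two dimensions
as the distances (the index is defined on the 2-D scatter; the dimension
count is configurable). RES is invariant to translation, uniform scaling
and label permutation, and is pinned against a brute-force double-loop
oracle at 1e-12.

The sweep evaluates RES for window lengths 50–400 ms in 50 ms steps on the
scatter construction (25 sampled windows per gesture per force = 450
points; sampling deterministic per seed). Windows advance with a fixed
100 ms stride for every length — the classification stride — because a
"50 ms overlap" reading would give a zero step at 50 ms windows.

## Synthetic data generator

Each gesture is a fixed `channels × sources` mixing matrix (4 band-limited
Gaussian latent sources, 20–450 Hz, standing in for muscle-group
activity), shaped by a per-channel activation envelope. A trial is
`gain · trial_factor · envelope(t) · (A @ sources) + noise`:

- `gain` per force level — defaults 1.0 / 2.0 / 3.5 for low / medium /
  high, separating amplitude features clearly while keeping all forces
  classifiable;
- `trial_factor`, a per-trial lognormal jitter (sd 0.15), and
  `envelope(t)`, a slow (≤1 Hz) lognormal drift (sd 0.2), model imperfect
  force maintenance: a subject tracking a nominal force by visual feedback
  holds it only approximately. Both are multiplicative and common to all
  channels, so they spread amplitude features without touching
  correlations — the mechanism by which the log transform visibly
  tightens clusters relative to raw features;
- `noise` is independent white sensor noise (sd 0.03 in channel units,
  i.e. a few percent of signal amplitude). Sensor noise is the one knob
  that genuinely degrades correlation invariance; at this level the
  correlation block drifts by less than 0.02 per entry when the force gain
  doubles;
- subjects are jittered copies (sd 0.1) of the shared gesture profiles.

The default grid is 9 subjects × 6 gestures × 3 forces × 5 trials of
8-channel, 10 s EMG at 2000 Hz. All randomness flows from one integer seed
through per-trial seed sequences, so trials are individually reproducible.

What the generator does *not* model: amputee-specific muscle pathology,
electrode shift, limb-position change, within-gesture nonstationarity
beyond the amplitude drift, or force-dependent spectral change (real EMG
shifts its spectrum slightly with force; here only amplitude scales).
Passing tests on this generator therefore demonstrate that the pipeline
exploits gesture-specific, force-stable spatial structure when it exists —
they do not predict absolute performance on amputee recordings, where the
published experience is substantially lower scores. A loader for the real
per-trial MAT layout is included for side-by-side runs when such
recordings are available.

## Problem sizes used by the test suite and acceptance script

The suite and `scripts/acceptance.py` run one synthetic subject with 4 s
(suite) or 8 s (acceptance) trials — 90 trials, ~3.5k/7k windows — which
is ample for every qualitative contrast evaluated (the Case-2 comparison
uses thousands of test windows) while keeping a full run around a minute.
The generator's defaults are unchanged by these runs; only `n_subjects`
and `duration_s` are scaled.

## Numerical choices and degenerate inputs

- log floor 1e-12 (features), `_EPS = 1e-12` guards in TDPSD/TSD ratios;
- correlation of a zero-variance channel → 0 + warning; SRDA on a single
  class → error; min–max of a constant column → 0.5 + warning;
- RES with all-degenerate clusters → "zero dispersion" error; a gesture
  with fewer than 2 points → error;
- trials shorter than one window → empty segmentation + logged warning;
- cross-validation with a missing trial for any gesture × force names the
  offending condition in the error.
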