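# Methods

`ecgrqa` implements a nonlinear-dynamics pipeline for multi-channel ECG
classification: delay-embedded recurrence images per channel, an
unsupervised convolutional autoencoder that fuses the channel stack into a
single small latent grid, and two classification heads — a CNN reading the
latent grid directly and a stacking ensemble reading ten recurrence
quantification (RQA) features of the latent grid.  This note records the
model, its assumptions, the tunable parameters, and the design decisions
taken where the method left choices open.

## Signal model and preprocessing

Records are multi-channel ECG in millivolts (canonically the 15 PTB leads:
12 conventional + Frank vx, vy, vz) sampled at 1000 Hz and downsampled to
250 Hz before analysis.  Downsampling uses rational-ratio polyphase
resampling; the anti-alias filter intrinsic to correct decimation is *not*
considered denoising, and no other filtering is applied — the analysis is
deliberately run on raw downsampled signals.  A naive keep-every-k-th
decimation mode exists for strict-literal reproduction.

Records are analysed on a fixed-duration window from the record start so
that the number of embedded states K is comparable across subjects.  The
full-scale default is 10 s at 250 Hz (N = 2500).

## Phase-space embedding

Each channel x₁…x_N is embedded as K = N − (M−1)τ state vectors
s_i = (x_i, x_{i+τ}, …, x_{i+(M−1)τ}).  The embedding lag τ comes from the
first minimum of the average mutual information (16-bin histogram
estimator; the first lag followed by an MI increase), with the first 1/e
crossing of the autocorrelation as an alternative.  The dimension M comes
from Cao's method: E1(m) = E(m+1)/E(m) with E(m) the mean ratio of
Chebyshev nearest-neighbour distances when the embedding is extended by one
dimension; M is the smallest dimension from which E1 stays within
`e1_threshold` of 1.  The default threshold is 0.2 because finite-sample E1
plateaus settle near 0.9 rather than 1 (with brute-force neighbour search
on windows of a few thousand samples); the companion statistic E2 ≈ 1 at
all m remains the cleaner signature of a stochastic signal.  Degenerate
duplicated states (e.g. a sine sampled commensurately with its period) are
excluded from the neighbour search.

The method leaves open whether (M, τ) are estimated per channel, per
record, or globally.  The pipeline default estimates one shared (M, τ) pair
from a reference channel (lead ii) of the first record, keeping the
recurrence-image geometry identical across subjects; per-channel estimation
is available through the same API.

## Recurrence images

The K×K matrix of pairwise Euclidean distances between states is the
recurrence matrix.  For the autoencoder, the matrix is min-max normalised
to [0,1] and bilinearly resampled to a fixed square image (224×224 at full
scale) — a continuous grayscale encoding; binary recurrence plots
(Heaviside threshold at ε, optionally chosen as the quantile achieving a
target recurrence rate, optional Theiler band) are used wherever line-based
RQA is wanted.  Per-record channel images are stacked in canonical lead
order, giving a C×224×224 tensor per subject.

Choices worth stating:

* The autoencoder consumes the *unthresholded* normalised distance matrix.
  Thresholding discards the distance gradations that make the image a
  meaningful grayscale input; both forms are exposed.
* ε is a single scalar per plot (the standard global-threshold recurrence
  plot).  A per-state threshold variant (fixed amount of neighbours) is not
  implemented.
* The Theiler band defaults to 0 — the feature formulas make no exclusion,
  so the line of identity is included.  Tests that measure dynamics
  (determinism of sine vs noise) set a Theiler band of 1 explicitly.
* Image resolution versus window length matters: one image pixel averages
  roughly (window length / image side) of signal.  At the full-scale
  default (10 s → 2500 samples, 224 px) a pixel spans ≈ 45 ms, which keeps
  QRS-scale texture visible.  Reduced-geometry runs scale the window with
  the image side to preserve this ratio; stretching a long window onto a
  small image averages beat-scale morphology away and measurably destroys
  class information.

## Autoencoder

A convolutional autoencoder maps the C×224×224 stack to a single-channel
14×14 latent grid: four stride-2 convolution blocks (kernel 4, padding 1,
ReLU; channel widths 32, 64, 128, then 1) halve the spatial side
224→112→56→28→14, and a mirrored transposed-convolution decoder with a
sigmoid output reconstructs the stack.  The bottleneck is a spatial feature
map (not a dense layer): the latent is meant to be read as an image by the
downstream heads, and its activation is linear so values are unconstrained
reals.  The loss is

    L(x) = mean|x − x̃|  +  (1 − MSSIM(x, x̃)),

the mean (not summed) absolute error so the two terms share scale, plus a
structural-similarity penalty.  MSSIM uses Gaussian-weighted windows with
the standard Wang parameters (window 11, σ = 1.5, population statistics,
data range 1) and is differentiated exactly through the same autodiff graph
as the convolutions.  Training uses Adam (default learning rate 5·10⁻³,
chosen for reliable CPU-scale convergence; batch size 16; hold-out
validation fraction 0.2; 1000 epochs at full scale).  All initialisation
and shuffling flow from one seeded generator, so training is bit-for-bit
reproducible.

The networks run on an in-repo reverse-mode autodiff engine over numpy
(im2col + GEMM convolutions, adjoint-based transposed convolutions).  It is
deliberately minimal — exactly the operations the two models need — and its
gradients are verified against central differences in the test suite.

## Latent RQA features

Ten features are computed from the diagonal/vertical line structure of a
square binary grid: recurrence rate RR, determinism DET, average diagonal
line length, longest diagonal line, diagonal-length entropy, laminarity
LAM, trapping time TT, longest vertical line, divergence DIV = 1/d_Lmax,
and the recurrence–determinism ratio RDR = N²·Σ_{len≥lmin} len·P(len) /
(Σ_{len≥1} len·P(len))², which coincides with DET/RR whenever no Theiler
exclusion is applied (the diagonal runs partition the recurrence points) —
an identity the tests assert.

* Minimum line lengths l_min = v_min = 2 (the standard RQA convention; the
  formulas leave them symbolic).
* Entropy is the Shannon entropy (natural log) of the normalised
  distribution of diagonal lengths ≥ l_min.
* Degenerate sentinels: no qualifying diagonal line → DET, mean length and
  entropy are 0; an empty grid → all ratios 0; no diagonal line at all →
  DIV is NaN (flagged missing rather than a silent division error).
* The latent grid is real-valued and the method does not state how it was
  binarised before line counting.  Default: min-max normalise, then apply
  Otsu's threshold, which adapts to each latent's own amplitude structure
  and keeps the recurrence rate informative.  A quantile policy (mark the
  top fraction of cells, pinning RR at that fraction and making the other
  nine features comparable at fixed density) is available; it discards the
  amplitude-pattern information that the latents carry, and on the
  synthetic benchmark this measurably weakens the feature route.

## Statistical screening

Every (feature, unordered group pair) combination is compared with a
two-sided Wilcoxon rank-sum test at α = 0.05.  No multiplicity correction
is applied by default (raw p < 0.05 reporting); Holm adjustment is behind a
flag.  The exact null distribution of the Mann–Whitney U statistic is
computed by the count (shift) recurrence for combined samples up to 25
without ties, and by enumerating group assignments when ties are present;
larger samples use the continuity- and tie-corrected normal approximation.
Significant results are reported at both granularities — distinct features
and (feature, pair) hits — since either count is a meaningful summary.

## Classification heads

**Latent CNN.** Three 3×3 convolutions (widths 16, 32, 64, stride 1,
padding 1) over the 1×14×14 latent, then six fully-connected layers
(256, 128, 64, 32, 16, classes) with softmax output, cross-entropy loss and
Adam.  Layer widths are this package's choice; only the layer counts are
fixed by the method.  Inputs are globally standardised.

**Stacked ensemble.** Base learners: an RBF-kernel SVM (with feature
standardisation — RBF kernels need commensurate scales — and probability
calibration), gradient-boosted trees (depth 3, 200 rounds), and RUSBoost.
RUSBoost is implemented in-package as SAMME boosting where each round fits
a shallow tree (depth 5) on a class-balanced random undersample drawn
proportionally to the boosting weights; boosting stops when the weighted
error reaches the SAMME bound or zero.  The meta-learner is logistic
regression over the concatenated base class-probability vectors.  Meta
features are out-of-fold (stratified 5-fold) by default; training the
meta-learner on in-sample base predictions — the literal procedure
described for the method — leaks training information and is available
behind `meta_features="insample"`.

Evaluation uses a stratified per-record train/test split (default 30%
test), a confusion matrix in the fixed class order HC, MI, BBB, CM, DR, and
per-class precision/recall/F1 with a zero-division → 0 convention.  The
original study does not describe its split protocol; with ~170 subjects and
single-record-per-subject classes the reported headline accuracies are not
reproducible without that protocol, so the package's own guarantees are
property-based (see below).

## Synthetic data

The generator provides (a) canonical signals — sine, Lorenz-x (RK4,
σ=10, ρ=28, β=8/3), logistic map, white noise — for validating embedding
and RQA behaviour, and (b) five-class quasi-ECG records.  A beat is a sum
of Gaussian waves (P, Q, R, S, T) with amplitudes ~1 mV; beats repeat at
normally-jittered intervals (mean 0.8 s); channels are fixed per-record
linear mixtures of the single beat source (gains 0.4–1.2, one inverted
aVR-like lead) plus white channel noise (σ = 0.03 mV).  Class morphologies:

| class | discriminating morphology |
|-------|---------------------------|
| HC    | regular rhythm (interval CV 0.02), narrow QRS |
| MI    | ST-segment elevation +0.25 mV, deepened Q (−0.3 mV), inverted T |
| BBB   | QRS widths ×2 with an R′ notch (0.6 mV) |
| CM    | amplitudes ×0.5, mildly widened QRS |
| DR    | strongly irregular rhythm (interval CV 0.25) |

These satisfy measurable contracts (DR interval CV > 0.15 vs HC < 0.05;
BBB QRS ≥ 1.5× HC at half maximum; MI ST offset ≠ 0; CM amplitude ≤ 0.6×
HC) that the tests verify by peak detection on the noiseless beat track.
The generator emulates lead redundancy and class-specific recurrence
texture; it does not model respiration, baseline wander, electrode
artefacts, P-wave arrhythmia subtypes, or intra-class pathology diversity.
Passing the synthetic benchmarks therefore demonstrates that the pipeline
machinery extracts and classifies recurrence structure — not that it
attains any particular accuracy on clinical ECG.

## Reduced geometry for CPU-scale runs

Full-scale settings (224 px, 14×14 latent, 1000 epochs) are impractical for
routine CPU testing.  The reduced geometry used by the test suite and the
acceptance script keeps the paper-facing quantities fixed (five classes,
15 channels, 250 Hz, 14×14 latent for the feature route) and scales the
rest: 56-px images over 2.5 s windows (preserving the ≈45 ms-per-pixel
resolution of the full scale), autoencoder widths (16, 32), tens of epochs
rather than 1000.  The autoencoder learning-progress check runs a separate
64-px / 8×8-latent configuration.  Problem sizes are stated in each test.

## Known limitations

* Under the quantile binarisation policy the RQA feature route fixes RR by
  construction, so class signal must come from the other nine features.
* Exact rank-sum enumeration is limited to combined samples of 25; larger
  groups silently use the normal approximation in `mode="auto"`.
* The autodiff engine is single-threaded float64 numpy; full-scale
  training (15×224×224, 1000 epochs) is possible but slow — hours, as with
  any CPU-only training of this size.
* Per-state (fixed-neighbour-count) recurrence thresholds, cross/joint
  recurrence plots, and windowed RQA time series are out of scope.
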