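# Methods

## Problem setting

A wheat canopy under progressive drought is imaged on seven key days
(1, 3, 6, 8, 12, 19, 25) with a hyperspectral camera and a thermal-infrared
camera. The task is to classify which key state a sample of plant pixels
comes from, using only interpretable inputs: six histogram statistics of ten
single-channel index images. The short study period covers days 1–12
(5 classes), the long period days 1–25 (7 classes).

## Index images and masking

Ten indices are computed per scene: TIR (the thermal image itself), NDVI,
GNDVI, GCL, SIPI, GI, the raw channels R₆₃₀/G₅₅₀/B₄₈₀, and NDblue. Channel
lookup resolves a named wavelength to the nearest cube channel within a
tolerance (default ±10 nm; ties go to the lower wavelength). The classical
index formulas are the standard literature forms; every band position is
configurable through `BandMap`, since different sensors sample different
grids. Pixels with a vanishing per-pixel denominator (e.g. SIPI where
ρ₈₀₀ = ρ₆₈₀) are flagged invalid (NaN) and excluded from masking and
feature extraction.

NDblue divides the green-minus-blue difference by its *image-wide* range, so
its output always spans exactly 1.0 and one constant threshold works across
days as the plant's absolute reflectance drifts. The plant mask is
`value > 0.1`, strict, with no morphological cleanup; it is rebuilt per day
from that day's own NDblue image. The same normalization (without the min
shift — the printed range-division form) is available for plain RGB frames
as NDGB. `compare_masks` reports per-candidate areas and pairwise Jaccard
overlaps, the quantitative core of choosing NDblue@0.1 over NDVI@0.15/0.25.
mNDblue = −(ρλ − ρ₄₅₀)/(ρ₈₅₀ + ρ₄₅₀) with λ = 550 nm is provided as the
un-normalized ancestor.

## Features

Masked pixel values are trimmed before anything else: TIR loses 1% at the
bottom and 5% at the top (hot background clutter leaks into thermal masks),
cube-derived indices lose 1% per side. Percentiles use the
linear-interpolation definition; if a pathological trim would empty the
sample, the single untrimmed median is kept so callers never see an empty
list. The six statistics are sample min/max/mean, population std (÷n — fixed
for reproducibility; at hundreds of pixels the ÷(n−1) distinction is
negligible), max−min, and Shannon entropy of the 64-bin equal-width
histogram over [min, max] of the (trimmed) sample. 64 bins keeps the
entropy estimate stable for subsamples of a few hundred pixels; it is
configurable. Entropy computed this way is invariant under increasing
affine transforms of the values, which is exactly why it measures state
*diversity* rather than state *level*.

Training samples arise by subsampling: each sample is an independent uniform
draw (without replacement) of ⌈0.15 · mask area⌉ mask pixels — the 10–20%
share at which classification quality is retained — with 100 samples per
day by default. Trimming is applied per subsample. How the original study
formed multiple samples per day is not recorded; random mask subsets are the
minimal mechanism and are declared as such.

## Classifier

One ReLU hidden layer between inputs and softmax outputs. Sizing follows
the index count: M = m × I inputs for m features of I indices, N = I + 5
hidden neurons (5 reserve), K output classes; the full configuration is
M = 60, N = 15, K = 7 with 60·15 + 15·7 = 1005 weights. Weights are
Kaiming-He normal (zero mean, variance 2/fan-in), biases zero.

Training: full-batch Adam on cross-entropy, learning rate 10⁻², at most 500
epochs, early stop when the epoch loss improvement falls below 10⁻⁶.
Features are z-scored per column from the training split (raw index scales
differ by orders of magnitude). The rate was set at 10⁻² because 10⁻³
demonstrably underfits small-M configurations within the epoch budget;
everything is configurable via `SLPConfig`. Mini-batching engages only above
1000 rows. Accuracy is averaged over independent trials (default 100; 50 in
the quicker checks), each with a fresh stratified 70/30 split, fresh
weights, and a fresh RNG stream spawned from the master seed; the mean
confusion matrix is row-normalized by true-class counts. A shuffled-label
control (labels permuted per trial) verifies that accuracy collapses to
1/K. Training time is recorded as summed wall clock per configuration; it
is reported for completeness but is hardware-dependent and not a stable
quantity.

## Ablation study

Four levels, each for both periods: (1) every (index, feature) scalar — 60
configurations; (2) all C(6,2) = 15 feature pairs within each index, with
the best single feature as the comparison diagonal and a flag for pairs
containing entropy or max−min; (3) each index with all six features
(M = 6, N = 6); (4) full-feature combinations of 2–5 non-TIR indices
(M = 6k, N = k + 5), enumerated exhaustively for sizes 2–3 and optionally
capped (deterministic subsample) for 4–5. Pairs are ranked by the sum of
short- and long-period accuracies, ties broken by summed training time
(faster first). Per-configuration seeds are derived deterministically from
the master seed and the configuration name, so reports are byte-stable.

## Synthetic data

The generator emulates the study conditions, not radiative transfer. Scene
rasters default to 64×64 with 8 bands (450, 480, 550, 630, 680, 700, 800,
850 nm) — desk scale; a 512×512×204 grid is available by configuration.
Plant pixels form spatially coherent blobs (a smoothed Gaussian random
field thresholded at the plant fraction, default 0.3). Background is a
single Gaussian "soil/pot" spectrum, dark and slightly blue-tinted so its
green-blue contrast sits below the NDblue threshold; its thermal channel
runs +3 °C over the canopy, which is what motivates the asymmetric TIR
trim. Sensor noise is additive Gaussian, σ = 0.005 reflectance.

Each key day is a Gaussian mixture over bands: a mixture mean that moves
along a healthy→dry spectral trajectory (visible up, blue down slightly,
NIR down), a per-band within-component spread, and 1–3 sub-populations
offset along the stress direction, modelling uneven stress entry. The
thermal mean rises +0.2 °C between day 1 and day 6, monotonically to +1.0 °C
on day 19, and falls back on day 25 (compensatory breakdown). Heterogeneity
follows the narrative trajectory: mild initial bimodality (day 1), a
leptokurtic homogenized state during active growth (day 3 — tight core with
a broad tail of laggards, which is what pushes its histogram entropy below
day 1), progressively separated sub-populations through days 6–19, and a
collapsed two-component state on day 25. The numeric trajectory constants
were calibrated once so that the *ordinal* entropy and spread patterns hold
with margin across master seeds (verified over 40 seeds during
development), and then frozen; nothing in the generator is fitted to any
real dataset, and absolute entropy values are not meaningful — only their
ordering is.

A `mean_matched=True` variant keeps the mixture mean and thermal mean
identical on every day and varies only spread and multimodality. It exists
to isolate the claim that the shape features (entropy, max−min) carry the
stress signal: on mean-matched data a (entropy, max−min) pair of the green
channel still classifies all seven states (≈0.94–0.98 mean accuracy) while
the single `mean` feature performs near chance.

What the generator does *not* emulate: leaf/canopy geometry, illumination
and white-reference effects, sensor-specific noise spectra, TIR/HSI
registration error (the two rasters are co-registered by construction;
real thermal cameras have a different raster), and the irrigated control
group. Passing tests therefore demonstrate that the pipeline's machinery
and its structural claims are sound under the stated statistical model —
not that the specific published accuracy tables transfer to other data.

On this generator one structural detail differs from the published study:
the index whose best feature pair falls short of 0.99 is NDblue rather than
NDVI. The reason is the same in kind — NDblue's image-range normalization
removes the level signal, leaving only shape information, just as the
published weak index lost its discriminative level differences.

## Numerical and degenerate-input choices

Range-normalized indices raise a degenerate-image error when the global
range is zero. Masks with no pixel above threshold raise an empty-mask
error; subsampling refuses masks under 10 pixels. Argmax prediction breaks
ties toward the lower class index. Confusion rows for classes absent from a
test split are left at zero (and stratified splitting guarantees presence
for the study's class counts). ENVI I/O supports BSQ interleave with
float64 payloads by default so cube round-trips are exact; feature tables
serialize floats at 17 significant digits for lossless CSV round-trips.

## Problem sizes used by tests and the acceptance script

Scenes 64×64 with 8 bands (≈1230 plant pixels per scene); 100 subsamples
per day at fraction 0.15 (≈185 pixels each); 50 trials for the headline
accuracy numbers, 20 for the mean-matched experiment, 2–5 for structural
grid checks. These sizes are the package's desk-scale defaults; every one
of them scales up by configuration.
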