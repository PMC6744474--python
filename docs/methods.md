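# Methods

This note documents the models, estimators, and numerical choices behind
`l4census`, and what the synthetic-data generators do and do not emulate.

## Electrophysiological feature extraction

**Protocol model.** A cell is a set of 600-ms square current steps on a
uniform time grid (the generators use 10 kHz), with 150 ms of pre-stimulus
baseline recorded. Two protocol variants are supported: *fixed holding*
(holding current 0 pA for every sweep, so the pre-stimulus voltage is the
resting potential) and *variable holding* (the pre-stimulus baseline is
offset sweep-by-sweep; the recorded current amplitude is the total injected
current during the step).

**Spike detection.** A spike is an upward crossing of dV/dt = 20 mV/ms;
the AP threshold is the voltage at that crossing, the peak the maximum
before repolarization below the threshold voltage. Excursions peaking below
−20 mV are rejected, and crossings within 1 ms of a previous peak merge
into it. These three constants operationalize the common practice of
current-clamp feature-extraction toolkits; no criterion is inferred from
data.

**Estimators.**

- *Resting potential / input resistance.* Fixed holding: median pre-stimulus
  voltage, and the median over hyperpolarizing sweeps of
  (steady-state deflection)/(injected current). Variable holding: slope and
  intercept of a robust line fit of steady-state voltage on current over the
  five most hyperpolarizing sweeps. The steady state is the mean raw
  voltage over the last 100 ms before stimulus offset — raw, because the
  100 ms average already suppresses noise and pre-smoothing would bleed
  post-offset samples across the stimulus edge. The baseline is the median
  of the 100 ms before onset. A slope in mV/pA is a GΩ; outputs are MΩ.
- *Robust line fits* (here and for the rheobase) enumerate all two-point
  candidate lines, score inliers with a residual threshold equal to the
  median absolute deviation of an ordinary least-squares prefit, and refit
  on the best consensus set. With at most ~15 sweeps this is the exhaustive
  limit of random-sample-consensus regression; it is deterministic and
  needs no seed.
- *Rheobase.* x-intercept of the robust fit of in-window spike count on
  current over the five lowest spiking currents, clamped to
  [highest silent current, lowest spiking current]; with a single spiking
  sweep the lowest spiking current is returned.
- *First-AP features* come from the first spike of the lowest-current
  spiking sweep. Width is measured at half amplitude with linear
  interpolation of the crossings. The AHP is threshold minus the post-spike
  trough (searched to the next spike, or 100 ms past the peak). The ADP is
  the first depolarizing hump above the trough within 10 ms: candidate
  humps are local maxima of a lightly smoothed trace (1 ms boxcar) with a
  0.5 mV prominence floor — a monotone recovery has none, so ADP is exactly
  0 for cells without a hump — and the amplitude is read from the raw trace
  against the raw trough.
- *Membrane τ.* Per hyperpolarizing sweep, a + b·exp(−t/τ) is fit by
  nonlinear least squares from stimulus onset to the voltage minimum
  (the "first phase"), with a log-linear initialization; the median over
  sweeps is reported. Subthreshold measurements (τ window, sag extrema) use
  a 3 ms boxcar-smoothed trace; spike detection always uses the raw trace.
- *Sag ratio* = (peak deflection)/(steady-state deflection) on the most
  hyperpolarizing sweep, both measured from the pre-stimulus baseline.
- *Adaptation index* = ISI₂/ISI₁, median over the five lowest currents
  with ≥ 3 spikes; *max spike count* counts spikes inside the stimulus
  window only.

Missing features (no hyperpolarizing sweep, no spikes, truncated AP) are
NaN and listed in `EphysFeatures.missing`, never silently zero.

## Morphology

Preprocessing soma-centers the reconstruction, then treats each branch
segment (between consecutive branch points/tips) as a polyline: resampled
to 1 µm arclength, with the slice-depth coordinate Y filtered by a
Savitzky-Golay filter (order 3, window 21, shortened to the largest odd
window that fits short segments). Segment endpoints are pinned so branch
points remain shared and the topology is exactly preserved; smoothing
across branch points would couple sibling branches, which is why the filter
is applied per segment.

Density maps sample points every 100 nm along each segment, normalize the
pooled coordinates of *all* cells of a cohort by one global minimum and
maximum (uniform scale, aspect preserved), project onto XZ, bin into
100×100 cells spanning [−0.1, 1.1]², and convolve with a truncated,
unit-mass 11×11 Gaussian kernel (σ = 2 bins, zero-padded borders, so mass
near the map edge may leak — interior-supported cells conserve mass to
better than 10⁻⁶ relative).

Morphometric conventions: stems are children of the root; branch points are
non-root nodes with ≥ 2 children (so tips = branch points + stems in a
strictly binary tree); branch order starts at 0 on stems and increments at
branch points; tortuosity is segment path length over end-to-end distance;
branch angles are measured between sibling directions at the branch point
(mean over sibling pairs when more than two children); path angles between
successive steps along a neurite.

## Pairwise classification and embeddings

The classifier is elastic-net-penalized logistic regression with mixing
α = 0.5. The penalty path contains 50 log-spaced values from λ_max (the
smallest λ that zeroes all coefficients) down to 10⁻³·λ_max; the inner
5-fold CV picks the largest λ whose mean deviance is within one standard
error of the minimum. Predictors are z-scored inside every fit using
training statistics only. The outer loop is 10×-repeated stratified 5-fold
(splitter seed 43); reported accuracy is the mean over the 50 held-out
folds. When density maps are among the predictors they are reduced to 10
principal components fit on the outer-loop training cells only. A
row-corruption probe (multiplying held-out rows by 10³ and checking the
fitted path is bitwise unchanged) verifies the absence of test-set leakage.

t-SNE uses the exact gradient, random initialization with seed 42,
perplexity 15 (early exaggeration 4 for morphology). For the combined
morphology embedding, density maps and morphometrics are each reduced to 10
PCs and each block is scaled by the standard deviation of its own PC1
before stacking into a 20-dim representation.

For the electrophysiology feature table, the t-SNE variant drops ADP
(zero-inflated) and latency (outlier-heavy), log-transforms the adaptation
index, and z-scores the remaining 11 columns; the classification variant
keeps all 13 with AI and latency log-transformed.

## Patch-seq mapping

Cells with total counts below 1500 are removed (strictly below; a cell at
exactly 1500 is kept). Variable-gene selection uses the dropout relation:
for genes with ≥ 32 reads in ≥ 10 cells, μ is the mean log₂ count over
counts strictly above 32 and τ the fraction strictly below 32 — a count of
exactly 32 contributes to neither, following the literal definitions; the
genes selected are those with τ > exp(−1.5 μ + b) + 0.02, with b found by
binary search (the selected-set size is monotone in b; if the target size
falls in a plateau gap, the attainable size nearest the target is returned,
preferring the larger set).

Mapping log₂(x+1)-transforms raw counts, intersects the atlas's
variable-gene list with the query's gene universe by name, and assigns each
cell to the argmax-correlation cluster centroid; zero-variance cells are
flagged unmappable. Embedding placement takes the coordinate-wise median of
the k = 10 most-correlated reference cells, with rank ties broken by
lexicographic reference-cell id.

## Sparse reduced-rank regression

The rank-r model minimizes ‖Y − XWVᵀ‖²/(2n) + λ(α‖W‖₁ + (1−α)/2‖W‖²) over
a sparse encoder W (genes × r) and an orthonormal decoder V (features × r).
With V orthonormal the loss separates, so the W-step is r independent
elastic-net regressions of YV on X (coordinate descent, tolerance 10⁻⁸) and
the V-step is the orthogonal Procrustes solution from the SVD of Yᵀ(XW).
V is initialized from the truncated SVD of the unpenalized least-squares
prediction; iteration stops when the relative loss decrease falls below
10⁻⁶ (at most 300 iterations), and the penalized loss is non-increasing by
construction (asserted in tests). The *relaxed* variant refits W without
penalty on the selected support and re-estimates V. After fitting, (W, V)
are jointly rotated so the training component scores XW are decorrelated;
the fit is invariant under this rotation and correlation biplots then obey
the unit-circle bound. Cross-validation standardizes X and Y per training
fold, reports pooled held-out R² (relative to ‖Y‖² of the standardized
targets) and per-component correlations corr(XW, YV) averaged plainly over
folds (no Fisher transformation).

## Circuit statistics

Connection probabilities are connected/tested per directed type pair;
zero-tested pairs are undefined (NaN), never 0; percentages print to one
decimal. The two-sided Fisher exact test sums hypergeometric probabilities
of all tables (margins fixed) no more probable than the observed one, with
the customary 1 + 10⁻⁷ relative tolerance against floating-point ties —
this minimum-likelihood convention reproduces the printed worked example
(p = 0.48 for 5/104 vs 3/122), whereas doubling the one-sided tail does
not. A degenerate margin yields p = 1.

Barrel detection normalizes the intensity profile to [0, 1], inverts
cytochrome-oxidase contrast, fits and subtracts the two-harmonic Fourier
baseline, smooths with a σ = 250 µm Gaussian, and reports local maxima
with prominence ≥ 5% of the smoothed range and ≥ 200 µm separation
(barrels are ≳ 200 µm apart). Two numerical choices matter here. First,
the baseline's fundamental frequency w is pinned to one cycle over the
sampled span (coefficients then solve a linear least-squares problem): the
baseline models uneven illumination varying on the scale of the image, and
freeing w lets least squares absorb leakage-correlated components of the
barrel periodicity itself — after σ = 250 µm smoothing (which attenuates a
400 µm period by ~4·10⁻⁴) that misfit would dominate the residual and move
the detected peaks. Pinning w keeps the baseline exactly orthogonal to
integer-cycle periodic structure. Second, the Gaussian smoothing uses
periodic (wrap) boundaries, consistent with the Fourier baseline's implicit
one-period view of the profile; reflective or edge-replicating boundaries
introduce artifacts larger than the attenuated barrel signal.

Known limitation: with only two barrels in a short field, the baseline's
second harmonic partially overlaps the barrel spacing, biasing detected
centers by ~20 µm (measured on the generator's default geometry); profiles
with more barrels or longer fields reduce this leakage.

## Synthetic-data generators

All generators are pure functions of their parameters and a seed.

**Sweep sets.** The subthreshold response is a leaky integrator
(exponential charging with τ); hyperpolarizing steps add a sag: the
deflection charges to the peak value d_ss(1 + sag) with time constant τ
(so the "first phase" is exactly exponential), then relaxes to d_ss with an
80 ms sag time constant. Spikes are stereotyped templates placed on the
subthreshold backbone at exact, known times: piecewise-linear rise
(0.6 ms) and fall (1.2 ms to threshold − AHP), an optional ADP hump (rise
then partial dip, so the hump is a genuine local maximum), and a fast
exponential recovery chosen to complete before the shortest permitted ISI
(8 ms) — overlapping tails would create spurious voltage steps at the next
AP onset, and each template tail is ramped back onto the risen backbone
over 3 ms for the same reason. The spike count follows the f–I line
n = slope·(I − rheobase); the ISI schedule is ISI₁, then a·ISI₁ for every
later interval, so the adaptation index is exactly a while long trains
still fill the window linearly in n. Gaussian voltage noise (0.1 mV SD,
typical of averaged whole-cell recordings) is added last. Ground truth is
exact by construction; the sag ratio and the first-AP threshold are
computed from the noiseless trace because they depend on the backbone
realization.

The population sampler draws resting potentials −75..−60 mV, input
resistances 80–300 MΩ, τ 12–35 ms, rheobases 30–150 pA, adaptation indices
0.9–2, sag amplitudes 0–0.5, AP amplitudes 55–85 mV, and latencies
10–100 ms — adult-cortex ranges. f–I gains are drawn from
{0.15, 0.2, 0.25, 0.3, 0.35} spikes/pA, i.e. an integer 3–7 extra spikes
per 20 pA step: with an integer count increment the rounding error of
integer spike counts is a *common* offset across sweeps, so the f–I
intercept (the quantity the rheobase estimator inverts) is displaced by at
most 1/(2·gain) ≤ 3.3 pA — the irreducible quantization of a 20 pA ladder —
rather than by independent per-sweep rounding noise.

**Morphologies.** Random binary trees grown by segment addition: active
tips branch with a fixed probability or terminate; segments are polylines
of 5 µm steps with angular wiggle (tortuosity) and an optional systematic
Z drift emulating laminar targeting. Counts and lengths are tracked during
growth.

**Counts.** Cluster centroids are log-normal expression profiles; counts
are negative-binomial (shared dispersion 0.2) around depth-scaled
centroids, so dropout arises from the count distribution itself — enough to
exercise the μ/τ selector without a separate zero-inflation term. Default
depth is 10⁴ counts/cell: the selectors and mappers are scale-free in the
regime where many genes clear the 32-read threshold, so emulating
million-read libraries would only slow the tests. The atlas is built from a
held-out reference half (per-cluster mean log₂(x+1) centroids, Gaussian
2-D embedding blobs per cluster, and a variable-gene list selected on the
reference counts).

**What the generators do not emulate:** biophysical AP shape diversity,
channel noise, electrode artifacts; real dendrite/axon identity and
laminar boundaries in morphologies; gene-length and batch effects, doublets
or ambient RNA in counts; distance-dependent connectivity. Passing the
round-trip tests therefore demonstrates the estimators are correct on data
satisfying their stated assumptions, not robustness to every artifact of
real recordings.

## Problem sizes

The test suite and acceptance script use 50 simulated cells for the
electrophysiology round trip, 500 cells / 300 genes / 5 clusters for
transcriptomic recovery, a 200-gene fixture for the gene-selection oracle,
n = 30 per class for the classifier checks, n = 200 / 100 genes for the
planted RRR model, and 100 random trees for the topology identity — sizes
at which every statistic is stable over seeds while the full pipeline runs
in a few minutes on one CPU.
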