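# Methods

This note documents the models and procedures implemented in `slns`, the
assumptions behind them, the defaults that matter, and what the synthetic
benchmarks do and do not show.

## The pipeline at a glance

A 2-D grayscale MRI slice passes through five stages:

1. **Noise normalization** — a hybrid fuzzy-Gaussian kernel.
2. **Texture features** — grey-level co-occurrence (GLCM) statistics.
3. **Segmentation** — HARIS, a heuristic two-objective clustering loop with
   elbow-based segment-count estimation and Mahalanobis pixel assignment.
4. **Classification** — a bidirectional sigmoid-recurrent network scores
   image patches tumor/non-tumor; segment-level fusion of patch votes
   produces the tumor mask.  A variational autoencoder can augment small
   training sets, and a persisted "self-learning memory" carries class
   weights and best fitness across runs.
5. **Impact analysis** — tumor core / enhanced / whole burden with
   texture-weighted damage indices and longitudinal progression.

All randomness flows from explicit integer seeds; every stage is
deterministic given its inputs and seed.

## Synthetic phantom

The phantom emulates a single axial slice: an elliptical skull ring (high
intensity), brain parenchyma, a circular tumor core and an enhancing rim,
over dark background, at 228x228 pixels by default.  Default region means
(background 5, brain 100, rim 140, core 180, skull 230) are pairwise at
least 10 intensity units apart — a *separability contract* every stage is
allowed to rely on and that the generator validates.  Noise is additive
Gaussian (default sigma 5) or Rician (modulus of a complex Gaussian
perturbation, the standard magnitude-MRI model); intensities are clamped to
[0, 255] and the clamping rate recorded.  Dataset generation jitters the
geometry and intensities per sample (relative uniform perturbation, default
10%) with per-sample seeds derived from one master seed.

What the phantom does **not** emulate: bias fields, partial-volume effects,
multi-modal contrasts, anatomical texture inside tissue classes, 3-D
continuity.  Passing phantom benchmarks therefore demonstrates the
machinery is correct and self-consistent, not that the pipeline reaches any
particular accuracy on clinical data.

## Noise normalization

The kernel combines each pixel with its Gaussian response `G` (sigma 1 px):

    out = lead - min(gain * f_z, 1) * (lead - smooth(lead))

`f_z(v) = 1 / (1 + ((v - t_max)/k_max)^(2 u_max))` is a bell-shaped fuzzy
membership.  By default the leading term is the **raw pixel** and the
reference level `t_max` is the pixel's own Gaussian response, making the
correction a fuzzy-weighted removal of the high-frequency residual: pixels
that agree with their neighbourhood (noise-like deviations) are smoothed
fully, pixels on a real tissue edge keep their value.  `k_max` defaults to
a robust noise-scale estimate (1.4826 x MAD of the residual, floor 1) and
`u_max` to 1.  The correction gain defaults to 4 with the effective
coefficient clipped at 1.

This choice was genuinely open: with the Gaussian response as the leading
term and a global reference level, the operator is a plain blur plus a
global soft-threshold and *increases* MSE against the clean image at noise
sigma 5–10 on the default phantom, because edge damage outweighs the
flat-region gain (edges here are 100–225 units tall).  The local-reference
raw-leading form reduces MSE at sigma 5, 10 and 20 in 20/20 seeded trials.
Both alternative forms remain reachable (`leading="gaussian"`, scalar
`fuzz_t_max`), and with `leading="gaussian"`, `gain=0` is exactly plain
Gaussian filtering (tested against a separable-convolution oracle).

A variance-of-Laplacian flag (threshold 50, configurable) records a binary
noisy/noise-free label in image metadata.

## GLCM texture

`counts[x, y]` is the number of in-bounds pixel pairs at displacement
`(d_row, d_col)` with quantized values `(x, y)`; symmetric mode counts both
orderings; probabilities are counts normalized by the total.  Grey levels
default to G=32 (256 levels would leave a 228x228 slice's matrix far too
sparse to be a stable feature).  Out-of-bounds pairs are skipped, never
wrapped.  Statistics: contrast, energy, homogeneity, Shannon entropy
(natural log, `0 log 0 := 0`).  The implementation is checked exactly
against a brute-force pair enumerator and against
`skimage.feature.graycomatrix`.

## Fitness machinery

* **Between-class variance** at threshold `t`: `w1 w2 (mu1 - mu2)^2`, the
  Otsu criterion; its argmax is verified to coincide with the exhaustive
  within-class-variance minimizer (Otsu duality) on random histograms.
* **Fuzzy-entropy threshold**: for each candidate level `t` the tumor
  membership of level `i` is the logistic S-curve `expit((i - t)/b)`, its
  complement the non-tumor membership; the score is the histogram-weighted
  Shannon entropy of the memberships split at `t` and the smallest argmax
  wins.  The bandwidth `b` is half the distance between the two most
  prominent histogram modes (fallback 32).  With this construction the
  score of a bimodal histogram peaks *between* the modes, because at a
  mode the far population contributes almost nothing while at the midpoint
  both populations contribute moderately; a too-small bandwidth collapses
  the threshold onto the dominant mode, which is why the bandwidth tracks
  the mode separation.
* **Intraclass correlation**: `var_seg / (var_seg + var_img)`; the
  doubly-degenerate case is defined as 0 and logged.
* **Segment fitness**: `p * N/k + q * sum_seg(S / n_seg)` with `S` the seed
  point count (defaulting to `k`).  The segmentation loop's `(alpha, beta)`
  fitness has the same shape and shares the code path.

## Self-learning memory and class weights

A JSON document (schema-versioned) holding the class weights, the global
best seed-point fitness (the running maximum over logged runs) and a run
log.  The weights are empirical: from smoothed 256-bin class-conditional
histograms of the classifier feature, `w_p` is the mean non-tumor/tumor
density ratio over the labeled samples and `w_q` the mean tumor density
mass (scaled so a uniform density gives 1).  Per-sample ratios are clipped
to [1e-2, 1e2]: with nearly disjoint class supports the raw ratio is
dominated by the smoothing pseudo-count and can reach 1e7, which would
zero out one class's loss weight in the next run.  Clipping preserves the
intended "much greater than 1 when separated" behaviour while keeping the
weights usable.  If a class is absent the weights are left unchanged with
a warning.

## HARIS segmentation

**Features.**  Default per-pixel feature vector: intensity plus two local
co-occurrence statistics (mean squared difference and mean inverse
difference of horizontally adjacent quantized levels over a sliding 9x9
window — the window-local GLCM contrast and homogeneity).  Intensity-only
mode exists for oracle tests.

**Initial segment count.**  The intensity histogram is clustered optimally
for j = 1..23 by dynamic programming (L1 cost about weighted medians over
the 256 bins; optimality makes the within-cluster distance curve monotone
non-increasing by construction).  The elbow is the maximum-curvature point
of the normalized curve (largest gap below the chord).  The scan ceiling of
23 reflects the expected over-estimate for a first hypothesis on this kind
of image; a constant image returns 1 with a warning.

**Objective I.**  Pixels go to the segment minimizing the Mahalanobis
distance; ties to the lowest id; empty segments are dropped with id
compaction.  The assignment metric is the **pooled** (pixel-count weighted)
within-segment covariance shared by all segments.  This was a correctness
decision, not a convenience: with each segment using its own covariance the
iteration is degenerate — a segment that grows its covariance scales its
distances down, swallows neighbours and grows further, and the fitness
diverges (observed directly on the default phantom).  Per-segment
covariances are still estimated (with ridge `1e-6 * trace/dim`) and
exposed; the per-segment RMS/mean contrast index is computed and logged but
does not drive assignment.  The partition is scored by
`f = sum_r alpha N / n_r + sum_r beta k / n_r` with
`alpha = sigma_i^2 / ((sigma_i^2 + sigma_e^2)/2)` from the pooled-within
and between-segment intensity variances and `beta` the class-probability
weighted within-class variance.

**Segment-count adaptation.**  The signal is the signed fitness change
between iterations: a negative signal splits the highest-variance segment
(new centroid at its farthest member), a positive one (with k > 2) merges
the two nearest centroids, zero leaves the partition alone.  Inside the
main loop adaptation is attempted when the fitness plateaus, and a
candidate is **gated**: a split is kept only when the target segment's
intensities are genuinely bimodal — the optimal 1-D 2-clustering of its
histogram must reduce the L1 cost by more than 60% (a single Gaussian
yields about 45%) — and the pooled within-variance improves; a merge is
kept only when it raises the pooled within-variance by less than 5%.
Without the gate the count collapses (the fitness's direct k-dependence
makes merges always look good) or explodes (splitting pure noise always
reduces within-variance).  The gate is what lets the loop start from an
elbow estimate of 3 on the default tumor phantom (the tiny core and rim
barely dent the area-weighted elbow curve) and still reach the correct 5
segments.

**Objective II.**  Per segment,
`sp_i = rand(0,1) * f_prev + rand(0,1) * (gb - f_prev)`; centroids move
`step * sp_i / gb` of the way toward the best configuration seen so far,
and the global best is the running maximum (hence non-decreasing).  The
step (default 0.1) decays as `1/(1 + iteration)` so the loop explores early
and converges late; with a constant step the stochastic nudging keeps the
fitness fluctuating above the plateau tolerance and the loop never stops.

**Stopping.**  Relative fitness change below `plateau_tol` (default 1e-4)
on two consecutive iterations with no accepted adaptation, or `max_iters`
(default 50, best-so-far returned with a warning).  Final segment ids are
sorted by ascending centroid intensity, which makes labelings comparable
across runs.  Non-brain pixels can be excluded via a mask and come back
labeled -1.

## VAE augmenter

A dense VAE sized for CPU desk scale: 32x32 inputs, one tanh hidden layer
of 256 per side, latent dimension 8, diagonal-Gaussian posterior, sigmoid
decoder head, Bernoulli per-pixel likelihood on [0,1] intensities (Gaussian
squared-error by flag).  Model, gradients and the Adam optimizer are
written directly in numpy; 200 epochs on 64 slices take well under a
minute.  The KL term is the closed Gaussian form and non-negative by
construction; it is cross-checked against a Monte-Carlo estimate in the
tests.  Log-variances are clipped to [-10, 10] for numerical safety;
divergence restores the last finite checkpoint.  Trained at this scale the
decoder beats the mean-image baseline by more than an order of magnitude in
reconstruction MSE; matching the training set's mean-intensity moments in
prior samples takes roughly 400 epochs.

## Recurrent patch classifier

Patches (default 12x12, one timestep per row; features = the row's
intensities plus four patch-level GLCM statistics, constant across
timesteps) feed two Elman-style sigmoid recurrences, one per direction;
a softmax readout on the concatenated full-context states `(ff_last,
fb_first)` gives the two class probabilities.  This is deliberately a plain
sigmoid recurrence, not a gated cell.  Training is batch BPTT with SGD
under the monotone schedule `lr = 0.1 / (1 + 0.01 * epoch)` (0.073 by epoch
38), cross-entropy weighted by the memory's class weights, balanced patch
sampling from the brain area, fully seeded.  Whole-image inference averages
the votes of overlapping patches (stride 4) into a per-pixel probability
map; the final tumor mask labels each *segment* by its mean patch
probability at threshold 0.5, so decisions come from the classifier but
boundaries from the segmentation.  How patch decisions become a region is
not dictated by the underlying model; this fusion is the package's
documented choice, and the raw probability map remains available.

## Impact analysis

From a ground-truth mask the core and enhanced regions pass through
unchanged; from a probability map, core = p >= 0.7, enhanced = a 3-pixel
morphological band around the core restricted to p >= 0.5, whole = their
union (disjointness and `whole = core + enhanced` hold by construction).
The damage index is `ln(1 + area) * (1 + GLCM contrast of the region)` —
area and texture are the two ingredients that matter for burden; the exact
functional form is the package's own, so the raw areas are always reported
alongside.  Its uncertainty ("erroneous index") is the half-width of a 95%
bootstrap interval over 200 resamples of the region's co-occurring pixel
pairs (pairs, not single pixels, because contrast is a pair statistic);
it shrinks roughly as 1/sqrt(n) on homogeneous regions.  Progression
reports absolute and relative deltas for all areas and indices and flags
growth only when the whole-area increase exceeds the two reports' combined
error half-widths.

## Evaluation

Pixel-level confusion counts with sensitivity, specificity, accuracy,
precision, F1 and Dice; zero-denominator ratios are 0 with an explicit
flag.  The end-to-end benchmark trains the classifier on 12 jittered
phantoms and evaluates the full pipeline on held-out jittered phantoms
(micro-averaged over pixels), 50 images by default.  Patch-level
evaluation is available through the patch encoder.

## Problem sizes and numerical choices

Benchmarks run at: 228x228 slices; 20 seeds for segmentation recovery; 50
trials for elbow recovery; 64 images x 200 epochs at 32x32 for the VAE; 50
images for the end-to-end benchmark — sizes chosen so the whole suite and
the acceptance script each finish in a few minutes on one CPU while keeping
every statistic comfortably away from its threshold.  Ties break toward
the smallest index everywhere.  Covariance ridge `1e-6 * trace/dim`;
logistic clipping at 1e-9 for Bernoulli likelihoods; histogram smoothing
pseudo-count 1e-6 per bin.

## Known limitations

* Phantoms are piecewise-constant; none of the benchmarks measure
  robustness to anatomy-like texture or bias fields.
* The elbow scan and bimodality gate operate on intensity only; structures
  distinguishable only by texture would need the gate generalized.
* The recurrent cell is a plain sigmoid recurrence; long sequences would
  saturate (patch rows are short by design).
* The damage index is ordinal, not physical: comparable within this
  package, not across instruments.
* 3-D volumes are processed slice-wise at best; no volumetric machinery.
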