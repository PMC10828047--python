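# Methods

## Synthetic paired dataset

Each pair couples two renderings of one number n ∈ {1, …, 9} that share a
color drawn from an 8-entry palette (red, green, blue, yellow, magenta,
cyan, orange, white):

* **Object scene** ("OSCN"): n solid objects of one shape (square, cross,
  triangle) at rejection-sampled positions on a black 32×32 RGB canvas.
  Object centers are at least 6 px apart in Chebyshev distance, so bounding
  boxes never touch and the connected-component count of the foreground
  always equals n — the renderer's ground-truth oracle used throughout the
  tests.  Shape and layout are private to this modality; number and color
  are shared with the digit.
* **Colored digit**: the numeral n rendered from a built-in 5×7 vector
  glyph, upscaled, affinely jittered (rotation ±10°, scale 0.85–1.1, shear
  ±0.15, shift ±2 px) under a per-image style seed, and tinted with the
  pair's palette color.  The jitter makes many visual patterns represent
  the same symbol, the property that forces the encoder to abstract over
  appearance.  Real MNIST IDX files can be substituted as the glyph source;
  nothing downloads by default.

Numbers are exactly balanced (counts per class differ by at most one);
the train/test split (80/20) is stratified by number; the whole dataset is
a deterministic function of one seed.  Archives are per-split, per-modality
compressed arrays plus one tab-separated label table.

**Equal-area objects.**  All three shape masks cover exactly 16 pixels, so
the total image intensity is 16·n times the color vector regardless of
shape.  Numerosity in these scenes is therefore deliberately carried by
total area, a cue that survives decoder blur and that small fully-connected
networks can exploit on CPU.  The generator exposes the shape masks in one
place for studies that want area and count decoupled; with the default
stimuli, "the model counts" and "the model integrates area" are not
distinguishable claims, and none of the package's conclusions depend on the
distinction.

**What the generator does not emulate.**  Real handwriting variability
(glyph jitter is affine, not stylistic), occlusion or size variation of
objects, luminance confounds beyond the area–count coupling above, and any
sensory modality other than vision.  Results on these stimuli demonstrate
properties of the learning rule, not of natural scenes.

## Models and training

Both modalities use the same architecture over a shared latent space
(default 20 dimensions, standard-normal prior):

* encoder: flattened pixels → 256 ReLU units → (location, softplus scale)
  of a diagonal Gaussian posterior (scales floored at 1e-4);
* decoder: latent → 256 ReLU units → per-pixel sigmoid mean.

The pixel likelihood is Gaussian with fixed scale σ = 0.1.  A Laplace
option exists but is not the default: under L1, the optimal prediction for
a pixel that is background in most scenes is the background itself, and at
this capacity the object decoder collapses to empty images; the L2 optimum
is the conditional mean, which preserves expected object mass even when
exact layout is not recoverable from 20 dimensions.

The multimodal objective is the K-sample importance-weighted
mixture-of-experts bound (K = 1 by default during training; the estimator
accepts any K and its variance shrinks with K, which the tests check).
Latents are reparameterized with explicit generator streams so runs are
bit-reproducible.  The log-sum-exp over mixture components and importance
samples detaches the max term, the standard numerically stable form.

Training uses adaptive-moment (Adam) updates, learning rate 1e-3, batch 64,
a fixed epoch budget (default 30) with no early stopping, one independent
model per seed (default five seeds per mode).  Single-mode training sums
the two per-modality bounds; the two autoencoders share no parameters, and
a gradient-isolation test asserts that one modality's loss has exactly zero
gradient on the other's weights.  Everything runs in float64 NumPy through
a minimal reverse-mode autodiff engine written for this package; its whole
op set is covered by central-finite-difference checks.

## Oracle classifiers

Generated images are scored by classifiers trained on clean labeled images
(train split) and validated on the clean test split; a classifier below the
clean-accuracy floor (default 0.95) refuses to score, because a weak oracle
would confound the measurement.  Raw-pixel MLPs memorize object layouts
instead of counting, so each factor is read from the invariant cue that
carries it: per-channel intensity totals for object-scene number and for
color (mass ∝ count at equal object areas; channel ratios identify the
palette entry), totals plus 4×4 block-averaged maps for digit identity, and
peak matched-filter responses of the three shape templates for shape.  A
small MLP (two 64-unit layers) is trained on those features per factor.

Reconstruction and cross-generation paths use the posterior mean, making
scoring deterministic.  Accuracies are unweighted means over the nine
number classes (classes are balanced by construction); confusion matrices
are tallied with rows = true number, columns = predicted.

## Latent metrics

All quantitative metrics use posterior-mean latents of test images in the
original latent space; the t-SNE embedding (perplexity 30, fixed seed,
PCA initialization) exists only for figures.

* **Silhouette** per factor: mean silhouette over points, Euclidean metric.
* **Number-line correlation**: Pearson r (Spearman available) between the
  36 pairwise Euclidean distances of per-number centroids (arithmetic mean
  of latents per class) and |i − j|, or |log i − log j| for the
  compressed-scale variant.  Degenerate inputs (identical centroids,
  single-label factors) raise instead of returning a number.
* **Mode comparisons**: Welch's unequal-variance t-test with
  Welch–Satterthwaite degrees of freedom, two-sided.  Welch is used for all
  ensemble comparisons because seed ensembles from different training modes
  have no variance-equality guarantee.  Chance-level comparisons use the
  one-sample t-test against 1/9, with zero-variance inputs flagged rather
  than silently producing infinities.

## Arithmetic probe

All 489 triples (a, b, c) ∈ {1..9}³ with a + b − c ∈ [1, 9] form the full
expression set; evaluations use a seeded subsample balanced over answers
(default 8 expressions per answer, 5 image draws per expression, operand
images drawn from the test split by label).  The probe is
decode(z_a + z_b − z_c) with posterior-mean latents, scored by the number
oracle against a + b − c.  Expressions with a = c reduce to reconstructing
b up to within-class latent spread, a cancellation property the tests
exploit as a sanity bound.

## Problem sizes

The default experiment configuration follows the full protocol: 2,700
pairs, 30 epochs, five seeds per mode.  The test suite exercises the same
code at desk scale — 1,800 pairs, 25 epochs, three seeds per mode for the
ensemble-direction checks, and 900 pairs for unit-level fixtures — sizes
chosen as the smallest at which the qualitative pattern (all generation
paths above chance; multimodal ensembles ahead on object-scene silhouette,
number-line correlations, and arithmetic) is stable across seeds.  The
acceptance script trains one model per mode at 2,700 pairs / 30 epochs.

## Known limitations

* Fully-connected coders cannot localize many objects from 20 latent
  dimensions; object-scene reconstructions are diffuse, and their scored
  accuracy (~0.2) is far below the digit modality's (~0.97).  The package's
  claims are about orderings and chance bounds, not absolute accuracy.
* The per-image silhouette for object-scene numbers is near zero even when
  the centroid number line is almost perfect: within-class layout variance
  dominates point-to-point distances.  Both metrics are reported for this
  reason.
* With equal-area objects, numerosity and total area are confounded by
  design (see above).
* Digit-modality arithmetic success partly reflects cancellation-type
  expressions (a = c or b = c), which require only good clustering, not a
  number line; the single-modal digit model scores well above chance on
  those.  The multimodal advantage is the meaningful signal.
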