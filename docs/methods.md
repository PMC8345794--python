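# Methods

This note documents the modeling and numerical choices behind `stroketex`,
what the synthetic phantoms do and do not emulate, and the limitations a
user should keep in mind.

## Problem and pipeline

The task is three-way classification of brain MRI slices into stroke
severity syndromes (LACS / PACS / TACS) from image texture alone.  The
pipeline is: resize + CLAHE → ADASYN balancing → 3-level DWT → fused
GLCM + GLRLM + HOS feature extraction over 7 sub-images → ANOVA-F ranking →
sequential forward selection + SVM → stratified 10-fold cross-validation
with confusion-count metric arithmetic.

## Preprocessing

Images are loaded as [0, 1] floats (integer rasters scaled by the dtype
maximum; multi-channel inputs collapsed by the channel mean) and resized to
200×200 with bilinear interpolation (anti-aliased when shrinking; nearest
and bicubic are available).  CLAHE uses 8×8-**pixel** tiles (a 25×25 tile
grid at working resolution), a normalized clip limit of 0.01 interpreted as
a fraction of the per-tile histogram, 256 histogram bins, and bilinear
blending of the tile mappings.  A `tile_mode="grid"` switch instead
interprets the tile parameter as the number of tiles per axis, since many
CLAHE implementations are parameterized that way.

## Wavelet stack

Each preprocessed image is decomposed with a 3-level 2-D DWT (default
`haar`, symmetric boundary extension; any discrete PyWavelets family can be
configured).  A 2-D DWT level yields three detail subbands but the catalog
uses one detail image per level, so H/V/G are fused by a configurable rule:
`mean_abs` (default, (|H|+|V|+|G|)/3), `diagonal`, or `max_abs`.  Haar is
the default because it is orthonormal, making the level-1 energy-partition
test exact to 1e-9.  Approximation and detail images are linearly
renormalized to [0, 1] before texture extraction so gray-level quantization
is well defined per sub-image; the raw coefficients remain accessible for
numerical checks.

## Texture features

**Quantization** bins [0, 1] uniformly into L levels (b = ⌊vL⌋, v = 1
clamped), default L = 8 — a small L stabilizes co-occurrence statistics on
200×200 images; 16/32/256 are configurable.

**GLCM**: distance-1 offsets at 0°/45°/90°/135°, symmetrized, counts
averaged over angles before normalization (standard rotation-robust
Haralick practice).  The default feature set holds 14 features: the 12
named linear/nonlinear features (autocorrelation, max probability,
dissimilarity, entropy, cluster shade, sum average, sum entropy, sum
variance, difference variance, difference entropy, IMC1, IMC2) completed
with cluster prominence and homogeneity; contrast and any other registry
member can be swapped in via configuration.  All logarithms are natural
with 0·log 0 ≡ 0; sum variance follows Haralick's original definition
(centered on the sum-entropy value); a degenerate marginal makes the IMC1
denominator zero, in which case IMC1 is 0 and a warning is logged.

**GLRLM**: maximal equal-level runs are counted per direction
(0°/45°/90°/135°) and the 11 Galloway/Chu/Dasarathy–Holder features are
averaged over directions.  Gray-level indices in the low/high-gray emphasis
weights are 1-based to avoid division by zero at level 0.

## Higher-order spectra

Projections are taken with the Radon transform over the inscribed circle of
the image (values outside are zeroed), so a projection of a 200×200 slice
has 200 samples; the angle convention is chosen so that a vertical
structure projects most sharply at 90°.  The projection of the
mean-subtracted image is zero-padded to nfft = 256 and the bispectrum is
the direct single-segment estimator B(f1,f2) = X(f1)X(f2)X*(f1+f2) with a
rectangular window — projections are short (≤ 256 samples), so segment
averaging would leave too few samples per segment.  Features are computed
over the non-redundant triangle Ω = {0 ≤ f2 ≤ f1, f1+f2 ≤ fs/2}:

* entropies 1/2/3 — Shannon entropies (nats) of |B|, |B|², |B|³ normalized
  to distributions over Ω (the convention of the bispectral-entropy
  feature literature);
* phase entropy — entropy of the phase histogram over N = 64 uniform bins
  of (−π, π]; zero-magnitude points are excluded (their phase is
  undefined), which makes a single-point bispectrum's phase entropy 0;
* mean magnitude — |B| averaged over Ω.

An identically zero bispectrum is defined to yield (0, 0, 0, 0, 0).  Note
that the *magnitude* of a single-segment bispectrum is insensitive to
quadratic phase coupling; coupling is detected in the magnitude of the
complex average over realizations, which is how the property test checks
it.

## Balancing

ADASYN oversamples every minority class toward the majority count
(one-vs-largest multiclass extension, processed ascending by class size).
Seed difficulty r_i is the fraction of majority-class members among the
k = 5 nearest neighbors in the full set (Euclidean metric); when no seed has
majority neighbors the budget is spread uniformly.  The per-seed budget is
apportioned by largest remainder so the class total is met exactly —
independent per-seed rounding can under-fill a class by up to half its
size.  Synthetics are x_i + λ(x_z − x_i), λ ~ U[0, 1), with x_z one of the
seed's k nearest same-class neighbors, so every synthetic is a convex
combination of two same-class originals; the synthetic count per class is
deterministic, hence seed-independent.

Balancing defaults to flattened-image space *before* feature extraction
(the protocol the pipeline reproduces); `balance.space = "features"`
applies it per training fold inside cross-validation instead, which is the
leakage-safe alternative.

## Ranking and evaluation

Each feature is scored by the one-way ANOVA F ratio (MS_between/MS_within);
zero within-group variance with separation gives F = ∞, p = 0; an all-equal
column gives F = 0, p = 1.  Ranking is F descending with ties broken by
original column index; since the F tail is monotone this is identical to
ranking by ascending p.  By default the ranking is recomputed on each
training fold (no selection leakage); a `global` mode ranks once on the
full matrix.

SFS walks the ranked list greedily, keeping a candidate when it strictly
improves accuracy under an internal stratified 5-fold CV of the training
split; scanning stops when consecutive non-improvements exceed `patience`
(default 5; 0 yields the longest strictly-improving prefix) or at
`max_features` (default 50).

SVMs are fit on train-standardized features (the train-fitted scaler is
applied to the test split) with C = 1; poly kernels use coef0 = 1 and
degree 2 or 3; the RBF gamma defaults to 1/(n_features·Var(X)).  Multiclass
decisions use one-vs-one voting.

### Confusion-count collapse

The three-class confusion of each fold is collapsed to binary TP/TN/FP/FN
with the majority (reference) class as the negative pole: TP counts
non-reference samples assigned exactly their correct class, FN the
remaining non-reference samples, TN/FP the correctly/incorrectly labeled
reference samples.  The counts then sum to the test-set size, ACC equals
the plain multiclass accuracy (so a shuffled-label null sits near 33 % for
three balanced classes), and on a balanced three-class problem the
positive:negative base is ~2:1 — consistent with the reference fold tables
this package's arithmetic is validated against.  A micro-averaged
one-vs-rest collapse is available (`collapse="micro_ovr"`), but note its
ACC is (1+2c)/3 in the balanced three-class case (c = multiclass accuracy),
i.e. ~55 % at chance.  When classes are balanced the reference class is
ambiguous; it can be set explicitly (`cv.reference_class`, e.g. `PACS`).

### Metric arithmetic and rounding

Per-fold metrics are exact rationals rounded **half-up** to 2 decimals.
Fold averages are means of the *unrounded* per-fold values, rounded the
same way — averaging the printed 2-decimal values instead shifts the RBF
mean accuracy from 93.62 to 93.61, so display rounding is never allowed to
propagate into summaries.  Zero-denominator metrics are reported as
undefined (`None`), never as 0, and are skipped in averages.

## Phantom generator

Each phantom is a Gaussian random field (unit variance, Gaussian smoothing
with a class-specific correlation length) inside an elliptical brain mask
(semi-axes 0.45/0.38 of the canvas), plus one soft-edged elliptical lesion,
plus pixel noise (σ = 0.05), clipped to [0, 1].  Class defaults on a
200-pixel canvas (geometry scales with the canvas):

| class | corr. length | lesion radius | contrast | offset | reading |
|-------|--------------|---------------|----------|--------|---------|
| LACS  | 2 px | 8 px  | +0.35 | 0.06 | small, high-contrast, deep |
| PACS  | 4 px | 20 px | +0.25 | 0.22 | medium, off-center cortical |
| TACS  | 6 px | 48 px | +0.20 | 0.10 | large, ≥ 25 % of the brain mask |

Class identity is carried by texture statistics and lesion geometry, not by
global intensity, so the GLCM/GLRLM/HOS extractors are genuinely exercised.
The phantoms do **not** model MRI physics (no pulse sequences, bias fields,
partial-volume or motion effects), anatomy, or the overlap between real
syndromes; a perfect phantom score therefore demonstrates that the pipeline
recovers class structure when present, not clinical-grade accuracy.
Accordingly the published classification figures on real MRI data are
covered as exact arithmetic reproductions from their per-fold confusion
counts, plus behavioral properties: oracle agreement of the extractors,
phase-coupling detection, ADASYN invariants, ≥ 90 % cross-validated
accuracy on well-separated phantoms and chance-band accuracy under label
shuffling.

## Problem sizes and determinism

The end-to-end evaluations (acceptance script and acceptance tests) use 60
phantoms per class at 200×200 with an 18-angle HOS grid (θ = 5°, 15°, …,
175°), 10-fold CV and three shuffled-label replicates; the full 6475-column
catalog is exercised on single images and in scaled-down pipeline runs.
All randomness flows from one run seed through named substreams (phantom,
balance, cv, sfs); identical configuration and seed give bit-identical
feature tables.

## Known limitations

* The 14-GLCM default set is one defensible completion of the classic
  12-name list; alternatives (e.g. including contrast) are configuration,
  and changing the set changes the 175-feature texture block accordingly.
* The detail-fusion rule, wavelet family, HOS estimator parameters and
  SVM hyperparameters are conventions, not fits; all are exposed in the
  config.
* Balancing before extraction (the default, reproducing the study
  protocol) lets synthetic/real image pairs straddle CV folds; use
  `balance.space = "features"` for the leakage-safe variant.
* Radon projections are taken over the inscribed circle; image corners are
  ignored (dark in brain imagery and in the phantoms).
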