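# Methods

This note documents the models, numerical choices and known limitations
behind blotmap. It is written for someone who wants to know exactly what
the package computes and what its validation does — and does not — show.

## The pixel-wise correlation statistic

Given an aligned, normalized stack of n gel images and one biological
value per sample, every pixel contributes n intensities. Both the
intensities and the covariate are converted to midranks (average ranks
for ties — essential for ordinal covariates such as FAB class, where ties
dominate), and

- r = Pearson correlation of the two rank vectors,
- t = r·sqrt((n−2)/(1−r²)),
- p = two-sided tail probability of Student's t with n−2 df.

The t approximation is the convention of standard statistical packages
and is the default here; for n ≤ 8 an exact mode enumerates all n!
covariate orderings and reports the fraction of orderings with |r| at
least the observed value (the identity permutation is included, so
p ≥ 1/n! and never 0). At |r| = 1 the t form degenerates; p is floored at
the smallest positive double rather than 0 so that downstream log-scale
work stays finite.

Pixels whose intensity is constant across samples carry no rank
information. They are marked *undefined* and excluded from masks and
regions — deliberately not r = 0, which would dilute significance masks
with artifactual nulls.

Significance masks threshold the raw per-pixel p at a chosen alpha
(0.005 and 0.02 are the conventional reporting thresholds for this assay;
0.05 for cohort statistics) and split by the sign of r. P-values are
reported unadjusted to keep region maps comparable across studies; a
Benjamini–Hochberg variant (`bh_significance_mask`) exists but is off by
default. Regions are 8-connected components with at least `min_area`
pixels (default 20 — a speckle filter tuned to the synthetic resolution,
not a biological constant). Each region is re-scored by summing its
member pixels per sample and applying the same Spearman machinery to the
sums; a single-pixel region therefore reproduces that pixel's map values
exactly.

Note on region t-values: for a region with summed-intensity Spearman r,
this package always reports t = r·sqrt((n−2)/(1−r²)). Printed t-values in
the literature for this assay are not always reproducible from r and n by
that formula (the aggregation used by legacy in-house software can
differ); we do not attempt to mimic any other aggregation.

## Preprocessing

Order: background subtraction → alignment → normalization.

**Background.** Each image's q-quantile (default q = 0.05) is subtracted
and the result clipped at zero. Spots occupy a small area, so a low
global quantile tracks the membrane background; because the downstream
statistic is rank-based, the choice among monotone background corrections
is uncritical. A consequence worth knowing: with Gaussian pixel noise of
standard deviation σ, the 5% quantile sits ≈1.645σ below the background
mean, so a residual of ≈1.645σ per pixel survives subtraction. This
residual is what dominates the total intensity used by normalization.

**Alignment.** Translation-only, integer-pixel registration: the offset
applied to each image is the argmax of the FFT cross-correlation of
mean-subtracted images against a reference (a stack index, default 0, or
an explicit template). The search is restricted to
|dy|, |dx| ≤ `max_displacement` (default 20 px). The restriction is not
an optimization: a p53 blot contains repeated similar structures (the FL
charge train and the β/γ pair have similar x-spacings), and an unbounded
argmax can lock one spot row onto the other ~90 px away whenever the
relative spot amplitudes of the two images are sufficiently discordant.
Gel-to-gel misalignment is physically small; a bounded search encodes
that. Borders exposed by shifting are filled with the image's own 5%
quantile (a background estimate), not zero, to avoid spurious rank
structure at edges. Flat (zero-variance) images cannot be registered;
they are flagged and passed through unshifted rather than aborting the
stack. Realigning an aligned stack yields zero offsets.

The aligned stack lives in the *reference image's* coordinate frame. Any
mask or ROI defined in another frame (e.g. a simulation's ground-truth
coordinates) must be translated by the reference's own displacement
before being applied to the aligned stack; the recovery harness does
this.

**Normalization.** Every image is scaled so its total intensity equals
the stack's median total. This removes per-image exposure/loading factors
exactly (the statistic becomes invariant to arbitrary positive per-image
scalings) while preserving relative spot proportions within each image,
which ROI densitometry needs; quantile normalization would destroy the
per-pixel intensity interpretation. Scaling one input image can move the
median itself, in which case all outputs change by one common factor —
irrelevant to every rank statistic and every ratio downstream. The
operation is idempotent.

A subtle, quantified side effect: after normalization each region's
signal is divided by a total that contains every other region's
amplitude. If two regions' amplitudes are coupled to the covariate with
opposite signs, each region's normalized signal inherits a small
perturbation anti-parallel to the other's, biasing both recovered
|Spearman| upward by roughly (cv·M_other/T) / (signal CV) · ρ_other,
where M is the other region's integrated spot mass and T the image total.
With the default synthetic geometry this bias is ≈ +0.02 on a planted
−0.61 at n = 21 — visible in the recovery means and well inside the
validation tolerance, but a genuine property of total-intensity
normalization that practitioners of this assay inherit, not an artifact
of the implementation.

## The synthetic study generator

The generator is the package's stand-in for patient gels, and its
defaults define the validated study conditions.

**Geometry.** 256×256 gels; five axis-aligned Gaussian spots — FL1, FL2,
FL3 side by side at row 88 (the FL charge train along the pI axis, FL1
most acidic/leftmost), β and γ at rows 176/184 (lower molecular weight).
Spot widths σ = (2.2, 1.6) px, peak amplitudes 400–1070 intensity units
on a flat background of 100, i.i.d. Gaussian pixel noise with σ = 15
(minimum peak-SNR 23), and a uniform random integer misalignment of up to
±3 px per sample. Amplitudes and sharpness were chosen so that spot mass
is a small fraction (~3%) of the post-subtraction image total, keeping
the normalization coupling described above small, while every spot core
remains individually detectable at the per-pixel level. Axis-aligned
Gaussians were chosen because their integrals are analytic
(2πAσxσy), which gives densitometry an exact oracle.

**Covariates.** Continuous (VPA-response-like): normal with mean 8.5 and
SD 25, clipped to [−60, 60] — matching a cohort whose median response is
8.5% with a range of about −56% to +49%. Ordinal (FAB-like): uniform on
{0,…,6}.

**Planted associations.** Each planted region key (a spot label, or the
groups FL = {FL1,FL2,FL3} and BETA_GAMMA = {β,γ}) receives one per-sample
amplitude factor shared by all its spots, so the summed region signal
carries exactly the planted coefficient — planting the two β/γ spots
independently would make their *sum* correlate more strongly than either
spot, which is the wrong contract. The factor is an affine transform
(mean 1, CV 0.35, clipped at 0; clipping is rare at this CV) of a latent
Gaussian g = ρz + sqrt(1−ρ²)ε, where z are Blom normal scores of the
covariate midranks. Because z is fixed given the covariate, the expected
sample Spearman coefficient has an exact closed form (a pairwise sum of
normal CDFs), and ρ is solved by root-finding so that E[sample r_s]
equals the requested value at the study's actual n, ties included. The
classical bivariate-normal identity ρ = 2·sin(π·r_s/6) is recovered in
the n→∞ limit; using it directly would leave a bias of ≈0.02–0.03 at
n = 21–29 and |r_s| ≥ 0.5, which matters when validation tolerances are
±0.05. Monte-Carlo calibration (500+ replicates per value) confirms the
planted means to within ~2 standard errors across continuous and ordinal
covariates.

**What the generator does not emulate.** Antibody chemistry, transfer
efficiency, saturation, spatially varying background, rotational or
elastic distortion, spot shape irregularity, and covariate measurement
error are all absent. Passing recovery tests therefore demonstrates the
*statistical* correctness of the pipeline under controlled conditions —
not robustness to every artifact of real membranes. In particular,
translation-only registration is exactly the generator's misalignment
model; on real gels with warping, a dedicated registration method would
be needed upstream.

## Densitometry

ROI quantification mirrors hand-drawn integrated-density measurements:
signal = sum of intensities in the ROI box minus the sum in a paired,
equal-area background box on empty membrane ("signal minus background
signal in a similar region"). Equal areas make a flat background cancel
exactly; mean-based correction is therefore unnecessary. Negative
corrected signals are clamped to 0 and flagged rather than raised — real
blots produce them, and analyses can filter on the flag. The FL:β/γ ratio
is undefined (NaN, excluded) when the β/γ signal is 0; log2 transforms
exclude nonpositive values with a warning rather than yielding −inf; fold
induction divides by the designated control condition, which maps to
exactly 1.0. ROI placement is user-supplied (or derived from the
synthetic layout); automatic spot detection is out of scope, matching how
these ROIs are drawn in practice.

## Cohort statistics

Spearman (on original values) and Pearson (conventionally on
log2-transformed signals) correlations use the same t machinery with
df = n−2; first-order partial correlations use
r_xy·z = (r_xy − r_xz·r_yz)/sqrt((1−r_xz²)(1−r_yz²)) with df = n−3,
validated against the least-squares-residual formulation to 1e−10 and
cross-checked against pingouin. Missing values are removed listwise
within each analysis, and the effective n is always carried on the result
object — printed p-values in this literature are sometimes consistent
only with silently reduced n, so blotmap never hides exclusions. The
reporting convention is two-sided p < 0.05.

The VPA response metric is (1 − mean(treated)/mean(control))·100 from
triplicate counts-per-minute; it is negative when treated cells
proliferate more than control. FAB labels M0–M6 map to 0–6 with subclass
letters ignored (M5a → 5); anything else (including M7) is rejected
rather than guessed.

## Validation design and problem sizes

The test suite checks each operation against an independent oracle
(brute-force rank correlation, exhaustive permutation enumeration,
analytic Gaussian integrals, residual-regression partial correlations)
and the pipeline end-to-end by parameter recovery: 200 seeded studies per
design, planted coefficients +0.80/−0.61 (n = 21, continuous) and −0.52
(n = 29, ordinal), with the mean recovered region coefficient required to
land within ±0.05 of the planted value. Null calibration uses 16 384
independent noise pixels at n = 21 (binomial 3·SE band around 0.05).
These sizes give Monte-Carlo standard errors of ≈0.01 on recovered means
— small against the ±0.05 band — while keeping a full run at minutes on
one CPU. `scripts/acceptance.py` reruns the recovery computation from
scratch with a caller-supplied seed.

## Known limitations

- Registration is translation-only and integer-pixel by design; the
  statistic's pixel identity stays crisp, but warped gels are out of
  scope.
- The normalization coupling bias (above) is inherent to total-intensity
  normalization with anti-correlated regions; it is measured and small
  at the default geometry, but grows with spot mass relative to image
  total.
- Detection at alpha = 0.005 has a hard floor at small n: two-sided
  p < 0.005 at n = 21 requires per-pixel |r| > 0.594, so regions whose
  true association is at or below that cannot appear in the 0.005 mask
  however clean the gels; coefficients just above it are detected only
  in the seeds where the realized sample coefficient lands above the
  threshold. Region-level statistics (summed intensity) do not suffer
  this pixel-level floor.
- Exact permutation modes are factorial in n and guarded at n ≤ 9.
- Per-pixel p-values are unadjusted by default; users scanning many
  pixels for discovery (rather than reproducing threshold maps) should
  use the BH variant.
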