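# Methods

## The measurement problem

High-content screens of 3D organoids read drug response out of morphology
rather than ATP. A well is a two-channel confocal z-stack — nuclei
(Hoechst-like) and F-actin (phalloidin-like) — and the analysis must turn
it into a single per-well response number that rises with drug effect, so
that a dose-response curve and an EC50 can be fit. The pipeline follows
the standard high-content pattern: project, segment, featurize, reduce to
a phenotypic distance against vehicle controls, fit.

## Synthetic screen generator

Because the pipeline must be testable without patient images, the
generator renders wells with known ground truth.

**Geometry.** Organoids are spheres with a concentric spherical lumen.
The actin channel renders the epithelial shell with a polarized-cortex
intensity model: membrane running parallel to the optical axis (the
annulus outside the lumen footprint) is bright; the apical caps directly
above and below the lumen carry a dim floor (10% of shell amplitude).
This is what gives maximum-intensity projections the dark-lumen
appearance of real phalloidin MIPs — a literal uniform 3D shell would
project to a filled disc and no lumen would ever be measurable in 2D.
Nuclei are Gaussian blobs (6 µm radius) placed on the shell; the nuclei
channel also carries a faint (4%) cytoplasmic body.

**Acquisition.** Defaults: 25 z-planes at 10 µm steps, 3.25 µm/px
lateral (low-magnification confocal with binning), 256×256 frames,
background 100 counts, Gaussian read noise SD 5, Poisson shot noise on
signal. Arrays are (z, y, x), 0-based.

**Dose → phenotype.** A severity fraction θ ∈ [0, 1] follows the Hill
occupancy θ(d) = E_max·dⁿ/(dⁿ + EC50ⁿ). θ linearly interpolates four
morphology axes: mean radius shrinks up to 40%, the lumen fraction of the
radius shrinks up to 60%, the expected nucleus count per organoid drops
up to 50%, and small bright debris blobs appear in both channels in
proportion to θ. Effect sizes are generator defaults chosen to look like
a strong cytostatic/differentiating response; they are design choices,
not estimates of any specific biology.

**Plate design.** Defaults mirror a standard screen: 9-point 2-fold
dilution series, 8 replicate wells per dose, 8 DMSO control wells, 384
wells capacity. `generate_screen` accepts per-compound top doses so that
each compound's dose range can bracket its own EC50 (e.g. 100 nM /
250 nM / 1.25 µM tops for compounds at 2 / 36 / 319 nM). Per-well seeds
derive from blake2s(master_seed, well_id), so wells are independent but
the whole plate is bit-reproducible from one integer.

**Out-of-focus objects.** A configurable fraction of organoids is
rendered collapsed into the top or bottom plane with heavy blur, so the
focus filter has genuine positives.

**What the generator does not emulate.** Optics (PSF, z-attenuation,
bleaching), Matrigel refraction, irregular/branched organoid shapes,
plate-edge and batch effects, and cell-level texture. Passing tests
therefore demonstrate that the analysis recovers what this geometry
encodes — counts, sizes, lumen structure, intensity — not that it would
segment any particular instrument's images unchanged.

## Segmentation

Analysis is 2D-projection based: per-channel maximum-intensity
projection, with the arg-max plane index kept as a focus map. Organoid
foreground is Otsu on a Gaussian-smoothed (σ 2 px) weighted channel sum
(0.6 actin + 0.4 nuclei, each max-normalized), hole-filled, with objects
under 150 px removed. A robust blank-frame guard (threshold must exceed
median + 6·1.4826·MAD of the smoothed frame) returns an empty labelling
on noise-only frames instead of thresholding noise.

Touching organoids are split by watershed. Seeds are maxima of the
smoothed distance transform of the foreground (minimum spacing 15 px),
not of nuclei density: nuclei in this geometry lie on the epithelial
shell, so the smoothed nuclei density of two touching organoids peaks
*between* them and mis-seeds the split. Components without a peak get
their distance-transform maximum as seed, so nothing is lost. Labels are
renumbered 1..n in row-major order — fully deterministic.

Lumens are detected per organoid: pixels below 0.4× the organoid's
median actin intensity, at least 2 px inside the organoid boundary,
minimum 9 px area, then dilated 1 px (within the interior) to recover the
rim that optical blur erodes. Nuclei: the smoothed nuclei channel is
thresholded by the maximum of Otsu and a bright-tail floor
(median + 0.3·(99.8th percentile − median)) — the tail floor stops the
faint cytoplasmic body from dragging Otsu down — and clumps are split by
watershed on the distance transform. Each nucleus is assigned to the
organoid containing its centroid; orphans are discarded.

**Out-of-focus filtering.** Per organoid, the focus score is the
variance of the Laplacian of the lightly smoothed (σ 1.5 px) actin plane
at the object's modal focus plane, normalized by squared mean intensity.
Smoothing first matters: raw shot noise has Laplacian variance
proportional to intensity and drowns the structural signal. Scores are
strongly bimodal (defocused objects score ~20× lower than sharp ones,
which themselves vary ~2× with size), so the rule is relative: remove
below 0.25× the per-well median score. A median−3·MAD rule was rejected:
with several defocused objects the MAD inflates and removes nothing,
and with few wells the natural spread of sharp objects gets clipped.
The relative rule is also idempotent in practice. Border-touching
organoids are always removed; children follow their parents.

**Detection floors.** The minimum organoid (150 px) and lumen (9 px)
areas are deliberately low. Larger floors make shrunken organoids and
lumens drop out of the masks discontinuously at high dose, which bends
the distance-versus-θ response convex and inflates fitted EC50s several
fold; with low floors the response is close to proportional and EC50
recovery is unbiased. Debris is rejected by shape and brightness
thresholds rather than area alone.

## Morphometry

Per organoid, the registry computes: 24 shape descriptors (areas,
perimeter via the Crofton estimator, axis lengths, Feret diameter,
eccentricity, solidity, extent, form factor 4πA/P², aspect ratio,
skeleton length and branch points — each size descriptor in px and µm
variants); 32 intensity statistics (8 stats × 2 channels × whole object
and epithelial shell); and for each child class (lumen, nucleus) counts,
presence flags, mean/max of the child shape descriptors, total areas,
child intensity, plus relational features (lumen-to-organoid area ratio,
lumen centroid offset, nuclei per unit area). That is 177 per-organoid
features; mean/median/SD/sum aggregation over the organoids of a well
plus the organoid count yields 709 per-well columns. Ratios with empty
denominators are 0 with a companion presence flag, so vectors never have
missing values; the SD aggregation uses ddof=0 so single-organoid wells
report 0, not NaN.

Two numerical choices differ from scikit-image defaults, both checked
against independent geometric oracles in the tests: solidity uses a
pixel-centre convex hull (Delaunay membership count), which makes
digitized convex shapes score exactly 1 where the corner-based hull
under-reports by ~5%; and perimeter uses the Crofton estimator, which is
within ~1% of the analytic circumference on discs of radius ≥ 12 px
where the weighted boundary count errs by 2–5%.

## Phenotypic distance

Training contrasts DMSO control wells with the top-dose wells of one
compound (per compound, per line). Features with zero variance are
dropped; the rest are standardized by the global training mean and the
pooled *within-class* SD. The default selection strategy fits a PCA on
the two class-centroid vectors: its first component is exactly the
standardized class-mean-difference direction, so ranking features by
|loading| ranks them by class separation in noise units. The top 10 are
retained (ties break by name; loading sign is fixed so the largest entry
is positive).

Full-matrix strategies (`pc1`, `best_separating`) are provided but not
default: with ~16 training wells and ~700 features the leading
eigenvalue of the pure-noise sample covariance (~(1+√(p/n))² ≈ 50)
exceeds any plausible signal eigenvalue, so every variance-maximizing
component is sampling noise and planted discriminating features are not
recovered. The centroid strategy recovers 3 planted 5-SD features among
its top 10 in 100/100 seeded repeats in the test suite.

Every well then gets D = ‖z − c‖₂ over the selected features, where z is
the well's standardized vector and c the standardized control-well
centroid (computed on training controls). D is reported per well and as
mean ± SD per (compound, dose) condition. D is invariant to positive
rescaling of any raw feature (the SD rescales with it), non-negative,
and 0 at the centroid.

## Dose-response

The 4PL r(d) = bottom + (top−bottom)/(1 + (EC50/d)^hill) is fit on log10
dose by bounded trust-region least squares (scipy), one point per well,
equally weighted. Initialization is data-driven (extreme-dose means; the
dose whose mean response is nearest the midpoint as EC50; hill 1);
bounds: EC50 ∈ [min dose/10, max dose×10], hill ∈ [0.1, 10], top/bottom
within the data range ± one span and unconstrained in order, so rising
distance and falling viability curves use the same code. The fit is
demoted to "No fit" when any of: the optimizer fails; |top−bottom| <
2× the pooled control-well SD (or the pooled replicate SD when no
controls are given); r² < 0.5 (strict); the EC50 lands within 5% of a
search bound. These thresholds are this package's operationalization of
the no-credible-curve outcome; the 0.5 cut is deliberate and strict
(r² = 0.49 is No fit).

Auxiliary calculations: percent viability = 100·raw/mean(control raws);
ΔΔCt fold change 2^−ΔΔCt with the housekeeping reference; derivation
rate = 100·established/collected.

## Problem sizes used in the tests

End-to-end checks run on scaled screens: 192×192×25 stacks, 5 organoids
per well, the full 9-point/8-replicate design (224 wells/screen, ~45 s
each), 3 screens for potency-order recovery; 50 seeded wells for
segmentation fidelity; 100 seeded repeats for feature-selection and
4PL-recovery statistics (those need no images). The demo analysis in
`analysis/` uses 128×128 frames and 3 replicates so the whole chain runs
in about a minute.

## Known limitations

Nucleus counts under crowding are lower bounds: 2D projection merges
nuclei that overlap in (x, y), so counts track but undershoot truth
(≈10–12 detected for 12 rendered on a large shell). Lumen areas carry a
±1 px rim uncertainty from blur compensation. The insensitive-line
"No fit" behaviour depends on the control-noise criterion; with very few
control wells the pooled SD estimate is itself noisy. Fitted EC50s from
distance curves are unbiased only insofar as the distance responds
proportionally to θ; feature sets dominated by late-collapsing
structures (e.g. lumen disappearance) bias EC50 upward, which is why the
detection floors above matter. No batch-effect handling is included.
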