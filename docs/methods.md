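# Methods

## The concavity statistic

A spore silhouette is a simple closed polygon in µm, counterclockwise, with
at least 64 vertices. Its suprahilar depression is

depression% = 100 · (area(hull) − area(shape)) / area(hull),

with the hull from a standard planar convex-hull construction on the
vertices and both areas from the shoelace formula (shapely provides both;
tests cross-check against an independent shoelace/qhull oracle and against a
brute-force pixel-counting oracle at 0.005 µm/px, which agrees within 0.1
absolute %). The statistic is similarity-invariant and zero exactly for
convex silhouettes. It equals 100·(1 − solidity), but is reported as the
concavity percentage because the biologically meaningful quantity is the
indented fraction of the hull.

Length is the maximum caliper (Feret) diameter over convex-hull vertex
pairs; width is the maximal extent perpendicular to the length axis. One
deliberate consequence, pinned by a regression test: the Feret length of a
rectangle is its diagonal. Feret-based axes stand in for manual ocular
measurements; the round-trip tests characterise (rather than correct) any
systematic offset, which is below 0.5 % at the default raster scale.

## Synthetic silhouettes

No generative spore model is published, so the generator uses the simplest
smooth family that can represent the three shape classes and be calibrated
exactly:

- **Body**: two half-superellipses sharing the width axis. The proximal half
  is elliptic (exponent 2); the apical exponent is 2 − 0.8·apex_sharpness,
  so apex_sharpness ∈ [0, 1] sweeps blunt-ellipsoid to acutely amygdaliform
  while the body stays convex.
- **Apiculus** (amygdaliform only): a raised-cosine ventral protrusion of
  height min(0.4 µm, 0.08·W) near the proximal end, lateralised by
  apiculus_offset. It is part of the silhouette — spores are segmented whole
  — but never extends the length or width extents, so L/W calibration
  excludes it, matching the convention of measuring spores without the hilar
  appendix. Because the hull bridges over the apiculus, an amygdaliform
  silhouette has a small floor concavity (≈0.4 % at the pulverulentus
  dimensions) even without a notch; targets below the floor raise an error
  naming the attainable range.
- **Suprahilar notch**: a raised-cosine indentation of chord
  notch_width_frac·L on the ventral flank immediately distal to the
  apiculus. Its depth is found by bisection so that the *measured* concavity
  of the discretised polygon equals the target within 5·10⁻⁴ absolute. The
  hull is recomputed for every candidate depth: the hull of a notched
  silhouette bridges the notch with a chord, so it is slightly smaller than
  the base ovoid's hull, and reusing the latter would miscalibrate by tens
  of percent (relative).

Rasterisation marks the pixels whose centers lie inside the polygon, via an
even-odd scanline fill with a half-open vertex rule — exact with respect to
that inside test and O(rows × edges). Masks are stored y-up with the scale
in µm/px; image writers flip rows. Contours are re-extracted at the 0.5
iso-level (marching squares), which roughly halves the staircase bias of
pixel-boundary polygons. Residual raster bias inflates the measured
concavity by about +0.4 % (absolute) at 0.02 µm/px and +0.8 % at 0.05 µm/px
— concavity work should use 0.02 µm/px or finer, while lengths and widths
are accurate to ≲1 % even at 0.05 µm/px.

## Populations

Populations mirror the n spores / m basidiomes / p collections fungarium
hierarchy. Collection-level (L, W) means are bivariate normal with the
preset between-collection SDs; spores scatter around their collection mean
with SD = within_sd_factor × between-SD (default 1.5 — the published
summaries report only SDs of collection averages, so the within/between
split is a modelling choice, configurable); per-spore concavity is lognormal
(strictly positive, right-skewed). Non-positive or width-exceeding draws
are resampled rather than clipped, avoiding point masses at the bounds; the
resample count is recorded and a rate above 1 % warns.

Preset means and SDs are the published per-species collection-average spore
statistics (pulverulentus 12.29 ± 0.90 × 4.87 ± 0.32 µm; mediterraneensis
12.67 ± 0.74 × 5.33 ± 0.32 µm; poikilochromus 11.83 ± 0.69 × 5.03 ± 0.25
µm). The length–width correlation is not published; 0.5 was chosen once
because it reproduces the published Q dispersion (≈0.18 for pulverulentus)
from the marginal SDs, and stays fixed. Concavity medians (4 %, 1.5 %,
1.0 %) sit inside the key's stated regimes for the three species. The
source material lists fewer basidiomes than collections in its [703/14/17]
tally; the generator instead treats m as a per-collection count, and the
default hierarchy (10 basidiomes × 5 spores per collection) is sized for
simulation studies rather than verbatim realism.

What the generator does *not* emulate: optical blur, staining texture,
touching or overlapping spores, segmentation errors beyond additive salt
noise, within-basidiome correlation structure, or any asymmetry families
beyond the superellipse/notch construction. Passing parameter-recovery
tests therefore demonstrates the correctness of the measurement chain on
clean single-spore masks, not robustness to real imaging artefacts.

## Summaries and display

Summaries average spores within each collection first and take
min/mean/SD/max across collection means (sample SD, n − 1); pooled per-spore
summaries differ under unbalanced sampling, and a regression test pins the
collection-mean convention. Whether the published min/max are over
collection means or raw spores is not stated; the collection-mean reading
is implemented. Q and apV are computed per spore and then averaged. The
measured silhouette area is reported as-is (the published species mean area
exceeds the π·L·W/4 ellipse value, so no elliptical correction is applied).
Display rounding is decimal round-half-up at two decimals (1.555 → "1.56");
all internal arithmetic is full precision.

## Statistics

- compare_groups follows the normality-gated protocol: Shapiro–Wilk per
  group at α = 0.05, then Welch's t if both pass, else two-sided
  Mann–Whitney. Welch rather than Student is the default because it is the
  safer choice under unequal variances; Student is available. Sidedness is
  two-sided throughout. Stars: p < 0.05 (*), < 0.01 (**), < 0.001 (***),
  boundaries exclusive.
- Mann–Whitney with both groups ≤ 8 uses full enumeration of all C(n+m, n)
  group assignments of the pooled values, counting arrangements whose U
  deviates from nm/2 at least as much as observed. This handles ties
  (half-credit in U) and degenerate constant groups (p = 1) exactly;
  larger samples use the tie-corrected normal approximation.
- The isoprobability ellipse is the Mahalanobis contour of the sample mean
  and covariance at the χ²(2 df) quantile of the probability level. The
  level defaults to 0.95 but is always an explicit argument — the published
  figures do not state theirs.
- The 2-D KDE uses a Gaussian kernel with Scott's rule, on a grid covering
  the data ± 3 bandwidths so the trapezoidal integral is 1 within 1 %.
- No multiple-testing correction is applied by default, matching the
  published analysis; callers can correct externally.
- The unit of analysis defaults to collection means (each point one
  collection), with pooled per-spore mode available.

## Identification key

The microscopy key is encoded in a versioned YAML schema (thresholds:
width 5 µm; lengths 12.0/12.5 µm; depression 2.5/3 %) and traversed exactly
as printed, with strict inequalities. The key's own gaps — width exactly
5 µm, depression in [2.5, 3] %, and conflicting characters at couplet 4
(where the printed length conditions overlap between 12.0 and 12.5 µm, so
categorical characters are checked first) — return an indeterminate outcome
carrying the unresolved couplet's candidate set. Unknown characters never
resolve a couplet. On simulated preset populations the modal outcome per
species is that species, with cross-species labels below 5 % (the residual
comes from genuine overlap of the size distributions, mostly
mediterraneensis collections whose average width falls under 5 µm). The
macromorphological field key ships as data with a best-effort traverser,
marked experimental.

## Arsenic

Medians are order-statistic medians (mean of the central pair for even n).
The hyperaccumulation flag defaults to a 50 mg/kg dry-matter threshold —
the level the one known boletalean arsenic hyperaccumulator routinely
exceeds (its published median is 160 mg/kg) — applied as median ≥ threshold,
with the threshold always echoed in output. The packaged 13-sample table is
reproduced as printed; the QC helper checks a reference-material measurement
against its certified interval (oyster-tissue standard: 7.65 ± 0.65 mg/kg).

## Alignment site tally

Gaps and IUPAC ambiguity codes count as missing; constant = one distinct
resolved base; variable = ≥ 2; parsimony-informative = ≥ 2 bases each in
≥ 2 sequences; singleton = variable but not informative; all-missing columns
fall outside both counts. The headline percentage divides by the full
alignment length. Published per-locus tallies produced by other programs
can differ by one or two sites at columns mixing gaps and ambiguities;
those edge rules are not reverse-engineered here.

## Problem sizes

The default test suite runs the full simulate→rasterize→extract→measure
chain at 10 collections × 4 basidiomes × 5 spores and 0.05 µm/px (sizes at
which collection-mean recovery is testable within 3 Monte-Carlo SEM), and
the acceptance script at 17/15 collections × 10 × 5 and 0.02 µm/px. Shared
statistical checks use 10⁴ replicates (Welch type-I calibration) and 10⁵
points (ellipse coverage).
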