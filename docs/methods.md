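# Methods

## The quantification model

A multiplex smFISH field is a 4-channel image: probe channels 1, 2
and 4 carry diffraction-limited dots, one per hybridised mRNA
molecule, and channel 3 carries the DAPI nuclear counterstain. The
pipeline estimates, for every nucleus, the number of mRNA copies of
each probe in and around that cell, under three modelling
assumptions:

* a single molecule appears as an isolated intensity peak whose width
  is set by the point-spread function, so dots can be detected as
  local maxima of a band-passed image;
* the nucleus (not the full cell body) is the segmentable unit, and a
  cell's transcripts lie within a fixed radius of its nucleus;
* imaging parameters are constant within a batch, so one threshold
  set per channel is valid for every field of an assay.

### Dot detection

Each probe channel is filtered with a difference of Gaussians,
`blur(I, σ₁) − blur(I, σ₂)`, σ₁ = 0.5 px and σ₂ = 3 px, both with
reflective boundary handling. The small blur suppresses pixel noise
at the dot scale; the large blur estimates the local background, so
constant offsets map exactly to zero and the filtered intensity of a
dot is background-free. Dots are 8-connected local maxima with
filtered intensity strictly above the channel threshold. Maxima on
the 1-px image border are discarded (incomplete neighbourhood).
Candidates are pruned greedily in decreasing intensity order with a
minimum separation of 2 px: of two detections closer than that, the
brighter wins. Local maxima were preferred over connected components
because components merge adjacent molecules; the separation radius is
half the typical dot FWHM, below which two maxima cannot be distinct
molecules at this sampling. Sub-pixel localisation is out of scope —
integer maxima positions are sufficient for a 10-px assignment rule.

Thresholds (th1, th2, th4) are free parameters chosen by eye on a
sample field (`tune_preview` renders the overlay) and then frozen for
the batch; the run log records the full parameter set and its hash.

### Nuclei segmentation

The default backend ("quantise-watershed"):

1. Gaussian smoothing of the DAPI channel, σ = 7 px, to suppress
   intensity inhomogeneity within and between nuclei.
2. Multi-level Otsu quantisation of the smoothed image into four
   classes: background plus three nucleus-intensity tiers. Three
   tiers because nuclei sit at different depths along the optical
   axis and are systematically unequally bright; a single Otsu split
   loses the dimmest nuclei.
3. Watershed on the inverted smoothed image within the tier-union
   mask, seeded from regional maxima (8-connectivity) collected
   per tier, so a dim nucleus contributes its own seed even when its
   absolute intensity is below a bright neighbour's flank.
4. Halo removal: σ = 7 smoothing dilates every object by several
   pixels, so each watershed region is gated back to the pixels whose
   lightly-smoothed (σ = 1) DAPI intensity clears the same lowest
   Otsu threshold. This reuses the quantisation's own background
   threshold — no new tunable — and restores boundary accuracy to
   the un-smoothed image's scale. Each label then keeps its largest
   4-connected component.
5. Components with area < `min_area` (default 150 px², suited to 63×
   fields; the right value depends on magnification and must be set
   per assay) are removed and labels are renumbered from 1.

Labels use 4-connectivity; maxima detection uses 8-connectivity.
The watershed's "adapted to the levels" step is one defensible
design among several; tier-wise seeding was chosen because it
directly addresses the failure mode the tiers exist for (dim nuclei
swallowed by bright neighbours).

Alternative segmenters register by name
(`register_backend(name, fn)`) and are selected via
`SegmentationParams.backend`. A "star-convex" name is pre-registered
as an interface stub for deep-learning star-convex-polygon segmenters;
no trained model is bundled, and selecting it without registering an
implementation raises immediately. Manually corrected label maps can
be supplied per field through the manifest's `label_path` column,
which overrides the backend for that field.

### Dot-to-nucleus assignment

A dot belongs to a nucleus when the Euclidean distance from the dot's
pixel to the nearest pixel of the nucleus' mask is ≤ 10 px (0 inside
the mask). The distance is measured to the mask boundary, not the
centroid, because nuclei are extended objects of varying size; the
boundary reading makes the rule independent of nucleus area. The
10-px bound is read inclusively. A dot within reach of several nuclei
goes to the nearest; exact ties go to the lower label, making
assignment deterministic. Dots beyond 10 px of every nucleus are
reported as unassigned per channel, so per channel
assigned + unassigned = detected. The implementation searches only
the (2·10+1)² window around each dot, which is exactly equivalent to
the exhaustive all-pairs computation for any distance within the
rule; a property test checks that equivalence on random instances.

### Ensembles and aggregation

A cell is positive for a marker when its copy count reaches that
marker's threshold. The assay never fixes this cut-off; the default
is 1 copy, it is configurable per marker, and it is recorded in every
animal summary because ensemble percentages depend on it. The two
panel layouts map channels to markers as
TH-panel: ch1→TH, ch2→zif268, ch4→Arc and
GFAP-panel: ch1→GFAP, ch2→zif268, ch4→Arc; the order is a fixed,
logged convention. The 2³ positivity combinations partition the
cells, so ensemble percentages sum to 100 by construction. Fields of
one animal are summed before any statistic, and group means average
animal-level values: the animal, not the cell, is the experimental
unit.

## Statistics

* **Phenotyping** ranks animals by mean intake over the final three
  sessions; the top and bottom ⌊N/4⌋ are High and Low drinkers. The
  quartile size rounding is not derivable from published group sizes,
  so floor was chosen and exposed. Boundary ties break by the
  earlier-session mean, then animal ID, making the assignment
  deterministic and permutation-invariant.
* **Kruskal-Wallis** uses mid-ranks with tie correction and the
  chi-square approximation (df = k−1). When every observation is
  identical the tie-corrected statistic is 0/0; the package returns
  H = 0, p = 1 with a degenerate flag. Pairwise follow-ups are
  unadjusted 2-group tests by default, with optional BH over the
  contrast family.
* **Correlation matrices** compute Spearman r (mid-ranks, two-sided
  p) for every session × metric cell, then Benjamini-Hochberg
  step-up q-values over all defined cells of one matrix — the
  conservative reading of correcting "the p values obtained"
  together. Cells with a constant vector are undefined and excluded
  from the BH family rather than zero-filled.

## The synthetic generator

`generate_field` renders what the pipeline needs to see to be
testable, with exact ground truth:

* **Nuclei**: ellipses (semi-major axis 18–28 px — 63×-scale nuclei;
  eccentricity 0–0.6, random orientation) with three relative
  brightness tiers (0.4/0.7/1.0 of 200 intensity units) assigned
  round-robin so every tier is present. Brightness falls off
  radially to 50% at the rim: projected chromatin is brightest at the
  nucleus centre, and this dome is what gives each nucleus an
  intensity peak for the watershed to seed from — a flat disc would
  have none after smoothing. Edges are blurred (σ = 1.5 px).
* **Placement**: a configurable fraction of nuclei is placed in
  touching pairs (centre distance 92% of the sum of the boundary
  radii along the joining direction, ≤ 30% boundary overlap); all
  other nuclei keep ≥ 10 px boundary clearance so "non-touching"
  still holds after σ = 7 smoothing. Contested pixels go to the
  ellipse whose normalised distance is smaller. Impossible
  placements raise after bounded retries.
* **Dots**: per nucleus and channel, Poisson(λ = 5 by default) dots
  at distinct pixels inside the nucleus mask, ≥ 4 px apart within a
  channel, rendered as 2-D Gaussians (σ = 1 px, amplitude 100). A
  further 5% of each channel's dots is planted > 25 px from every
  nucleus — beyond the 10-px rule plus the largest halo a smoothed
  segmentation can add — so their unassigned label is unambiguous.
  Ownership is recorded at generation time and is valid under the
  pipeline's own rule because owned dots lie inside the owner's mask.
* **Noise**: i.i.d. Gaussian (sd 2 by default, amplitude/noise 50)
  added to all channels. All randomness derives from the spec's
  seed; identical spec gives bit-identical output.

`generate_behavior` simulates a 48-animal, 21-session drinking
cohort: constant 10 mL baseline, with a planted quarter of animals
escalating linearly at 1.5 mL/session from session 7 (escalating
drinkers in this paradigm separate from the rest after roughly the
first week), Gaussian noise (1 mL default), clipped at 0. The planted
escalator list is carried on the returned table as the phenotyping
oracle.

What the generator does **not** emulate: 3-D z-stacks and optical
sectioning, autofluorescence and structured background, chromatin
texture, dot intensity variation from partial hybridisation, nuclei
cut by the field border, and cell-density gradients. Passing tests
therefore demonstrate the pipeline's correctness relative to its own
model of the data (isolated Gaussian dots, dome-shaped nuclei,
additive noise), not detection performance on degraded real tissue —
on real data the thresholds and min_area must be re-tuned per batch,
which is exactly why they are exposed and frozen per run.

## Numerical choices and degenerate inputs

* Gaussian filtering uses sampled normalised kernels truncated at
  4σ, reflective boundaries (verified against dense convolution to
  1e-10 relative error).
* Detection tie-break: equal-intensity candidates are ordered by
  (row, column) before greedy suppression, so results are
  reproducible across runs.
* Multi-Otsu on an image with too few grey levels falls back to a
  midrange split; a blank DAPI channel yields an empty label map, not
  an error. Watershed pixels unreachable from any seed become their
  own components rather than holes.
* An animal with zero cells reports missing ensemble percentages with
  a logged warning; constant vectors make a correlation cell missing,
  and the BH family shrinks accordingly.
* Batch runs are deterministic: identical inputs and config produce
  byte-identical CSVs; the run log stores the config hash.

## Problem sizes used in the validation suite

The shipped validation uses 20 fields of 512×512 px with 20 nuclei
each for count recovery, 50 two-nucleus fields for touching-pair
separation, 100 random instances for the assignment oracle, 1000
random p-vectors for the BH closed form, and 10 cohorts of 48 animals
for the correlation-onset pattern — sizes at which every oracle is
exact and the whole suite completes in well under a minute per
component.

## Known limitations

* The intensity-seeded watershed still merges touching pairs whose
  brightness contrast is extreme at small sizes; the star-convex
  backend interface exists for exactly those fields.
* Assignment measures to the segmented mask, so segmentation halos
  or erosions move the effective 10-px boundary; the halo-gating
  step bounds this at roughly the light-smoothing scale (~1 px).
* Copy counts are per nucleus-plus-surround, not per cell body; dense
  neuropil dots between cells are attributed to the nearest nucleus
  within reach, with no nuclear/cytoplasmic distinction.
* BH q-values control the false-discovery rate per matrix; single
  cells should not be over-interpreted, and with ~20 truly coupled
  cells per matrix roughly one false discovery per matrix is expected
  at q < 0.05.
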