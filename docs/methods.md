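# Methods

`stromametry` quantifies the composition and 3D morphology of placental
villous stroma from category-labeled image stacks, and validates every
estimator end-to-end on synthetic villus phantoms with exactly known
ground truth. This note records the models, the defaults and why they
were chosen, and what the validation does and does not demonstrate.

## Design-based stereology

Volume fractions are estimated by systematic uniform random sampling
(SURS) with point counting. For a stack of *n* slices, a starting slice
is drawn uniformly from the first `start_window` slices (default 50) and
every `slice_period`-th slice after it is sampled (default 50); a
`grid_rows x grid_cols` point grid (default 4 x 4, 16 points) with a
fresh uniform random offset per sampled slice is overlaid, and each point
takes the category of the pixel under it (the pixel containing the
point's continuous coordinate, i.e. `floor` of each coordinate — a
deterministic rule chosen to avoid boundary ambiguity). The random start
makes every slice equally likely and the random offset makes every pixel
equally likely, so the point fraction is an unbiased estimator of the
volume fraction; its error is binomial, shrinking as 1/sqrt(points).

Two denominators are reported, following how villus composition is
tabulated: fractions of *villous tissue* (all categories except the
intervillous space) and fractions of the *stromal compartment* — exactly
the four stromal constituents (extracellular matrix, extracellular
vesicles, stellate cells, macrophages), which sum to 100%. Pericytes,
endothelium and capillary lumen are villous but extra-stromal. Absolute
tissue volume multiplies the villous point fraction of *all* points by
the volume of the region analysed.

Aggregation across placentas is mean-of-ratios: per-placenta fractions
are computed first, then averaged with SEM = sd/sqrt(n). This weighs
placentas equally regardless of how many points each contributed (the
two tabulated denominators are therefore not mutually consistent under a
single pooled division — a property of the aggregation, not an error).

Sampling adequacy: the running mean of per-slice fractions is computed,
and flagged adequate when the last 5 running means all lie within ±10%
(relative) of the final value — a quantitative stand-in for judging a
plotted running mean to have stabilised; the thresholds are package
choices.

## Morphometry

Each object is measured by its longest extent along the three block
axes. Extents convert voxel spans to physical units *per axis before
ordering*, which matters because stacks are anisotropic (pixels of a few
nm, slices of tens of nm). The largest extent is the **length**, the
mean of the two shorter is the **width**, and width/length is the
**ratio** (1 for a sphere, < 1 for ovoids). The extent convention is
`(max_index − min_index + 1) × spacing` — voxel centers plus one voxel
width; the alternative center-to-center convention differs by one voxel
and the choice is declared, not derivable from a manual protocol.
Axis-aligned extents are the definition here; rotated principal-axis
diameters are out of scope. Objects whose bounding box touches the
volume edge are flagged `boundary_clipped` and excluded from size
summaries by default (their extents are truncations).

A measurement-protocol property worth knowing: for a freely rotated
ovoid, every axis-aligned extent lies between the true width and true
length, so the measured ratio is biased toward 1 (≈0.84 measured for a
true 0.71 at uniform random orientation) and the measured length is
biased slightly low. The vesicle-field generator used for validating
parameter recovery therefore aligns each long axis with a randomly
chosen grid axis, where the protocol is exact up to voxelization; a
`uniform` orientation mode exists and a test documents the bias
direction.

Two selection modes mirror the two ways vesicles are found: *systematic*
(vesicles hit by at least one SURS grid point — size-biased by design,
since hit probability is proportional to volume) and *targeted*
(up to 2–3 per placenta inside a size window, default < 300 nm, the
typical stromal-vesicle size range in other tissues).

## Contacts and networks

A vesicle is in contact with a partner category when any vesicle voxel
is 26-adjacent (faces, edges, corners) to a voxel of that category from
a different instance — the permissive digital analogue of counting any
visible touching. Adjacency to the syncytiotrophoblast stands in for
contact with the trophoblast basal lamina, which has no separate label.
Contact percentages are reported to the nearest integer. "Any stromal
cell" means stellate cell or macrophage.

Stellate networks are connected components of the graph whose vertices
are stellate cells (one nucleus each) with edges for 26-adjacent cell
pairs; the summary is the mean number of nuclei per network ± SEM.

## Statistics

Size comparisons use the Mann–Whitney U test, exact by full enumeration
of all group labelings when the pooled sample has ≤ 12 untied values
(small-sample p-values verifiable against independent oracles), else a
normal approximation with tie and continuity corrections. The
ovoid-shape test is a one-sample Wilcoxon signed-rank of the ratios
against 1, exact for n ≤ 20 via the signed-rank distribution computed by
dynamic programming. Welch's t-test (unequal variances, Satterthwaite
df) is provided for mean ± SEM style summaries. Two-sided p-values are
twice the smaller tail, capped at 1; degenerate inputs (identical
constant groups, all ratios exactly 1) return p = 1 by convention. The
choice of a rank test for size comparisons (which are summarised as
median and range) and of the signed-rank test for the ratio-vs-1
question are package choices.

## The villus phantom

The phantom emulates an SBF-SEM stack of a terminal villus on a
192×192×192 grid at (50, 14, 14) nm spacing — deliberately anisotropic
to exercise unit conversion. This is a *scaled model*: the field of view
is ~2.7 μm across while a real terminal villus is tens of μm, so the
objects inside are proportionally miniaturized. What the phantom is for
is validating the estimators against exact ground truth, which is always
*measured from the emitted volume* (by exhaustive voxel counting and
object bookkeeping), never copied from the request — placement and
rasterization error are part of the truth.

Construction, in order:

1. **Villus boundary**: the cross-section is the region on one side of a
   gently curved arc (the field of view catches one side of a villus),
   sized by bisection to cover 62% of the image; the rest is
   intervillous space.
2. **Trophoblast bands**: villous pixels sorted by distance from the
   boundary; the outermost quota becomes syncytiotrophoblast, the next
   cytotrophoblast. Quota cuts on a distance ordering make these counts
   exact.
3. **Capillaries**: four centerlines along the slicing axis, clustered
   toward the far side of the pocket from the deepest stroma point (so
   the stroma stays one compact reserve rather than a web); pixels
   sorted by distance to the nearest centerline receive the lumen,
   endothelium and pericyte quotas in nested order. Exact counts again.
4. **Vesicles**: ovoids (prolate spheroids, one long axis, matching a
   width defined as the mean of the two shorter extents) with log-normal
   lengths and logit-normal width:length ratios, uniformly random
   orientation, placed by rejection sampling anywhere in the stroma
   (non-overlapping; a length cap of 6× the median keeps rare extreme
   draws placeable). The in-phantom median length (196 nm) is a
   scaled-model choice sized so the default 100 vesicles carry the
   vesicle share of the stromal compartment; after drawing, the whole
   cohort is rescaled by one common factor so its total volume lands on
   the vesicle quota exactly — composition is controlled while the
   scale-free shape distribution is preserved (per-phantom medians vary
   a few percent instead of the total volume varying ~12%). True-size
   vesicles are exercised by the separate vesicle field below.
5. **Macrophages**: ellipsoidal blobs packed until their quota is
   reached, kept out of every vesicle's 26-neighbourhood.
6. **Stellate cells**: modeled as thin horizontal *process sheets* (the
   sheet-like sails stellate processes form in the stroma), stacked
   along the slicing axis with a 3-slice period (2-slice sheet + 1-slice
   gap). A cell is an exact-pixel-area patch grown inside the free
   stroma cross-section of one level; a network is a run of patches on
   consecutive levels, overlapping in-plane so a one-voxel vertical
   process tube through the gap connects consecutive cells. Network
   sizes are drawn from a shifted Poisson (1 + Poisson(mean − 1),
   default mean 3.3 nuclei) and realized exactly. A 2-pixel carving
   margin around every patch plus the slice gaps guarantee that
   different networks are never 26-adjacent, so detected components
   equal generated networks exactly. Sheets tile the crowded villus
   cross-section efficiently, which is what makes a 21.6%-of-stroma
   stellate load reachable at this scale; earlier compact-cell designs
   (ellipsoidal bodies with free-direction tubes) jam well below that
   density because inter-network exclusion shells dominate.
7. **Contacts**: every vesicle is halo-protected during sheet carving;
   afterwards, vesicles are visited in random order and a one-voxel
   stellate process "nub" is grown from the nearest sheet along an
   in-plane geodesic (threading around other vesicles and around other
   networks' cells) to touch the vesicle, until exactly
   `round(contact_fraction × n_vesicles)` contacts exist. Contact
   designation is post hoc, which introduces no size bias because all
   vesicles are drawn i.i.d.; the remaining vesicles keep a clean
   26-neighbourhood, so the detected contact fraction equals the
   requested one exactly. The generator verifies this before returning.

Packing feasibility depends on shape: configurations the geometry cannot
realize (e.g. more contacts than reachable vesicles in a small, crowded
volume) raise an explicit error naming the category rather than
degrading the ground truth.

Determinism: a single generator seeded from the spec drives every draw;
the same spec yields a bit-identical volume.

## The vesicle field

True-size morphometry is validated on a dedicated vesicle field: each
vesicle is rendered in its own tight volume at (50, 25, 25) nm spacing
with log-normal lengths (median 2750 nm, log-sigma 0.70, calibrated from
the reported range 350–7730 nm spanning ≈4.4 sigma at n = 27) and
logit-normal ratios (median 0.71, logit-sigma 0.97, calibrated the same
way from 0.25–0.96). Long axes are grid-aligned by default (see the
orientation note above). Rasterization is slice-wise, so even the rare
multi-hundred-voxel objects keep a small memory footprint.

## Validation problem sizes

The composition cohort is 8 phantom placentas (192³ voxels each), each
point-counted with the full design and many pooled, independent sampling
passes. The reference validation in `scripts/acceptance.py` pools 600
passes per placenta: one pass over the desk-scale 192-slice phantom
yields only 64 points (a real 300–2000-slice stack yields several times
that), and the sparsest stromal category occupies only ~4% of the
stromal compartment, so a few-percent relative error on its fraction
needs thousands of stromal points per placenta. Pooling passes raises
intensity without touching the sampling design itself. The pytest suite
uses 10 passes per placenta and the two-SEM comparison, which is
self-calibrating at any intensity. The morphometry field uses 1000
vesicles, pinning the sampling error of the population median near 3%.
Network recovery pools the ~25–30 networks of each of the 8 phantoms.

## What passing tests show — and what they do not

The phantoms validate the *estimators*: unbiasedness of point counting,
correctness of extent measurement under anisotropy, exactness of contact
and component detection, and the small-sample statistics against
brute-force oracles. They do not emulate segmentation error, imaging
noise, section compression, or anatomical irregularity (real capillaries
meander, real stellate cells branch in all directions, real vesicle
populations need not be log-normal — the skewed-distribution form is a
modeling choice). Agreement on phantoms therefore demonstrates that the
quantification pipeline is correct, not that any particular biological
measurement is.

## Known limitations

- The stromal fractions of the scaled phantom are controlled to within a
  fraction of one object (sheets are carved to exact areas; vesicle and
  macrophage loads stop within half an object of quota), but the vesicle
  fraction inherits the sampling variance of 100 random sizes
  (coefficient of variation ≈ 12% per phantom).
- Stellate cells carry exactly one implied nucleus each; no separate
  nucleus label is emitted, so nuclei-per-network equals cells-per-
  component by construction.
- The exact Mann–Whitney mode requires no ties; tied data fall back to
  the corrected normal approximation whatever the sample size.
- `select_targeted_vesicles` needs true sizes (phantom ground truth) or
  a pre-measured candidate list; it does not segment anything itself.
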