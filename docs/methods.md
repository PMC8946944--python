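# Methods

## The measurement model

### Zonal colocalization (xenograft mode)

The unit of analysis is a single-plane, micron-calibrated multichannel
image of one tumor section (nuclear stain, pimonidazole, one or more
marker channels). The recipe:

1. **Tissue mask** — threshold the nuclear channel, fill interior holes
   (necrotic, DAPI-dark cores are still tumor area for zone purposes;
   switchable off), erode by `erosion_px` **pixels** (default 10). The
   erosion unit is pixels deliberately — it protects against sampling the
   section edge at acquisition resolution — while every other
   morphological length in the package is specified in microns and
   converted through the image's own calibration
   (`radius_px = max(1, round(length_um / pixel_size_um))`).
2. **RBC mask** — red blood cells autofluoresce across all filter sets, so
   they are segmented once in the nuclear channel with a cutoff that must
   exceed the tissue threshold, and excluded from every measurement.
3. **PIMO seed** — super-threshold pimonidazole within tissue, using a
   *fixed* intensity cutoff shared by all serial sections of one tumor
   (never re-fit per section), followed by the minimum-size filter and RBC
   subtraction.
4. **Zones** — the seed is expanded into annular bands by thresholding the
   Euclidean distance transform: ring *k* is the set of tissue pixels whose
   distance to the nearest seed pixel lies in ((k−1)·w, k·w], default
   w = 15 µm, two rings; background is tissue further than n·w (30 µm).
   Distance-transform dilation gives exact micron semantics for concave
   and merging seeds — two nearby pockets' rings merge by union, each
   pixel assigned by its nearest seed, with no double counting. Cumulative
   bands are measured from the *original* seed (>0–15, >15–30 µm), not by
   re-dilating the first ring.
5. **Statistics** — per zone, the mean of the *raw* marker channel, and
   the fold change versus the background-zone mean. Normalizing by distal
   background absorbs additive offsets, which is why no background
   subtraction is applied first. Empty zones yield missing values, never
   zero; an empty background flags all folds undefined.

Thresholds are value objects (`fixed` / `otsu` / `quantile`) recorded in
every mask's provenance, because in practice cutoffs are chosen
empirically per tumor and reproducibility requires writing the choice
down. Note that Otsu on a nuclear channel containing RBC speckles can
lock onto the speckle/tissue split rather than the tissue/slide split
(three-class histogram); per-tumor fixed thresholds are the recommended,
recorded practice, and are what the built-in study configurations use.

The `>30 µm` minimum-size filter is interpreted as the equivalent-circle
**diameter** of an 8-connected component ("size" as a linear extent, the
common microscopy reading); a component-area interpretation is selectable
(`size_measure="area"`). Components at exactly the floor are removed
(strict `>` keeps).

By default the RBC mask is excluded from *all* zones, not only the seed:
autofluorescent speckles would otherwise inflate ring and background
means. `exclude_rbc_everywhere=False` restores the narrowest literal
recipe (seed-only subtraction).

When several optical fields of one tumor are analyzed, both a
pixel-weighted pooled fold and an unweighted mean of per-field folds are
reported, since either aggregation is defensible and they differ when
fields contribute unequal zone areas.

### Percent-positive area (PDX mode)

Serial sections can be compared only by area, not pixelwise. Differences
from the xenograft recipe are exactly two: the tumor mask comes from
E-cadherin (with hole-filling — the membrane stain is a lace of rings —
and *no* edge erosion by default), and no dilation is applied to the
marker binary. The stain threshold is computed once on the anchor section
(the triple-stain image) and applied verbatim to the others, so
section-to-section staining intensity cannot re-tune the cutoff; the
minimum-size filter is retained. The score is
100 · |stain ∩ tumor| / |tumor| per section, plus anchor/single ratios
(missing when a single stain covers zero area). The anchored threshold is
a single intensity from the anchor image applied to all sections; a
per-channel alternative would be a trivial extension but is not the
default.

### DE summaries

Given per-contrast tables (gene, log2FC, Padj; raw p-values are BH-adjusted
on load), genes are inner-joined across contrasts (dropped genes are
reported in a sidecar — averaging over a varying number of contrasts would
mix scales). Outputs per gene: mean log2FC; mean −log10 Padj with Padj
floored at 1e−300; the all-contrasts heatmap selection (strict Padj < 0.05
and |log2FC| > 2 in every contrast, intersected with the hypoxia gene
set); and the pre-ranked metric — Padj rank (average ties) per contrast,
averaged, times sign(mean log2FC), with sign(0) = 0. Because the rank
direction feeding enrichment is a convention, both are emitted
(`signed_rank_metric`, ascending = rank 1 most significant, the default,
and `*_desc` reversed); neither is asserted as canonical. Row
mean-centering subtracts each gene's own mean across samples.

## The synthetic-data generator

The generator emulates the features the pipeline must be robust to:
a rectangular tissue footprint with smooth nuclear texture; 1–3
overlapping random ellipses per hypoxic pocket (irregular blobs);
a pimonidazole channel that is plateau-bright inside pockets
(`pimo_fold` × background, default 5) with a sharp exponential edge of
half-distance `gradient_halfwidth_um` (default 2 µm — adduct formation is
threshold-like in oxygen tension); marker channels following a radial fold
profile that is the seed fold inside pockets and interpolates linearly
through the ring-midpoint folds to 1.0 at the outer band edge; very bright
RBC disks (10 × background) burned into every channel; and additive
Gaussian noise clipped at zero.

Defaults are 512×512 px at 1 µm/px, three pockets of radius 30–60 µm,
background mean 100, noise SD 10 (10% of background), zone folds
{seed 3.0, ring1 2.0, ring2 1.5}, five RBCs of radius 6 µm. Pocket
centers keep the pocket plus a 30 µm halo clear of the tissue edge when
the frame permits, so annuli and background exist around every pocket;
pockets are clipped to tissue otherwise and the ground truth reflects the
clip.

Because the marker profile varies *within* each annulus, the area-weighted
mean of the profile over a ring is close to, but not exactly, the nominal
midpoint fold. The ground truth therefore records the **realized** mean of
the noiseless fold field over each ground-truth zone (RBC excluded); by
construction, recomputing any zone mean from the emitted noiseless image
over those masks reproduces the recorded value to machine precision, and
the seed and background folds equal their nominal values exactly. All
recovery statements in the tests are against these realized truths.

Serial sections share one pocket geometry, rigidly translated per section
by a seeded jitter of magnitude ≤ `jitter_um`/2 (so any two sections
differ by ≤ `jitter_um`). The stain content — noise field and RBC
placement — is intentionally shared across sections of one set, which
makes zero-jitter serial sections bit-identical; this is an oracle
contract, not a claim about physical sections. PDX-style panels
(`generate_pdx_sections`) render each stain as a hard-edged plateau over a
chosen subset of the pockets, with the anchor covering all of them, so the
recorded true percent areas are exact pixel counts and the anchor is the
union of the single-stain patterns by construction.

DE tables plant `n_hypoxia_genes` (default 40 of 5000) with log2FC ~
N(4, 0.5) and Beta(0.5, 200) adjusted p-values; nulls are N(0, 0.5) with
Uniform(0,1) adjusted p-values. Adjusted p's are generated directly —
the summaries consume Padj, so simulating counts would add machinery
without adding oracle power.

All generation is a pure function of (spec, seed), with separate child
streams for geometry, content, and jitter.

### What the generator does not emulate

No microscope PSF, no stitching artifacts or flat-field error, no z-stacks,
no staining chemistry, no spatial correlation between noise and structure,
no vascular geometry. Passing recovery tests therefore demonstrates that
the *computational* recipe is correct and stable under calibrated noise —
not that any particular biological conclusion transfers to real tissue,
where threshold choice and section quality dominate. Pocket size and
frequency defaults are free parameters of the simulation, not estimates of
real tumors.

## Numerical choices

* Mask convention is `pixels >= threshold`; a constant image under Otsu
  returns the constant (full mask) and the degenerate case is visible in
  provenance.
* Component connectivity is 8 (configurable), structuring elements are
  discrete disks, and dilation-by-distance uses `scipy`'s exact Euclidean
  transform; the test suite cross-checks band membership against an
  independent nearest-neighbor (k-d tree) query.
* Ranks use average tie-handling; BH adjustment is the standard step-up
  with monotonicity enforcement, checked against a hand implementation.
* Output tables are written with `%.10g` floats; reruns with identical
  config and seed are byte-identical (timestamps live only in provenance
  records, never in tables).
* Problem sizes in the test and acceptance runs (512² sections, 20-section
  recovery experiments, 5000-gene tables) were chosen as the smallest
  instances at which discretization error is comfortably below the
  tolerances being asserted.

## Known limitations

* Single-plane, pre-stitched TIFF input only; no vendor formats, no
  registration of serial sections.
* The pipeline quantifies descriptive fold changes and percent areas; it
  performs no inference across tumors.
* Enrichment analysis itself is out of scope: the package emits the
  pre-ranked `.rnk` input, in both rank conventions, and stops there.
* Otsu thresholding is provided for convenience but is not robust on
  three-class histograms (slide / tissue / speckle); fixed recorded
  thresholds are the intended workflow, mirroring empirical per-tumor
  threshold practice.
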