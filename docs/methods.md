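# Methods

This note documents the models and procedures implemented in `palateseq`,
the parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions.

## Synthetic sections

A section emulates a coronal slice through the embryonic secondary palate
at desk scale. Coordinates are Cartesian µm, x rightward, y downward (image
convention), origin at the frame's top-left corner, so raster masks and
point tables share one frame.

**Geometry.** Two palatal shelves (PL, PR) are modelled as rotated
rectangles centred at 1/4 and 3/4 of the frame width (frame default
1200 × 900 µm). Per shelf, the length along the axis is drawn uniformly
from 380–440 µm, the oronasal depth from 240–280 µm, and the orientation
uniformly over the half circle. These sizes put a shelf cross-section in
the few-hundred-µm range typical of E12.5–E13.5 murine sections while
leaving room for twelve 80 µm ROIs. The ground-truth oronasal axis is the
shelf's long mid-line; a 10 µm epithelial strip runs along one long edge
(the oral margin), and the half containing the strip is the oral (OP)
domain. Realistic tissue morphology (curved shelves, tongue, tooth buds) is
deliberately out of scope: rectangles and disks keep every geometric oracle
exact.

**Gene model.** Each gene has a base intensity (transcripts/µm²),
multipliers for the three regions (epithelial strip, oral mesenchyme, nasal
mesenchyme), a log2 fold change applied in condition "B" relative to "A",
and a mitochondrial flag. The default panel places *Shh* only in the strip
and *Ptch1* in the oral mesenchyme — the marker configuration that defines
the oronasal landmark — plus patterning and extracellular-matrix genes with
and without condition effects (*Col1a1* +2, *Eln* +1.5, *Tnn* +3, *Wnt5a*
−1.5, and *Fmod* +2.5 restricted to the oral domain so that scope-dependent
detection is testable), a null background, and two mt- genes. Base
intensities (0.004–0.3 /µm²) give roughly 40–60k transcripts per section,
comparable per-gene to a targeted in situ panel and cheap enough that the
full suite runs in seconds.

**Transcripts.** Counts per (gene, region) are Poisson with mean
`base · multiplier · 2^(lfc·[condition==B]) · area`; locations are uniform
within the region, i.e. an inhomogeneous Poisson process with piecewise
constant intensity. Quality scores are uniform in [20, 40); a configurable
5% of transcripts get qv in [5, 20) to exercise the quality filter
downstream. The ground truth records each transcript's OP/NP label (by the
truth axis) and each gene's true LFC.

**Bin grids and nuclei.** Nuclei are non-overlapping disks (default 150 per
section, radius 4–9 µm, ≥2 µm separation) placed by dart throwing inside
the shelves and rasterized at the bin pitch (2 µm) by the center-in-disk
rule; per-nucleus counts are Poisson with mean `intensity(region) · area`.
Nuclear transcripts are placed uniformly over the nucleus's *rasterized*
footprint rather than the continuous disk — a deliberate choice so that
bin-center aggregation recovers the per-nucleus truth exactly, which turns
the recovery test into an exact integer identity instead of a tolerance
check. An extra-nuclear fraction (default 0.3) of transcripts is placed in
the shelves outside any labelled pixel, exercising the unassigned-bin path;
the extra-nuclear process has total rate f/(1−f) times the nuclear rate per
gene, so the expected fraction of all transcripts outside nuclei is f.

Because the generator's regions are rectangles and disks with piecewise
constant intensity, passing tests demonstrate correctness of the
*computations* (geometry handling, counting, statistics), not robustness to
segmentation errors, optical artefacts, cell-density gradients or irregular
morphology — real-data properties the generator does not model.

## Nuclei-anchored binning

A bin is assigned to the nucleus whose label-mask region contains the bin's
**center** (nearest-pixel lookup after converting both frames to µm; masks
are never resampled). Center containment, rather than area-overlap
apportionment, keeps counts integral and the assignment unambiguous. Counts
are summed per nucleus; bins whose center falls on background stay
unassigned, giving the exact conservation law
`sum(cell matrix) + sum(unassigned bins) = sum(grid)`.

Nuclei are then filtered by area bounds and minimum UMI. No published
thresholds exist for this filter, so the defaults — 16 µm² minimum (≈ a
2-pixel artefact at 2 µm pitch), 800 µm² maximum (≈ a 16 µm-radius disk,
larger than any plausible single nucleus here), 10 UMI minimum — are
declared package defaults, exposed in config and stamped into the filter
report. Mitochondrial transcripts are removed by case-insensitive symbol
prefix (default `mt-`, the murine convention); an empty prefix is rejected
because it would match every gene.

## Oronasal partition

The co-expression field is the pointwise product of the two markers'
Gaussian KDEs evaluated exactly (chunked, separable kernels) on a regular
grid. Defaults: bandwidth 20 µm and grid step 5 µm — the bandwidth is a
few cell diameters, small against the ~250 µm shelf depth but large enough
to bridge the epithelial strip and adjacent mesenchyme into one ridge; both
are configurable.

The axis direction is the first principal axis (field-weighted PCA) of the
field's top-decile support inside the shelf, with a deterministic sign
convention. The line itself is then translated along its normal to bisect
the shelf's extent in that direction, and the returned anchor is the
field-weighted centroid projected onto the line. The translation step is a
considered design choice: the *Shh*/*Ptch1* co-expression locus necessarily
hugs the oral margin (that is where the epithelium is), so a line through
the co-expression centroid would graze the shelf edge rather than separate
its oral and nasal halves; the markers therefore orient the axis, and the
shelf's own extent positions it — mirroring how the axis is drawn through
mid-shelf in manual practice. For a marker cloud symmetric about the
mid-shelf the two rules coincide.

OP/NP assignment is by signed perpendicular distance to the axis line. The
oral side must be named by an explicit reference point; the pipeline uses
the *Shh* KDE mode (oral-epithelial by construction) so the decision never
consults simulator truth. Points exactly on the line are labelled OP.

## ROIs and densities

ROIs are standardized by area: 6400 µm² with a ±100 µm² tolerance (the
tolerance is taken in area units). The default shape is a square of side
80 µm, oriented along the fitted axis so that placement is independent of
the section's orientation in the frame; circles (r ≈ 45.1 µm, polygonized
to 64 segments, area 6390 µm² — within tolerance) are optional. Three ROIs
are placed per side of the axis per shelf: 2 shelves × 2 domains × 3 = 12
per section.

Because the original ROI selection was manual, placement here is a
declared, seeded algorithm: candidate centers on a jittered grid (step
20 µm, refined deterministically down to 2.5 µm if a narrow domain needs
it) are kept when the ROI polygon lies entirely inside the shelf with every
vertex on the correct side of the axis, ranked by contained transcript
count, and accepted greedily without overlap. Ties break by position, so a
fixed seed reproduces ROIs byte-for-byte.

Transcripts with qv below 20 are excluded before counting (a standard
imaging-platform quality cut; configurable). Counting is point-in-polygon
with the boundary inclusive; densities are exactly count/area in µm⁻².
The ROI CSV schema is
`roi_id,shelf,domain,area_um2,gene,count,density_per_um2` (+ optional
`group`), and one-file-per-ROI legacy exports can be assembled by passing a
list of paths to the reader.

## Differential expression

Per gene, with groups A and B as the first and second arguments of
`run_dge`:

- **LG₂FC** on raw mean densities: `log2((μ_a + ε)/(μ_b + ε))` with
  pseudocount ε = 1/6400 µm⁻² (one transcript per default ROI) applied
  symmetrically. Raw-density fold changes with near-zero denominators
  produce the extreme but finite LFCs (|LFC| ≈ 6–9) characteristic of
  domain-restricted genes; ε = 0 with a zero mean is an error instructing
  the caller to set a pseudocount.
- **Variance gate**: F = s²_max/s²_min (larger sample variance in the
  numerator), two-tailed p = min(1, 2·SF(F)); below α = 0.05 the gene takes
  Welch's t-test (Welch–Satterthwaite df), otherwise Student's pooled
  t-test. Both are two-tailed and computed on `log2(x + 1)`-transformed
  densities, the variance-reducing normalization. Genes with zero variance
  in both groups get p = 1, a `degenerate` flag, and are never classified
  up or down.
- **BH**: step-up adjustment `p_adj(i) = min_{j≥i} (m/j)·p_(j)` capped at
  1, across all genes tested in the contrast. (The adjustment is monotone
  along the sorted order but not idempotent — re-adjusting adjusted values
  can only raise them.)
- **Classification**: up if p < 0.05 and lfc > 1; down if p < 0.05 and
  lfc < −1 (the two-sided |LG₂FC| rule, matching how downregulated genes
  are reported). The classification p is BH-adjusted by default and
  switchable to raw; either way the choice is stamped into the output
  metadata, since published volcano plots often leave it implicit.
- **ORA**: one-sided hypergeometric upper tail per gene set, significant
  when p < 0.05 and the overlap exceeds one gene. Gene sets are plain-text,
  one per line (`name<TAB>gene1,gene2,…`); no database access.

The pipeline (`run_comparison`) pools ROIs across sections per group and
runs the contrast at three scopes — whole shelves, NP only, OP only —
reporting lfc oriented as log2(B/A) (test over baseline). Outputs are
deterministic functions of (config, seed); the manifest records config,
seed, version and per-stage counts, and a failed stage aborts the run with
the stage named and the manifest marked incomplete.

## Problem sizes and verification

The test suite and the acceptance script run entirely on synthetic data at
the default sizes above: sections of ~40–60k transcripts, 60–150 nuclei,
2000 null genes × 6 ROIs/group for type-I calibration, 25 genes for effect
recovery, and 1000 random cases per statistical oracle. Statistical
components are verified against independent implementations (textbook-
formula F/Student/Welch, a brute-force BH step-up, exact rational
hypergeometric tails, statsmodels' `fdr_bh`); geometric components against
counting oracles (bin centers in a disk ≈ πr²/pitch², brute-force
point-in-polygon); and end-to-end behaviour against the simulator's ground
truth (axis angle, domain labels, per-nucleus counts, true LFCs).

## Known limitations

- The OP/NP boundary is a straight line per shelf; curved boundaries are
  not representable.
- Nucleus segmentation itself is out of scope: the label mask is an input,
  and the area/UMI filter is the only defence against its errors.
- The density DGE treats ROIs as exchangeable replicates; section-level
  random effects are not modelled (n ROIs per group is small, and the
  original design pools ROIs the same way).
- Normalization/clustering of the cell-by-gene matrix (and model-based DEG
  calling on it) is downstream of this package's scope; the matrix is
  written in standard MTX + CSV form for those tools.
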