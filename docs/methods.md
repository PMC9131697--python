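# Methods

`issmap` implements the analysis stack used in targeted in situ sequencing
(ISS) studies of oligodendrocyte heterogeneity: probabilistic typing of
decoded transcripts against single-cell reference profiles, followed by
abundance, density, and neighborhood statistics over annotated tissue
regions. Because the real imaging data cannot be regenerated at a desk, the
package ships a synthetic-tissue generator whose defaults reproduce the
statistical regime of the published experiments; every downstream stage is
validated end-to-end against that generator's known ground truth.

## Cell typing model

Decoded spots (gene symbol + x/y in μm) are first assigned to segmented
cells by **nearest centroid within a hard radius** (default 15 μm; beyond it
a spot is background). This is a deliberate simplification of the full
pciSeq joint model, which infers spot-to-cell and cell-to-type assignments
simultaneously: the hard assignment is deterministic, exactly testable
against an all-pairs oracle, and sufficient for every downstream statistic
computed here. The joint model is out of scope by design.

Given per-cell gene counts `n_cg` with total `N_c`, the posterior over cell
types is

    P(k | n_c) ∝ π(k) · Π_g Poisson(n_cg ; N_c · q_gk)

where `q_gk` is the reference mean-expression profile of type `k`,
pseudocounted (ε = 10⁻³) and normalized to sum to one over the panel.
Scaling by `N_c` makes the total expected count equal the observed total for
every type, so the exposure cancels and the posterior is effectively a
multinomial likelihood over the panel — cells are typed by the *composition*
of their transcripts, not their yield. Computed in log space; a cell with no
assigned spots keeps the prior (uniform by default; the analysis states no
informative prior). Cell area is carried through the tables but does not
enter the likelihood, a documented divergence from pciSeq.

Cells are called winner-takes-all (argmax of the posterior; exact ties go to
the earlier panel type, deterministically), and only cells carrying at least
one transcript of the pan-lineage marker (*Plp1* for oligodendrocytes) are
retained. No posterior-probability filter is applied by default: real
studies report low-certainty cells rather than excluding them, and the
optional `min_probability` argument exists for sensitivity analyses.

Mean "pie charts" per called type are the arithmetic means of posterior
vectors over the cells called as that type (an alternative runner-up
co-occurrence reading is exposed via `co_occurrence=True`); the confusion
matrix averages the renormalized non-winning posterior mass, excluding
exact one-hot cells, which carry no confusion information.

## Synthetic tissue generator

The generator is first-class, tested code; its defaults encode the study
conditions rather than convenient values.

* **Panel.** `make_reference_profiles()` builds 13 types × 9 dedicated
  markers + 6 shared markers + 1 pan marker = 124 genes. Dedicated markers
  sit at 3.0 mean counts per cell against an off-target floor of 0.05
  (contrast 60), shared markers are elevated in 2–3 types (lineage-adjacent
  populations share genes), and the pan marker sits at 4× the marker level.
  The elevated pan expression reflects that the gating gene is chosen to be
  highly expressed across the whole lineage; with pan expression at the
  single-marker level, a quarter of simulated cells would carry zero pan
  transcripts and fall at the gate, which does not match tissue where
  essentially every segmented lineage cell is pan-positive.
* **Layouts.** `brain_coronal`: a cortical band (GM) of depth `scale` μm on
  a callosal band (WM) of depth 0.3·`scale`, with a straight
  pial-to-white-matter depth axis, layer boundaries at fractional depths
  0.10 / 0.35 / 0.50 / 0.75 (layers I, II/III, IV, V, VI), and a
  lateral-to-medial subdivision into S1, M1, M2, Cg1, Cg2.
  `spinal_cord`: a gray-matter ellipse inside a white-matter ring.
* **Cells.** A homogeneous spatial Poisson process per region. Age presets
  use the published densities (cells/mm²): CTX/CC = 207.2/648.4 at P10,
  193.5/750.4 at P20, 170.1/608.6 at P60. Spinal-cord presets use GM 350 /
  WM 650, a package choice consistent with the brain white-matter density
  (the source reports only spinal tissue areas, not densities). Types are
  drawn from region-dependent abundance mixes that qualitatively follow the
  published age profiles (precursor-rich at P10/P20; MOL5/6-dominated at
  P60; MOL2/3 enriched in cord WM). Cell areas are log-normal (median
  80 μm², σ = 0.5) and are schema completeness only.
* **Transcripts.** Per (cell, gene) counts are Poisson with mean
  `s · q_g,type`, where `s` is the target transcripts-per-cell — 13.4 (P10),
  14.6 (P20), 17.4 (P60), matching the published per-age means. A
  negative-binomial option (`dispersion`) exists for robustness tests. Each
  transcript becomes a spot at the centroid plus isotropic Gaussian noise
  (σ = 4 μm, so >99% of spots fall within 16 μm ≈ the assignment radius).
* **Background.** Uniform positions and uniform gene identities, by default
  5% of the realized true spot count (the source does not quantify ISS
  noise; 5% is a repository choice that exercises the radius cut and
  misassignment paths).
* **Determinism.** One `numpy` seed drives everything; identical inputs and
  seed give bit-identical tables. `shuffle_labels` permutes type labels
  over fixed positions and is the null configuration of the neighborhood
  test.

What the generator does *not* emulate: segmentation errors (cells are
points, not masks), optical crowding, barcode misreads/crosstalk, curved
cortical geometry, and 3-D structure (sections are 2-D, as in 10-μm
cryosections). Passing tests therefore demonstrate correctness of the
*computations* under the stated statistical regime, not robustness to
imaging artifacts.

## Abundance statistics

Counts per (region, type) use point-in-polygon on centroids; a centroid on a
shared boundary belongs to the region listed first (deterministic), and
cells outside all regions are kept in an `unassigned` bucket. Densities
divide by polygon area (mm²) of the annotation, not a hull of the cells.
Relative abundances divide each type's count by the region's pan-positive
total (%, summing to 100).

The rate of change between two conditions is
`ratio = 100 − 100/(X/Y)` with `X ≥ Y > 0` oriented so `X` is the larger
condition: 30 vs 10 gives 66.66%, i.e. the increase of 20 is two thirds of
the larger value. A type absent from the smaller condition has an undefined
ratio (flagged NaN), never 100%.

Group comparisons are one-way ANOVA across conditions with Tukey-HSD
pairwise contrasts (scipy), starred at 0.05/0.01/0.001/0.0001. No
across-type family correction is applied by default, mirroring how such
results are conventionally reported; Benjamini–Hochberg across types is
available (`bh_across=True`). Groups with fewer than two samples are
flagged not-testable; zero-variance input is flagged degenerate with p = 1.

## Density maps and depth profiles

2-D maps are fixed-bandwidth Gaussian KDEs (default bandwidth 100 μm, grid
spacing 20 μm — the source states neither; both are recorded in outputs) in
units of cells/μm², masked to the region polygon. A uniform boundary
correction divides each node by the kernel mass falling inside the polygon
(computed by Gaussian-blurring the polygon mask); without it a homogeneous
population looks artifactually dim along region borders, which would
distort the normalized maps. A section is normalized by the single maximum
over all types and nodes (global max exactly 1); for the spinal cord the
same normalization is applied per compartment so GM and WM panels are each
self-normalized, matching the split display convention.

Depth profiles project centroids onto the straight pial-to-white-matter
axis (0 = pial surface, 1 = white matter; projections outside [0,1] are
clipped and counted, warning above 5%) — a documented simplification
relative to atlas-registered curved streamlines. Occurrence along depth is
a 1-D Gaussian kernel sum (bandwidth 0.05 of cortical depth) whose integral
equals the cell count; per-layer occupancy integrates between the
fractional layer boundaries. Across-section averaging reports mean ± SEM,
either raw or with per-section unit-integral normalization
(`normalize=True`), since the source does not state which was used.
Per-area occurrences normalize each cortical area by its own pan-positive
total so areas of different size are comparable, and feed the same
ANOVA/Tukey machinery.

## Neighborhood analysis

Cells are nodes of the Delaunay triangulation (dual of the Voronoi
tessellation, whose cells can be computed clipped to the section polygon
for display); since the Delaunay graph provably contains every node's true
nearest neighbor, per-node nearest neighbors and Euclidean distances are
read off the graph. Degenerate inputs (< 3 points, collinear) fall back to
a brute-force nearest-neighbor scan with the triangulation flagged
unavailable. Edges are not pruned by length by default (no pruning is
described at the source); a maximum-edge-length option exists for
sparse-region artifacts.

Nearest-neighbor composition row-normalizes the counts of (type a → NN of
type b) to percentages; mean distances are reported to each type's most
prevalent neighbor type (ties to the earlier panel type, flagged).

Enrichment is a permutation test on fixed positions: the null permutes
labels over nodes (preserving the label multiset and the graph exactly),
the statistic is the ordered nearest-neighbor pair count (default,
matching nearest-neighbor-preference heatmaps) or the symmetric Delaunay
edge count, z = (obs − null mean)/null sd, and the empirical p uses the
add-one correction `p = (1 + #{null ≥ obs})/(1 + N)` so p is never zero.
Default 1000 permutations, seeded (the source does not state its count);
one-sided enrichment by default with a two-sided option, and per-pair
p-values without multiple-testing correction by default (BH available), in
both cases mirroring the reporting convention.

## Orchestration and reproducibility

The `issmap` CLI wraps the library: `simulate`, `type`, `abundance`,
`density`, `neighbors`, `run-all`, `validate`. `run-all` derives per-stage
seeds from one global seed via `numpy.random.SeedSequence`, writes all
outputs as CSV/GeoJSON/PNG, and records a `manifest.json` (config echo,
package version, per-stage status, timings, row counts); the pipeline is a
pure function of (inputs, config, seed). `validate` returns a
machine-readable issue list for the input files.

## Problem sizes and test design

The validation suite simulates sections at reduced spatial scale (layout
scales of 400–1000 μm, hundreds to a few thousand cells per section),
chosen so the suite exercises every code path at realistic densities while
remaining quick to run. Calibration checks use 200 label-randomized
tissues of 500 cells (499 permutations each); planted-effect recovery uses
20 replicates of 4 sections. Oracle tests compare the closed-form
posterior against literal Poisson enumeration (10⁻¹² relative) and
graph-derived nearest neighbors against O(n²) scans up to n = 1000.

## Known limitations

* Hard spot assignment ignores assignment uncertainty near cell borders;
  crowded tissue would blur counts between adjacent cells.
* Straight-axis depth is only valid for approximately radial cortical
  geometry.
* The homogeneous Poisson placement has no cell-body exclusion, so
  simulated nearest-neighbor distances are slightly shorter at equal
  density than in tissue with finite cell sizes.
* Neighborhood analysis is centered on cell bodies; cells with extensive
  processes may interact well beyond their nearest-neighbor distance.
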