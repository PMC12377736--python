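# Methods

This note documents the models, operational definitions and numerical choices
behind `els_mapper`, what the synthetic benchmark does and does not emulate,
and the known limitations.

## Scope and data model

The package analyses 2D multichannel wholemount images (channels: B = CD45R,
T = CD3, Ki67, optional nuclei) with a known pixel size, or tables of
already-phenotyped cell coordinates. All geometry is in micrometres with the
origin at the image top-left, x rightward, y downward (position = 0-based
pixel index × pixel size). Per-sample outputs are ELS records (one row per
structure); per-cohort outputs are mouse summaries keyed by genotype, sex and
age group.

## Detection

Cells are detected per channel with scale-normalised Laplacian-of-Gaussian
blob detection (`skimage.feature.blob_log`) over a physical spot-scale window
of 2.5–5.0 µm (the rendered puncta have σ = cell_radius/2 = 2.5 µm at the
default cell radius of 5 µm), followed by intensity-weighted sub-pixel
centroid refinement in a ±σ window. The response threshold default of 0.3
sits between the ≈0.5 response of a unit-amplitude punctum and the response
tail of background noise at std 0.2 (a full 2048² noise-only canvas yields
fewer than ~10 false blobs, which the `min_cells` filter removes downstream).
Two puncta closer than about one spot σ merge into a single detection; this
is documented, not corrected.

Phenotype fusion: a detection present in both lineage channels within
`bt_radius` (pipeline default 2.5 µm) is one physical cell and keeps the
channel with the higher peak intensity — no biological B/T double-positives
are expected, and a radius tighter than the Ki67 colocalization radius
(5 µm) avoids fusing genuinely adjacent B and T cells in intermingled
aggregates. Ki67 detections are matched greedily by distance (ties by index)
to at most one unmatched lineage cell within the colocalization radius.

## Aggregation

Aggregates are the transitive closures of the "within eps" relation
(single-linkage at eps), not DBSCAN: the core-point notion would make
membership depend on a second density parameter the classification does not
need. Clusters below `min_cells = 10` cells are discarded so scattered single
cells never count as an ELS. The default `eps = 50 µm` exceeds the
nearest-neighbour gap tail of the sparsest realistic structure layout (see
benchmark conditions below) while staying well below half of the minimum
structure separation; both parameters are config-exposed and should be
re-tuned for tissues with different cell densities.

The boundary is an alpha shape built from the Delaunay triangulation
(triangles kept when circumradius ≤ α, α = 2 × median nearest-neighbour
distance), falling back to the convex hull when the alpha shape is empty or
disconnected. Elongated follicles are thus not over-measured the way a convex
hull would. Fewer than three cells, or a collinear cluster, is a degenerate
geometry error.

## Typing

"Compartmentalized" and "surrounded" are operationalized as follows; the
three phenotypes are verbal definitions in the source literature, and the
thresholds here are this package's explicit, config-exposed choices.

* **Mixing score.** For each cell, the fraction of its k = 5 nearest
  neighbours (Euclidean, distance ties broken by index) with the opposite
  lineage, averaged over cells. The segregation p-value is
  `(1 + #{permutation score ≤ observed}) / (n_perm + 1)` under n_perm = 999
  random relabellings with lineage counts fixed. The add-one form makes the
  p-value super-uniform under the null, which the calibration benchmark
  verifies empirically.
* **Surroundedness.** Radii measured from the aggregate centroid. Requires
  (a) median B radius < median T radius with one-sided Mann–Whitney p < 0.05,
  and (b) T cells in the outer radial half (r ≥ median radius over all
  cells) occupying ≥ 270° of twelve 30° sectors. The outer-half split uses
  the overall median radius — robust to unequal lineage counts.
* **Cascade.** Type 3 iff mixed ∧ segregation p < α ∧ surrounded ∧ Ki67⁺
  fraction ≥ p_prolif; else type 2 iff mixed ∧ segregation p < α; else type
  1. Defaults α = 0.05, p_prolif = 0.05, and "mixed" requires ≥ 5 cells of
  each lineage (`min_minority`), so a stray cell cannot flip compartment
  status. Raising p_prolif can only demote type 3 to type 2 — the cascade is
  monotone in that threshold. The Ki67⁺ fraction is computed over all cells
  of the aggregate. A "lacking a defined shape" criterion sometimes used to
  describe intermediate phenotypes has no operational definition and is
  deliberately not part of the rule set.

The per-mouse "score" is reported as the tuple (counts by type, total count,
total area, ordered size list) rather than a scalar — collapsing quantity and
complexity into one number would impose an arbitrary weighting.

## Spatial mapping

Samples are pooled by mapping four named sinus landmarks (rostral tip,
confluence, left/right transverse ends) onto a template in a unit frame with
a 6-dof least-squares affine fit; collinear landmark sets are rejected. Exact
correspondences are recovered to machine precision (the registration
benchmark checks < 1e-6). Deformable registration is out of scope.

Density maps use a pointy-top hexagonal tessellation anchored at the frame
origin, `hex_diameter` = 0.05 of the template width by default (the source
figures do not state a hex size). Assignment is by nearest hex centre via
cube rounding with a deterministic (distance, centre-x, centre-y) tie-break,
so raw counts are conserved by construction. Displayed gray levels clip at 50
counts per hex; circles are drawn with radius ∝ √area so that circle *area*
tracks structure area, coloured blue/orange/red for types 1/2/3. Maps pool
all mice of a genotype × sex × age group by default (per-mouse maps are a
flag away); whether published maps show sums or means per mouse is not
stated, and sums are used here.

## Statistics

* **Spearman**: average ranks for ties; exact two-sided p by full
  enumeration of the n! rank pairings for n ≤ 9, t approximation otherwise.
  Constant input raises rather than returning NaN.
* **Kruskal–Wallis**: tie-corrected H with χ² p (df = groups − 1) via
  `scipy.stats.kruskal`; an all-tied input is defined as H = 0, p = 1 (the
  tie-correction denominator vanishes; there is no evidence against the
  null).
* **Post hoc**: Dunn z-tests on the pooled ranks (tie-corrected variance),
  adjusted with stepwise Holm–Šidák (`statsmodels.multipletests`). Dunn is
  preferred over pairwise Mann–Whitney because it reuses the omnibus rank
  pool.
* **Bell fit**: the bell-shaped female age trend is fit with the minimal
  bell-capable model, a quadratic in age (a Gaussian bump is available via
  config); R² = 1 − SS_res/SS_tot with the SS_tot = 0 case defined as 0; the
  peak −b/(2c) is reported only when the fit is concave. Age groups are coded
  1, 12 and 18 months (the ">18 mo" group needs a fixed numeric code for
  regression; config-exposed).
* **Pfaffl**: ratio = E_t^ΔCt_t / E_r^ΔCt_r with efficiencies in fold per
  cycle (must exceed 1). The ratio is exactly multiplicative in ΔCt, which
  the tests assert.

## Synthetic benchmark: what it emulates and what it does not

Scenes are 2048 × 2048 px at 2 µm/px (a wholemount field at desk-scale
memory), with additive Gaussian background noise of std 0.2 against
unit-amplitude cell puncta (SNR 5). Structure layouts follow the minimal
geometries satisfying the verbal type definitions: type 1 is a single-lineage
disc or an interleaved two-lineage disc; type 2 is two tangent discs of
radius r/2, one per lineage, with no proliferation; type 3 is a B core
(disc, 0.5 r) inside a T shell (annulus, 0.6 r – r) with a Ki67⁺ fraction of
the B cells. Cell counts are drawn per structure to be unambiguous under the
default thresholds (each lineage clears `min_minority`; the type-3 overall
Ki67⁺ fraction clears p_prolif with margin; the T shell is dense enough that
its outer half occupies ≥ 9 of 12 sectors except with negligible
probability).

Two generator choices deserve emphasis:

* **Interleaved "mixed" type 1.** Noncompartmentalized two-lineage structures
  plant B and T cells in pairs around shared anchor points rather than as
  i.i.d. uniform labels. With exchangeable labels, any α-level permutation
  test rejects at rate α by construction, so an i.i.d.-labelled "mixed"
  structure is statistically indistinguishable from a chance-segregated one;
  the interleaved layout models the biologically intended phenotype —
  lineages locally intermingled — and makes it identifiable.
* **Resolvable density.** Structure radii (50–110 µm depending on layout) are
  drawn so the planted nearest-neighbour spacing stays above roughly two spot
  σ. Denser aggregates are common in real tissue and would need a smaller
  imaging PSF or a density-aware detector; the benchmark deliberately stays
  in the regime where point detection is well-posed, so passing it shows the
  pipeline logic is correct, not that the detector resolves arbitrarily
  crowded follicles.

Benchmark scenes place ~8–12 structures on the sinus ribbon with ≥ 250 µm
separation and a type mix of roughly 40/35/25. The generator does not
simulate vascular or lymphatic channels, nuclei-based segmentation, plaque
channels, uneven illumination, or 3D structure.

Cohort tables draw per-mouse counts from a negative binomial parameterized as
variance = mean + dispersion · mean² (dispersion 0 is special-cased to the
deterministic round(mean) model; the lognormal-rounded alternative uses
σ² = ln(1 + dispersion) and is continuous in it). Per-structure areas are
lognormal around the group mean (CV 0.8); types follow the group's mixture.
The wild-type designs encode a monotone male trend (means 6 → 10.75 → 21.63
across ages 1/12/>18 mo, n = 8 per group) and a bell-shaped female trend
(7 → 30.22 → 14.25, n = 8/9/8) with dispersion 0.15; published spreads are of
unspecified kind (SEM vs SD), so dispersion is always an explicit input and
never inferred from them.

## Numerical choices and degenerate inputs

Seeds fix all randomness: scene generation is bit-identical per (spec, seed),
the rendering noise stream is derived from the scene seed, and pipeline
permutation seeds derive from (config seed, sample id, aggregate id) via
SHA-256, so re-running a pipeline yields byte-identical CSVs. Distance ties
in k-NN and in greedy matching break by index; hex-boundary ties break to the
lexicographically smaller centre. Single-lineage aggregates raise a
"not applicable" signal from the mixing and surroundedness statistics and are
classified type 1 by the cascade. Degenerate geometry (zero-width ribbon,
coincident or collinear landmarks, < 3 or collinear cells) raises a dedicated
error rather than returning garbage.

## Known limitations

* Intensity-region (area-based) analysis is not implemented; the pipeline is
  committed to cell-point analysis throughout.
* The detector undercounts in aggregates whose true nearest-neighbour
  spacing falls below ~2 spot σ; counts of *structures* are robust to this,
  per-structure cell counts are not.
* Landmark registration is affine only; strongly distorted wholemounts would
  need thin-plate or diffeomorphic registration.
* The permutation segregation test has α-level false positives by design, so
  a noncompartmentalized two-lineage aggregate has a ~5% chance of a type-2
  call on any single sample; cohort-level conclusions should rely on the
  summary statistics, not single-structure calls.
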