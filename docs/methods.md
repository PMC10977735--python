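# Methods

This document describes what `mitomorph` computes, the model behind each
stage, every parameter with its default and rationale, what the synthetic
generator does and does not emulate, and the package's numerical choices
and limitations. All statements about performance or accuracy refer to
quantities computed by this package's own test suite and
`scripts/acceptance.py`; no external empirical claims are made.

## 1. Scientific problem and measurement model

Mitochondria form a dynamic network whose morphology — fragmented grains
versus fused tubular webs, swollen versus thin tubules, perinuclear
versus peripheral placement — reflects cellular state. `mitomorph`
quantifies this morphology per single cell from one 2D, three-channel
fluorescence field:

* a **nuclei** channel (DNA stain),
* a **cell** channel (plasma-membrane / cytoplasm stain),
* a **mito** channel (mitochondrial stain).

The measurement model treats the thresholded mitochondrial signal of one
cell as a *landscape* and summarizes it with 31 descriptors spanning cell
geometry, mitochondrial cluster geometry and topology, skeleton
connectivity, per-organelle shape, and subcellular localization. The
analysis unit is the cell; fields are batch-processed into one CSV row
per cell.

### Conventions

Arrays are row-major with origin at the top-left and 0-based indices.
All geometry is in pixels. `pixel_size_um` (default 0.108333 µm, a
typical 60× camera pixel) is carried on images for unit conversion in
reporting; no feature is rescaled internally.

## 2. Segmentation

Segmentation is a fixed, fully deterministic cascade; no random numbers
are used anywhere in the measurement path.

### 2.1 Nuclei

1. **Band-pass**: difference of Gaussians, `nuclei_sigma_lo = 3`,
   `nuclei_sigma_hi = 12` px. The narrow blur suppresses shot noise, the
   wide blur removes slowly varying background, so the filtered image is
   centered near zero and a median threshold is meaningful. Scales are
   matched to nucleus-sized blobs (tens of pixels).
2. **Threshold** strictly above the median of the filtered image.
3. **Minimum area** `nuclei_min_area_px = 2000`: debris and stray
   maxima are far below a real nucleus footprint at the default pixel
   size (a 15 µm nucleus covers ≳ 10⁴ px).
4. **Fill holes**, then **dilate** by a disk of
   `nuclei_dilate_radius_px = 3` to recover the dim nuclear rim lost by
   thresholding.
5. **Watershed split** of touching nuclei on the smoothed Euclidean
   distance transform, seeded at its h-maxima (h = 2 px). h-maxima
   suppression is used because raw regional maxima on the near-flat EDT
   ridge of a single elongated nucleus produce several shallow seeds and
   over-split it; a 2 px depth is far below the EDT dip between two
   genuinely distinct nuclei.
6. **Border clearing**: partially imaged nuclei (and hence their cells)
   are removed.

**Integer quantization.** When the nuclei channel contains integer
counts (any camera image), the band-passed response is rounded to whole
counts before the median threshold. Sub-count float residue from the
Gaussian filtering is symmetric around zero, so a strict `> median`
float threshold marks almost exactly half of all background pixels — the
critical occupancy for 2D site percolation — and the background becomes
one giant spanning component that defeats the area filter. Rounding
restores integer-image behaviour: flat background maps to exactly 0 and
occupancy falls well below the percolation threshold. The rounding is
skipped for genuinely non-integer input.

### 2.2 Cells

Cells are grown from their nuclei with a seeded watershed on the negated
cell channel:

1. The relief is `-cell_channel`; nucleus interiors are forced to the
   global minimum minus one quantization step (the smallest difference
   between distinct relief values), so each nucleus is the unique
   deepest plateau of its catchment.
2. Unseeded watershed labels every catchment; catchments overlapping a
   nucleus inherit its label.
3. Residual catchments (local background basins) are merged iteratively:
   in each pass, every residual region touching at least one labeled
   cell joins the neighbour with the *lowest mean boundary intensity*
   (the dimmest shared border is the least likely to be a real membrane;
   ties go to the lower cell label). Passes repeat to a fixed point.
   All regions of a pass are assigned simultaneously from the pre-pass
   adjacency statistics, which is deterministic and order-free.
4. **Intensity floor**: pixels dimmer than `cell_intensity_floor` are
   returned to background. The floor has no published default and is
   data-dependent; when left `None` it falls back to Otsu's threshold of
   the cell channel (or no floor for a constant channel). Nucleus
   interiors are exempt — a cell always retains its seeding nucleus, so
   a floor above the image maximum shrinks cells to their nuclear cores
   rather than deleting them.

### 2.3 Mitochondrial clusters

1. Band-pass with `mito_sigma_lo = 1`, `mito_sigma_hi = 4` px — matched
   to tubule cross-sections of a few pixels.
2. Threshold at `mean + mito_threshold_k_sd · SD` (k = 1) of the
   filtered image.
3. Minimum area `mito_min_area_px = 10`: single hot pixels and their
   PSF halos are removed; a real mitochondrion at 0.108 µm/px covers
   tens of pixels.
4. Intersection with the cell foreground; components straddling a cell
   boundary are split per cell. Every cluster therefore lies in exactly
   one cell (`cluster_to_cell` map).

A *cluster* is a connected component of this mask — possibly several
fused or touching mitochondria.

### 2.4 Connectivity conventions

Component labeling and border tests use 8-connectivity
(`label_connectivity = 2`); watershed flooding uses 4-connectivity
(`watershed_connectivity = 1`), the usual choice that keeps ridge lines
thin.

## 3. Skeleton analysis

Each cluster is thinned to a 1-px topological skeleton
(`skimage.morphology.skeletonize`). Skeleton pixels are classified by
their 8-neighbour count: ≤ 1 neighbour → **end point** (an isolated
single-pixel skeleton counts as one end point), ≥ 3 → **junction
point**. Because thinning produces small clumps of junction pixels at
real branchings, 8-adjacent junction pixels are merged into one
**junction node** for counting.

Removing junction pixels decomposes the skeleton into **branches**.
Branch length is geodesic: axial steps count 1, diagonal steps √2,
summed over the branch's minimum spanning tree (for a 1-px path the MST
is the path itself; the MST makes the measure well defined for the rare
thick-crossing residues thinning can leave).

### Isolated mitochondria

Clusters may contain several organelles. The pixels of each cluster are
re-partitioned among its skeleton branches by a watershed on the
distance-to-skeleton relief seeded at the branch labels and confined to
the cluster support. Pixel support is conserved *exactly*: every cluster
pixel belongs to exactly one isolated mitochondrion (clusters whose
skeleton is a pure junction clump are kept whole under a fresh label).
These catchments are the package's proxy for individual organelles.

## 4. The 31 descriptors

Per-object definitions (objects = cell, cluster, or isolated
mitochondrion):

| Descriptor | Definition |
|---|---|
| Area | pixel count |
| Perimeter | `skimage` contour-walk perimeter |
| Compaction | minor/major axis of the moment-equivalent ellipse (∈ (0,1]) |
| Elongation | major/minor axis (≥ 1) |
| Roundness | equivalent diameter / (perimeter/π); 1 for a circle |
| Euler number | components − holes (1 solid blob, 0 annulus) |
| Solidity | convex-hull perimeter / object perimeter (note: perimeter-based, not the conventional area ratio) |
| Fractal2/8/32 | box-counting fractal dimension at box sizes 4, 16, 64 px (see §5) |
| Skel_Width | total cluster area / total skeleton length (mean tubule width proxy) |
| Skel_Length | summed branch lengths |
| Skel_Branch/EndPointsCount | junction-node and end-point counts |
| Skel_BranchPointsEndPointsRatio | B/(B+E), 0 when B+E=0 |
| Mito_Length | geodesic length of the organelle's skeleton branch |
| DistToMembrane / DistToNuclei | mean Euclidean distance of the cell's skeleton pixels to the nearest non-cell pixel / nearest nucleus pixel |
| RatioDistMemb0Nucl1 | per-pixel dn/(dm+dn), averaged (0 = hugging the nucleus, 1 = at the membrane) |

Ellipse axes are floored at 1 px so 1-px-wide lines stay finite;
single-pixel regions take the defined limits (all shape ratios 1).

**Aggregation to the cell**: areas and lengths (`MitoCluster_Area`,
`Skel_Length`, `Mito_Length`) are **summed** over the cell's objects;
every other per-object descriptor is **averaged**; counts are object
counts. `MitoCluster_Perimeter` is a mean (it is a shape summary, not a
mass-like quantity). `Mito_MeanIntensity` is the intensity sum over all
cluster pixels divided by total cluster area; `Mito_MaxIntensity` is
the mean of per-cluster maxima. A cell with no detected mitochondria
carries NaN (never 0) in the mitochondrial descriptors.

## 5. Box-counting fractal dimension

The cell's cluster-union mask (cropped to the cell's bounding box) is
zero-padded to the smallest enclosing 2^P square (e.g. 320×200 → 512²).
For every dyadic box size r = 1, 2, …, 2^P the number N(r) of occupied
boxes is counted by recursive 2×2 reduction. The per-scale dimension is
−d log N / d log r via central differences (`np.gradient`), and
Fractal2/8/32 read the profile at r = 4, 16, 64.

Exact limits (verified by the test suite): a filled square gives FD = 2
at every scale, a straight line FD = 1, a single pixel FD = 0. The
implementation is verified against a brute-force double-loop box counter
on 100 random masks.

## 6. Morphospace: spider profiles, significance, sigils

* **Normalization**: per-condition feature means Vp are min–max
  normalized across the conditions under comparison,
  `Vn = (Vp − Vmin)/(Vmax − Vmin)`; features constant across conditions
  are pinned to 0.5 and flagged degenerate. Vn is affine-invariant per
  feature and always places the extreme conditions at 0 and 1.
* **Significance**: per-feature two-sample t-tests of each condition
  against the reference (Welch's unequal-variance test by default; the
  statistical unit is the cell, or the experiment mean when a replicate
  column is supplied). Tiers: `*` p < 0.05, `**` p < 0.01, `***`
  p < 0.001.
* **Spider plot**: the 31 axes ordered by five ontology groups
  (Abundance, Shape, Connectivity, Size, Density & Texture); the
  reference is the 0.5 circle, other conditions are polylines, and
  significant features carry circles sized by tier.
* **Sigil classification**: a pure rule-based function of the
  per-feature (direction, tier) pairs onto three axes — mitochondrial
  state M1–M7 (M2 fusion, M3 branching, M4 compaction, M5 dislocation,
  M6 fission, M7 swelling), localization I1–I3 (I2 membrane-ward, I3
  nucleus-ward), cell shape C1–C6. M1/I1/C1 are the no-change codes;
  composite firings are reported with a conflict flag rather than
  silently resolved.

## 7. Synthetic field generator

`synthgen` produces three-channel fields with exact ground truth, used
for validation and as a worked example. The default parameters define
the study conditions of the package's self-validation.

**Scene.** `n_cells = 4` cells on a jittered 2×2 grid in a 768² frame.
Each cell is a smooth Fourier-perturbed blob (`cell_radius_px = 150`,
i.e. ~32 µm footprint) with one elliptical nucleus
(`nucleus_radius_px = 70`, ~15 µm). Cell placement raises an error when
the requested cells cannot fit.

**Mitochondrial network.** Tubule centre lines are radially constrained
persistent random walks in the cytoplasm (heading diffusion 0.12
rad/step, tangential launch, steering back toward the launch radius) —
tubules arc around the nucleus as in adherent cells. The total
centre-line budget is fixed (`mito_total_length_px = 1200` per cell) and
divided among `round(5 + 75·fragmentation)` tubules. Centre lines are
inflated to tubes by thresholding the distance transform at the
*continuous* half-width `1 + 3·swelling` px (width ≈ 0.3–1 µm). The
continuous width (rather than an integer disk radius) keeps distinct
swelling levels distinct; its upper end is deliberately kept within what
the σ = 1/4 band-pass can represent — much wider tubes hollow out under
the band-pass, a limitation of the measurement recipe itself (§9).

**Knobs** (all in [0, 1]):

* `fragmentation` — few long, occasionally branched tubules → many
  short grains at constant total budget. Side-branch probability decays
  continuously as `0.3·(1 − fragmentation)`.
* `swelling` — tubule width, as above.
* `perinuclear_bias` — a mixture model of perinuclear recruitment: with
  probability b the tubule orbits in the inner 15 % band next to the
  nucleus, otherwise anywhere in the cytoplasm. The expected network-to-
  nucleus distance is linear in b.

**Rendering.** Binary masks → intensity (near-black backgrounds 20/40/20
counts, foregrounds 3000/1500/4000, as in an acquisition optimized for
minimal background) → Gaussian PSF (`psf_sigma = 1` px) → Poisson shot
noise at gain `noise_level²` (0 disables noise). All randomness flows
from a single `numpy` generator seeded by `seed`; identical parameters
give bit-identical fields.

**Ground truth**: true nucleus/cell/mito label masks plus per-cell true
object counts, end/branch points of the thinned true mask, drawn width
and true mean distance to the nucleus.

**What the generator does *not* emulate**: 3D structure and defocus,
chromatic shifts and channel bleed-through, photobleaching, camera read
noise and fixed-pattern noise, intensity heterogeneity along tubules,
cristae substructure, touching/overlapping cells, and non-mitochondrial
organelle signal. It is a geometry-and-statistics benchmark, not an
optics simulation.

## 8. Validation performed by this package

Computed by `pytest` and `scripts/acceptance.py` (see README for how to
run; numbers are recomputed on every run):

* box-count equality with a brute-force oracle on 100 random masks;
  exact FD limits (2/1/0);
* exact cluster↔isolated pixel conservation on synthetic fields;
* skeleton fixtures (bar → 2 ends/0 junctions; cross → 4 ends/1
  junction);
* aggregation and normalization identities;
* byte-identical batch outputs for 1 vs 2 workers;
* ground-truth recovery on noiseless fields: every true cell matched;
  per-cell cluster count within ±10 %, end points within ±20 %, nucleus
  and cell IoU ≥ 0.9;
* monotone dose responses (Spearman |ρ| ≥ 0.9 over 5 levels × 20
  cells/level): MitoCluster_Count ↑, Mito_Roundness ↑ and per-object
  Mito_Length ↓ with fragmentation; Skel_Width ↑ with swelling;
  DistToNuclei ↓ and RatioDistMemb0Nucl1 ↓ with perinuclear bias.

## 9. Numerical choices and limitations

* **Strict thresholds** (`>` median, `>` mean+1SD) and integer
  quantization of integer input (§2.1) make segmentation reproducible
  across platforms; all floating-point reductions are deterministic.
* **Per-field parallelism only**: fields are independent, results are
  assembled in sorted field order, so outputs are identical for any
  worker count.
* **Band-pass width ceiling**: the σ = 1/4 mito band-pass suppresses
  the interior of structures wider than ~8 px; very swollen
  mitochondria would be detected as hollow rims and Skel_Width would
  saturate. At the default pixel size this begins near 1 µm width.
* **Skeleton sensitivity**: thinning erodes ~w/2 from each branch tip,
  so skeleton length slightly under-reports centre-line length for wide
  tubes; end-point counts on noisy data can gain spurious 1-px spurs.
* **Perimeter-based solidity** follows the source definition and is
  *not* interchangeable with conventional area-based solidity.
* **Welch t-tests per feature are not multiplicity-corrected**; the
  tier display is descriptive, as in the original visualization. Use
  the returned p-values for any formal inference.
* **2D only**: all features are projections; out-of-plane structure is
  invisible by design.
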