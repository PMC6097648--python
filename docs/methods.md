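# Methods

## Data model and conventions

Stacks are 3D 8-bit grids ordered `(slice, row, col)`. Slices are frontal
sections whose index increases anterior→posterior by default; the
`VoxelGeometry` metadata (`ap_axis`, `ml_axis`, `medial_direction`, pitches
`dx`, `dy`, `dz` in µm) makes the anatomical axes explicit instead of
assumed, because specimens are mounted and 3D-rotated per preparation.
Stacks are analyzed pre-oriented; no rotation is re-implemented — the
manifest carries the orientation metadata. Voxel indices are 0-based;
physical positions are voxel-center × pitch. Default pitches are the
acquisition values 0.22 µm in plane; the slice step is not implied by the
data and must be stated per specimen (1 µm in the synthetic studies).

Masks on disk are 8-bit TIFFs with 0/255 semantics; any nonzero value reads
as true with a warning so masks drawn in common annotation tools load
unchanged. 16-bit intensity inputs are linearly rescaled onto [0, 255]
with a warning. All mask/stack binary operations demand congruent shape
and geometry and fail loudly otherwise; nothing broadcasts silently.

## Agglomeration removal (white top-hat)

Brp-short fusion protein forms large, bright, non-specific blobs that do
not represent active zones. They are removed by a per-slice grayscale
opening — minimum filter then maximum filter with a discretized disc,
radius 3 px — subtracted from the original with clamping at 0 (8-bit
saturating arithmetic). The opening is anti-extensive for this flat
footprint, so the residual is nonnegative; bright structures strictly
smaller than the disc pass through voxel-exactly while interiors of wider
structures cancel to zero. The "3 pixels" parameter is interpreted as a
radius (the convention of the interactive tool's rank-filter dialog); the
radius-1 disc is pinned to the full 3×3 square so outline counts have a
closed form. Filters are 2D per slice — rank filtering a stack in the
interactive tool operates slicewise — and borders replicate edge values.

Contrast readjustment after the top-hat is a separate, flagged step
(`rescale_contrast`: linear min–max stretch onto [0, 255], constant stacks
unchanged, rounding half-away-from-zero for determinism). The pipeline
applies it by default before thresholding, matching the published order of
operations, but `remove_agglomerations` itself returns the raw top-hat so
the two effects can be audited independently; histogram-shape thresholds
are not invariant to rescaling, which is why the flag is explicit and
logged.

## Histogram auto-thresholds

All thresholds operate on one 256-bin histogram pooled over the whole
stack ("stack histogram"), with bin 255 excluded ("ignore white") so
saturated voxels never drive the level. Foreground is intensity strictly
greater than the level; argmax ties break to the lowest level. Per-channel
defaults: Intermodes for Brp, Default/IsoData for dye fill (DA488) and
Neurobiotin, Rényi entropy for ShakB — the method map is configuration.

* **Intermodes**: smooth the histogram with a 3-bin running mean
  (reflected ends) until exactly two strict local maxima `j, k` remain;
  level = ⌊(j+k)/2⌋. Histograms that never become bimodal within 10,000
  passes (e.g. a single spike) are an error, not a guess.
* **Default/IsoData** (iterated intermeans): bins 0 and 255 are first
  zeroed (erased and saturated areas would otherwise bias the class
  means), then from the midpoint of the nonzero support iterate
  `t ← round((mean ≤ t + mean > t)/2)` to its fixed point, rounding half
  up, with cycle detection. With all mass in one interior bin the level is
  that bin. This variant is pinned and tested against its own fixed-point
  oracle; no bit-parity with any external binary is claimed.
* **Rényi entropy**: candidate levels maximize the summed
  background/foreground Rényi entropy at orders α = 1/2, α → 1 (Shannon)
  and α = 2 over all splits with mass on both sides; the three sorted
  candidates are merged with the published spread-dependent weighting
  (1-2-1 when all agree within 5 levels, 3-1-0/0-1-3 when one pair
  agrees) through the cumulative mass around the extreme candidates. Each
  candidate is verified against an exhaustive-split oracle.

## Derived measures

All quantities are voxel counts with unit conversion. Per-slice area is
foreground count × dx·dy; total volume is Σ area × dz. Overlap volume is
the voxelwise AND count × voxel volume — used both for putative active
zones (Brp ∧ GF) and plaque colocalization (ShB ∧ Brp per territory).
Surface area is approximated by the volume of the one-pixel outline
(mask minus its per-slice radius-1 erosion) divided by the in-plane pixel
size; for an a×b single-slice rectangle this reduces to the closed form
(ab − (a−2)(b−2)) voxels.

The medial compartment is split at a single plane perpendicular to the
mediolateral axis, `round(5 µm / dx)` = 23 px medial of the dendrite
center. The center is the mediolateral centroid of the largest connected
component (26-connectivity) of the GF mask over the whole stack — one
plane, not per-slice, since a per-slice center would wobble with branches.
Voxels strictly beyond the plane are medial; the boundary voxel itself is
core; the two parts are disjoint and exhaustive by construction.

Dye coupling is the mean NB cross-sectional area over `round(10 µm / dz)`
slices centered on the anteriormost GF slice (lowest slice index on the
anteroposterior axis containing dendrite foreground), truncated at stack
edges. The window is defined by physical length, not slice count, so
non-1 µm slice steps are handled by the same rule.

Colocalization percentages use the plaque volume inside each territory as
denominator; an empty denominator reports 0 with a warning instead of
failing a batch run. Region masks (JO-A/JO-B territories) are inputs —
products of manual tracing in real data, of ground truth in phantoms.

## Synthetic phantoms

The generator renders, at 0.22 µm / 1 µm pitch into a 128×128×60 default
stack: a 1 µm-radius dendrite tube along the slice axis with straight
medial branch offshoots (defaults 6 and 7 µm from the axis, clipped with a
warning at the stack border — growth is neuropil-bounded); JO-A axon
cylinders around the dendrite, four of them NB-filled; a JO-B cluster
10 µm medially; 0.5 µm Brp puncta in both territories (25/35, more in
JO-B) plus 40 active-zone puncta seated on the dendrite surface; 1 µm
ShakB plaques (24 JO-A vs 6 JO-B, the ~4-fold control asymmetry), 60% of
them centered on a distinct existing punctum so that plaque/active-zone
colocalization exists by construction (plain-conjunction overlap then
measures roughly 7–20% of control plaque volume as colocalized, the same
order as observed in tissue — the exact percentage is dominated by the
punctum-to-plaque mask size ratio); and 3 µm agglomeration blobs painted
into the Brp channel but never the native-antibody (nc82) channel.

Objects are voxelized at their sub-voxel centers (a voxel belongs to a
ball iff its center is inside), avoiding the systematic volume
overestimate of lattice-aligned voxelization. Rendering order: geometry at
nominal intensity → anisotropic Gaussian PSF → Poisson photon noise +
Gaussian read noise → clip and round to 8 bits. Ground truth is taken
before blur and noise, so truth volumes equal pre-noise foreground
exactly. PSF sigma defaults to (0.4, 0.08, 0.08) µm (z, y, x): lateral
FWHM ≈ 0.19 µm and axial FWHM ≈ 0.94 µm, standard high-NA confocal
resolution; with photon scale 1.0 and read noise 4 DN the plaque SNR is
≈ 10 and the pipeline recovers single-specimen plaque volume within
~±10% of truth, inside the ±20% recovery budget the validation demands.
Out-of-bounds objects raise an error naming the object.

Randomness is centralized: each structure class and each channel's noise
draws from its own fixed substream of the specimen seed, so changing one
class's count (say, JO-B plaques) leaves every other structure and channel
bit-identical — this is what lets the tests show that a plaque-only
manipulation cannot move the active-zone measures except through the
statistics' false-positive rate.

Group studies assign each group multipliers on four effect dimensions
(JO-B plaque load, NB-coupled axon count, medial branch length, AZ count),
with per-specimen lognormal variability (log-sd 0.2, a typical ~20%
between-animal CV) around group means, one child seed per specimen. The
standard validation study mirrors the four-genotype design: control; a
4-fold JO-B plaque group; a reduced-coupling group; and a positive-control
group with 2.5× active zones and 2× medial branch length.

What the phantoms do **not** emulate: real dendrite tortuosity and
tapering, spectral bleed-through, depth-dependent attenuation, antibody
penetration gradients, or spatial correlation between biological structure
and imaging noise. Passing tests therefore demonstrate that the
measurement and statistics chain is correct and calibrated on geometry it
fully controls — not that any specific biological effect size in real
tissue is reproduced.

## Statistics

Shapiro–Wilk normality per group is computed and reported, not used to
switch tests (the design applies ANOVA to normally distributed measures);
constant samples report NaN with a warning. Group comparison is one-way
ANOVA followed by all-pairs Tukey–Kramer HSD,
`q = |m_i − m_j| / sqrt(MSE/2 · (1/n_i + 1/n_j))` against the studentized
range distribution on (k, N − k), valid for unequal animal counts. SEM is
sd/√N with N = animals. Star codes: `*` p ≤ 0.05, `**` p ≤ 0.01, `***`
p ≤ 0.001, boundaries inclusive. Degenerate zero-variance designs report
F = 0, p = 1 for equal means. Under exchangeable groups the any-pair
family-wise error stays at the nominal 5% (checked by simulation).

## Problem sizes used in validation

The recovery and null studies run 4 groups × 8 animals on 128×128×60
stacks; the test suite evaluates 20 seeded studies of each kind and the
acceptance script 10 of each, sizes at which the constructed effects are
detected with essentially full power while a complete study analyzes in
~15 s. Threshold oracle checks use 50 random mixture histograms per
method; Monte-Carlo calibrations use 100–500 replicates.

## Known limitations

* The Default/IsoData and Rényi-entropy variants are pinned to the
  formulations above; other implementations differ in end-bin handling and
  tie-breaks by ±1–2 levels.
* The surface-area proxy is a resolution-dependent estimator, not a mesh
  area; it is only meaningful for comparisons at fixed voxel geometry.
* The medial partition assumes one dominant connected dendrite component;
  heavily fragmented masks would anchor the boundary on the largest
  fragment.
* Intermodes fails (by design, with an error) on histograms that never
  become bimodal, e.g. after an all-false ROI crop.
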