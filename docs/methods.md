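# Methods

## Measured quantities

A projected multi-channel image is partitioned into background, **core**
(the cohesive central cell mass) and **outgrowth** (every cell-covered pixel
outside the core: sprouts still attached to it and detached single cells).
From this partition the package reports, per image:

- areas `A_core`, `A_outgrowth` in px² (and µm² when a pixel size is known:
  `A_um2 = A_px · s²` for isotropic pixel edge `s`);
- the ratio `A_outgrowth / A_core`, reported as *missing* (not 0, not an
  error) when the core is empty;
- per channel `c` and region `R`: mean intensity, integrated density
  `ID_c(R) = Σ_{p∈R} I_c(p)` and the regional percentage
  `100·ID_c(R)/(ID_c(core)+ID_c(outgrowth))`. The integrated density is
  computed as the direct pixel sum; *mean × area* is the same number by
  construction and the identity is asserted in the tests. The percentage
  denominator deliberately excludes background: it expresses how a cell
  type's signal splits between the two measured regions. A channel with no
  signal in either region gets a missing percentage, never 0/0.
- the count of single cells outside the core in one channel (default the
  macrophage channel).

Fold change between conditions is the ratio of condition means, with the
reference pinned to exactly 1. For repeated-measures designs a per-batch
paired table (reference value, condition value, their ratio) is emitted; no
hypothesis tests are computed — the tidy CSVs feed any statistics
environment.

## Projection

Default is per-channel maximum-intensity projection: for sparse fluorescent
structures (thin sprouts, small cells) the maximum preserves contrast that a
mean would dilute, and it is idempotent, which makes pre-projected input and
stack input interchangeable. Sum and mean are available as tags. No
registration, deconvolution or illumination correction is attempted.

## Pixel classification

Per-pixel features are multiscale filters on each channel (all channels by
default, since the core carries every cell type while sprouts and detached
cells occupy specific channels): Gaussian smoothing, Gaussian gradient
magnitude and Laplacian at sigmas {1, 2, 4, 8} px, with reflective borders.
Difference-of-Gaussians and the largest structure-tensor eigenvalue are
available kinds; each kind contributes exactly one feature per (channel,
sigma), keeping the feature count at |sigmas|·|kinds|·|channels|.

The classifier is a 100-tree random forest with balanced class weights and a
fixed seed; inference is deterministic. The out-of-bag score over the
labeled pixels is recorded as the held-out accuracy estimate. A class with
zero labeled pixels is an error naming the class; fewer than 50 labels per
class is a recorded warning. Annotations arrive as sparse label masks
(−1 = unlabeled) or polygon JSON rasterized to masks.

Two segmentation idioms are supported, mirroring the two ways trainable
pixel classification is used in practice: (a) direct three-class
classification refined morphologically, and (b) a two-class cell/background
split — from a classifier or from the deterministic threshold fallback
(fixed value or Otsu) — with the core extracted morphologically
(erosion by `r_core` = 5 px annihilates sprouts, the largest surviving
component is dilated back, hole-filled and intersected with the mask).
The threshold fallback intentionally returns the cell mask plus QC flags
rather than a finished label map: the core/outgrowth split is a separate,
composable step (`segment_by_threshold` does both).

## Region refinement

Core candidates are 4-connected components of the core class after opening
(radius 3 px) and hole filling; the largest wins, ties broken by centroid
proximity to the image center (fields image one centered spheroid; nothing
defines multi-spheroid fields). All other core-labeled pixels are relabeled
outgrowth — stray core islands far from the spheroid are by definition
migrated cells. Outgrowth objects under 9 px² are dropped as speckle; the
bound is kept below the area of a single detached cell (radius ≥ 2 px) so
real cells always survive. 4-connectivity conservatively separates sprout
tips that barely touch the core. A core touching the border is kept but
flagged (its area is then a lower bound). Refinement is idempotent and
always yields a partition.

## Cell detection

Scale-normalized Laplacian-of-Gaussian responses are maximized over sigmas
1.5–3.5 px (5 steps) on the max-normalized channel; maxima below 0.3 or
closer than 2 px (weaker one) are suppressed; peaks are refined to subpixel
precision by a 3×3 center of mass. Rationale for the defaults: a disk-like
cell of radius r peaks near σ = r/√2 (≈ 2.1 px for the 3-px cells the
generator plants), so the sigma range brackets the cell scale without
extending to multi-cell scales where crowded clusters grow interstitial
maxima; a unit-contrast cell's matched response is ≈ 0.55–0.65 while
pure-noise responses at the highest validated noise stay below ≈ 0.2, so
0.3 splits the two populations; normalization uses the smoothed-image
maximum because the raw maximum is inflated by noise spikes. Detection is
restricted to outside the core dilated by 2 px (rim artifacts), but
detections on background-labeled pixels count — a detached cell whose dim
halo was classified background is still a migrated cell.

## Synthetic generator

`SpheroidScene` renders what a projected 10X confocal field of a
collagen-embedded spheroid looks like: a filled disk core carrying all three
cell-type channels at nominal intensity; unbranched anti-aliased sprouts
(capsules with a 1-px soft edge) radiating from the core rim, carrying the
FLS and EC channels with independent per-sprout intensity jitter
(0.7–1.0×); detached cells as small disks in the macrophage channel only
(jitter 0.8–1.0×), rejection-sampled inside an annulus with centers ≥ 2r
apart (a placement error is raised when the ring cannot host them).
Structures compose per channel by pixel-wise maximum. Defaults: 256×256 px,
core radius 40, 18 sprouts of mean length 55 ± 10 px and width 5 px, 12
detached cells of radius 3 in a 105–122 px ring, nominal intensity 200,
additive Gaussian noise σ = 8 (4% of nominal; validation sweeps go to 20%),
Poisson noise off.

Ground truth is frozen on the quantized noiseless composite before noise is
drawn: the core mask is the geometric disk, outgrowth is every other
positive pixel, and the per-channel noiseless images are returned verbatim.
Geometry, plane assignment and noise use three independent RNG streams split
from one seed, so the optional Z-stack mode (structures distributed over
planes) projects back to exactly the single-plane render of the same
parameters, and the same seed is bit-reproducible.

Sprout angles are stratified (even grid + bounded jitter) so sprouts do not
overlap at default densities and the expected outgrowth area is linear in
sprout count. `make_condition_set` scales the sprout count by the requested
fold (mean length absorbs integer rounding) and the detached count
proportionally; the scaling is accurate through fold 2 (measured 2.04 over
8 replicates). At fold 4 rim crowding makes sprout overlap unavoidable and
the realized area is ≈ 3.6× — real dense outgrowth overlaps the same way —
so fold 4 should only be used for ordering, not calibration.

What the generator does *not* emulate: sprout branching and anastomosis,
intensity falloff along sprouts, uneven illumination, out-of-focus haze,
chromatic misregistration, autofluorescent matrix texture, and cores with
irregular (non-disk) outlines. Passing the synthetic suite therefore shows
the measurement machinery is correct and noise-robust under these
conditions; it does not certify classifier performance on real tissue,
where classifiers are expected to be retrained per image pool (the manifest
supports per-image model overrides for exactly that workflow).

## Validation problem sizes

The test suite and `scripts/acceptance.py` train on a 3-image pool spanning
noise σ ∈ {8, 24, 40} with 2% of truth pixels as annotations, sweep 20
scenes at noise up to 20% of nominal, recover counts for K ∈ {10, 50, 200}
planted cells (on a 512×512 field with a 120–240 px ring, since the default
ring cannot host 200 non-overlapping cells), and run an 8+8-replicate
two-condition cohort with an imposed 2× contrast. Typical results: mean
core IoU ≈ 0.99, mean outgrowth IoU ≈ 0.96, worst-case ratio error ≈ 5%,
exact count recovery at zero noise, cohort fold change within 1.87–2.06
across seeds, byte-identical reruns.

## QC and missing-value policy

Per-image failures in a batch are logged and skipped, never fatal. Images
flagged "empty core" are excluded from ratio and percentage summaries only
(all exclusions listed in `exclusions.csv`); their remaining metrics are
still reported. All intensities are held as unsigned integers as read and
all statistics are computed in float64; coordinates are (row, col), 0-based.

## Known limitations

- Area-based outgrowth carries no information about sprout length, number,
  branching or network topology; systems whose phenotype changes shape but
  not area need complementary measures.
- The threshold fallback underestimates outgrowth on noisy images (Otsu
  cuts the dim sprout fringe); it is a deterministic baseline, not a
  substitute for a trained classifier.
- One spheroid per field is assumed; multi-spheroid fields would need
  instance handling the refinement deliberately does not attempt.
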