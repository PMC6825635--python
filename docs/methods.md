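# Methods

`microvasc` quantifies tumor microvasculature in 3D immunofluorescence
volumes (single channel, typically the endothelial marker CD34 in cleared
tissue imaged by light-sheet microscopy).  This note records the models,
conventions, numerical choices and known limitations behind each stage.

## Volumes and the analysis grid

A volume is a `VoxelGrid`: a 3D nonnegative intensity array in (z, y, x)
axis order with physical spacing (dz, dy, dx) in µm, z being the
optical-section axis.  Light-sheet acquisitions are strongly anisotropic
(here 0.585 µm laterally, 5 µm between sections); all analysis runs on an
isotropic grid, 5 µm by default, reached by **block averaging**: the block
size per axis is `round(target/spacing)` (minimum 1) and each output voxel
is the plain mean of the input voxels it covers.  Block averaging rather
than interpolation preserves the fraction-of-signal semantics that the
density statistic depends on; a constant volume stays constant and, for
evenly dividing extents, the global mean is preserved exactly.  Voxels
left over at the upper border are folded into the last block instead of
padded, so no intensity is fabricated at edges.

Spacing is always caller-supplied: TIFF resolution tags in cleared-tissue
exports are unreliable and are only compared against the supplied values
to emit a warning.

## Vessel segmentation

Vessels are segmented by **hysteresis thresholding**: a voxel is positive
iff its intensity is ≥ the low threshold and it is connected, through
voxels ≥ the low threshold, to at least one voxel ≥ the high threshold.
This keeps dim vessel stretches contiguous with bright ones while
rejecting isolated background fluctuations.  Implementation: label the
low-mask (scipy.ndimage, connectivity 6/18/26 as configured) and keep
components containing a high voxel.  With low = high this reduces exactly
to simple thresholding, and output is monotone in both thresholds.

Default connectivity is 26: thin vessels running obliquely to the grid
disconnect under face-only adjacency.  Components smaller than
`min_component_voxels` (default 27 ≈ a 15 µm cube at the 5 µm grid) are
removed as noise speckle.  This cleanup intentionally biases density
downward by deleting true fragments smaller than the cutoff (e.g. vessel
tips just entering the field); on noise-free input there is nothing to
suppress and the appropriate setting is 0.

When no fixed thresholds are configured, `auto_thresholds` derives them
from the histogram ("otsu-split"): high = Otsu threshold of the full
histogram, low = midpoint between high and the histogram mode below it
(the background peak).  This presumes a background/vessel bimodal
histogram; on a signal-free noisy volume Otsu will still split the noise,
so runs on volumes that may contain no vessels should use fixed
thresholds.  A constant volume is reported as degenerate and the pipeline
emits an empty mask with a warning.

## Vascular graph and radii

The mask is thinned to a one-voxel-wide centerline by 3D topological
thinning (scikit-image's Lee-style `skeletonize`).  Two repairs make the
result satisfy the downstream contracts: (i) a component whose skeleton
vanished entirely (possible for components of a few voxels) gets one voxel
back — the component's deepest voxel by distance transform — so the
skeleton preserves the 26-connected component count; (ii) residual solid
2×2×2 blocks, which the thinning pass occasionally leaves in dense
branched regions, are removed by a deterministic greedy pass that only
deletes a voxel when its remaining 26-neighbourhood stays one connected
component and a background 6-neighbour exists (no disconnection, no sealed
cavity).

Graph extraction: nodes are skeleton voxels whose 26-neighbour count
differs from 2 (endpoints, branch points); segments are maximal centerline
paths between nodes; a pure cycle (every voxel degree 2) receives one
anchor node and a single closed segment, so every skeleton voxel belongs
to exactly one polyline, with branch voxels shared as endpoints.
Positions are physical (µm).

The **radius** at a centerline point is the anisotropy-aware Euclidean
distance transform of the mask sampled at that point — the radius of the
largest ball centred on the centerline that fits inside the vessel.  On
digital cylinders of radius 3, 4 and 6 voxels the interior mean estimate
is within 0.17 voxel of truth (the estimator slightly overestimates, by
the distance from the surface to the first excluded voxel centre).  Near
segment ends the distance transform is truncated by the end caps, so
cylinder-recovery checks evaluate interior points only (two voxels in from
the skeleton ends; thinning itself already retracts ends by roughly one
radius).

Per-sample mean radius is the unweighted mean over all centerline points.
A length-weighted mean or per-segment mean are defensible alternatives;
the unweighted point mean is the simplest single number and is what the
summary reports.  Calibre classes follow the conventional pseudo-colour
bounds: thin < 3 µm, thick > 11 µm, boundaries inclusive to intermediate;
class fractions are length fractions with each inter-point step classified
by the mean radius of its endpoints.

## Density heterogeneity features

The volume is split digitally into z-sections one voxel thick at the
analysis grid (5 µm).  Section density = 100 × positive voxels / section
voxels (or tissue-mask voxels when a tissue mask is supplied; sections
with no tissue are dropped with a warning).  Over the ordered density
series the features are:

* mean density, percent scale;
* variance, **population variance on the fraction scale** (densities/100);
* skewness g1 = m3 / m2^(3/2);
* excess (Fisher) kurtosis g2 = m4 / m2² − 3;

central moments with 1/n normalisation, no small-sample bias correction
(negligible at hundreds of sections).  The conventions are pinned by the
published pilot table this package reproduces: its normal-urothelium
kurtosis is negative (only possible on the excess convention) and its
sample 1 pairs mean density 25.67% with variance 0.001135 (only possible
with variance on the fraction scale, σ ≈ 3.4 percentage points).
Skewness and kurtosis are scale-invariant, so the fraction/percent split
affects neither.  A constant series has variance 0 and undefined
skewness/kurtosis, which propagate as missing values (NaN/null) rather
than exceptions so batch runs survive degenerate samples.

Group summaries are unweighted arithmetic means of each numeric field
across samples.  Group comparison reports differences and ratios only —
no significance testing, which would be meaningless at pilot sample
counts.

The scientific signal: a spatially homogeneous vascular bed gives a
near-symmetric density distribution (skewness ≈ 0, excess kurtosis ≈ 0),
while vessels crowded into part of the depth range give many near-empty
sections plus a heavy right tail — high skewness and kurtosis, the
signature separating invasive from superficial tumors.

## Synthetic phantoms

`generate_tube_network` emulates a cleared-tissue vessel volume: trees
grow as persistent random walks (direction perturbed by a bounded random
rotation per 5 µm step, branching with probability 0.05 per step to depth
≤ 3, which keeps the branching process bounded), carry lognormal radii,
and are rasterised as solid circular cross-sections.  The intensity model
is vessel level 180 on the mask, Gaussian PSF blur (σ 1 µm), plus
N(20, 5²) background noise, clipped at zero.  Tubes are grown and
rasterised in a region padded by 25 µm on every face and cropped, so
sections at the volume faces are not depleted by sphere clipping — without
this the homogeneous density distribution acquires an artifactual heavy
left tail.

Spatial regimes: `homogeneous` walks fill the volume; `clustered` confines
seeds to the leading `cluster_z_fraction` of z and reflects walks at the
slab faces, so vessels genuinely concentrate in a slab.  Both modes
consume the identical random sequence, so a matched pair differs only by
the z-compression of the same trees, and `cluster_z_fraction = 1.0` is
bit-identical to homogeneous.

Default conditions (chosen once): 128³ voxels at the 5 µm grid, 120
trees, radii lognormal(median 6 µm, σ 0.35), `cluster_z_fraction` 0.1.
The tree count puts homogeneous-mode density at 15–21%, the range reported
for real CD34-labelled tumor tissue; the slab fraction follows from the
moment structure of zero-inflated series — occupied fraction p gives
excess kurtosis ≈ (1 − 6p(1−p))/(p(1−p)), positive only for p ≲ 0.21, and
p ≈ 0.05–0.1 reproduces the kurtosis (≈ 5–20) and skewness (≈ 2–4) scales
observed in real invasive tumors.  At these defaults the clustered member
of a matched pair shows higher excess kurtosis and skewness than the
homogeneous member in 10/10 paired runs.

What the phantoms do **not** model: light-sheet stripe artifacts,
depth-dependent attenuation and scattering, labelling inhomogeneity,
vessel taper and diameter continuity at branch points, and anatomically
realistic branching statistics.  Passing phantom tests therefore
demonstrates correctness of the measurement chain on known geometry, not
performance on real tissue; real-data thresholds in particular will need
per-dataset choice (the published study did not disclose its thresholds).

`generate_density_series` draws i.i.d. series from Gaussian, lognormal,
exponential or Gaussian-mixture families with closed-form population
skewness/kurtosis returned alongside, for estimator tests without any
imaging; draws are clipped to [0, 100] and the clipped fraction reported
(a warning above 1%, where moments start to distort).

## Pipeline, determinism, blinding

`run_sample` chains load → downsample → segment → densities → features →
skeleton/graph/radii → summary, writing every intermediate artifact plus a
MANIFEST recording completed stages; a failing stage propagates with its
name and partial outputs are kept.  Everything is deterministic for a
fixed config and seed — reruns produce byte-identical summary JSON.
Sample labels (stage/grade) are attached only at the reporting step;
feature computation never reads them, mirroring blinded analysis.  The
summary table has the fixed column set (sample_id, label, cd34_density,
variance, kurtosis, skewness, vessel_radius_um, n_sections); group rows
are appended per label by `run_group`/`report`.

## Reference data

`microvasc.reference_data` carries the published per-sample feature
vectors of a four-tumor pilot study (two TaG1, two T3G3, plus a normal
urothelium mean row).  The underlying image volumes were never deposited,
so per-sample values cannot be recomputed from images at all; they serve
as inputs to the summarise/aggregate/report path, whose group-mean rows
are recomputed from them and match the published means to one unit in the
last printed digit (the published table mixes rounding conventions, e.g.
19.815 printed as 19.81 but 1.10495 as 1.105).

## Problem sizes used in validation

Validation runs are sized to settle each question without waste: moment
estimators at n = 10⁵ (Gaussian) and 10⁶ (exponential); the
hysteresis-vs-flood-fill oracle on one hundred 16³ volumes cycling 6/18/26
connectivity; cylinder recovery at radii 3/4/6 voxels, length 40; mask and
density recovery on a 64³ noise-free phantom; the heterogeneity contrast
on ten matched 128³ pairs; determinism on a 32³ phantom run twice.
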