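# microvasc

3D tumor microvasculature morphometry from light-sheet volumes.

Solid-tumor aggressiveness correlates with how disorganised the tumor's
blood-vessel network is.  In cleared, immunolabelled tissue (e.g. the
endothelial marker CD34 in iDISCO-cleared biopsies) a light-sheet
microscope delivers a full 3D view of that network, and simple
distributional statistics of the vessel signal separate phenotypes that
2D histology struggles with: high-grade invasive urothelial tumors show
strongly right-tailed per-section vessel-density distributions (high
skewness and excess kurtosis), while low-grade superficial tumors and
normal urothelium sit near symmetric.  `microvasc` implements the full
measurement chain for anyone who has such volumes — or who wants to
validate the chain on synthetic ground truth:

1. **Volume I/O** — TIFF z-stacks with physical voxel spacing, block-mean
   resampling to an isotropic analysis grid (5 µm default).
2. **Segmentation** — hysteresis thresholding (voxel kept at intensity
   ≥ low iff connected to a voxel ≥ high), connectivity 6/18/26,
   histogram-derived or fixed thresholds, speckle removal.
3. **Vascular graph** — 3D thinning to a centerline, node/segment graph
   extraction, per-point radius via the anisotropy-aware Euclidean
   distance transform, calibre classes (thin < 3 µm / thick > 11 µm),
   CSV spatial-graph export.
4. **Density heterogeneity** — per-5 µm-z-section marker density d_k (%),
   and over the series {d_k}: mean, population variance (fraction scale),
   skewness g₁ = m₃/m₂^{3/2} and excess kurtosis g₂ = m₄/m₂² − 3 with
   1/n central moments.
5. **Synthetic phantoms** — branching-tube networks with exact ground
   truth (mask, centerlines, radii, densities), homogeneous vs
   z-clustered regimes, PSF blur and background noise, plus i.i.d.
   density-series generators with closed-form moments.
6. **Pipeline & CLI** — `microvasc run` chains everything per sample with
   a manifest and deterministic outputs; `microvasc report` aggregates
   per-sample summaries into a table with group-mean rows.

## Worked example 1: phenotype report from published per-sample features

The package ships the per-sample feature vectors of a four-tumor pilot
study (two low-grade superficial TaG1, two high-grade invasive T3G3) as
`microvasc.reference_data`; the group-mean rows below are recomputed from
them, not stored:

```python
import microvasc as mv
from microvasc.reference_data import utuc_pilot_summaries

table = mv.run_group(utuc_pilot_summaries())
print(table.to_string(index=False))
```

```
sample_id label  cd34_density  variance  kurtosis  skewness  vessel_radius_um  n_sections
        1  TaG1        25.670  0.001135    2.8700   1.65700            3.5790       483.0
        2  TaG1        13.960  0.021580    4.8650   0.55290            3.1180       377.0
        3  T3G3        22.510  0.006638   16.0900   3.73400            3.1970       506.0
        4  T3G3        21.650  0.014660   23.0100   3.84500            2.7330       414.0
mean_TaG1  TaG1        19.815  0.011357    3.8675   1.10495            3.3485       430.0
mean_T3G3  T3G3        22.080  0.010649   19.5500   3.78950            2.9650       460.0
```

The invasive group's density kurtosis (19.55 vs 3.87) and skewness (3.79
vs 1.10) dwarf the superficial group's, while mean density and vessel
radius barely differ — the heterogeneity features, not the amount of
vasculature, carry the phenotype:

```python
ta = mv.aggregate_group([s for s in utuc_pilot_summaries() if s.label == "TaG1"], "TaG1")
t3 = mv.aggregate_group([s for s in utuc_pilot_summaries() if s.label == "T3G3"], "T3G3")
print(mv.compare_groups(ta, t3).to_string(index=False))
```

```
         feature      TaG1      T3G3  difference    ratio
    cd34_density 19.815000 22.080000    2.265000 1.114307
        variance  0.011357  0.010649   -0.000709 0.937618
        kurtosis  3.867500 19.550000   15.682500 5.054945
        skewness  1.104950  3.789500    2.684550 3.429567
vessel_radius_um  3.348500  2.965000   -0.383500 0.885471
```

## Worked example 2: full pipeline on a synthetic volume

```python
import numpy as np
import microvasc as mv

spec = mv.PhantomSpec(shape=(64, 64, 64), n_trees=15, seed=1)
grid, truth = mv.generate_tube_network(spec)
mv.write_tiff_stack(mv.VoxelGrid(grid.data.astype(np.float32), grid.spacing), "phantom.tif")

config = mv.PipelineConfig(input_path="phantom.tif", spacing_um=(5, 5, 5), output_dir="out")
summary = mv.run_sample(config, "phantom01", "homogeneous-demo")
print(summary.as_row())
```

produces (artifacts under `out/phantom01/`: mask, skeleton, spatial graph
CSVs, density series, summary, manifest):

```
{'sample_id': 'phantom01', 'label': 'homogeneous-demo',
 'cd34_density': 17.631149291992188, 'variance': 0.0007388620724668726,
 'kurtosis': -0.30346587272743397, 'skewness': 0.6046969694544105,
 'vessel_radius_um': 5.693364756199188, 'n_sections': 64}
```

Against ground truth: the phantom's true mean density is 17.314%
(estimated 17.63% through blur and noise), the radius distribution has
median 6 µm (estimated point mean 5.69 µm), and the near-zero excess
kurtosis correctly reports the homogeneous regime; rerunning the same
config reproduces the summary byte-for-byte.  The same chain is available
from the shell: `microvasc phantom | segment | graph | features | run |
report` (see `microvasc --help`).

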