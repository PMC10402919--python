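# spheroidq

Semi-automated quantification of 3D spheroid outgrowth from multi-channel
confocal fluorescence images.

## The problem

Multicellular spheroids embedded in a collagen matrix — for example
co-cultures of fibroblast-like synoviocytes (FLS), endothelial cells (EC)
and macrophages used to model inflamed synovial tissue — expand by cell
migration: filamentous sprouts radiate from the cohesive central core and
single cells detach and wander into the matrix. Standard angiogenesis tools
quantify one channel (EC sprouts) and do not transfer to heterogeneous
multi-cell-type systems. `spheroidq` quantifies the *outgrowth*: everything
cell-covered outside the core, whichever cell type it is, directly from the
multi-channel image.

For each spheroid image the pipeline computes:

- **outgrowth/core area ratio** — `A_outgrowth / A_core`, the headline
  expansion statistic;
- **per-channel integrated densities** — `ID_c(R) = Σ_{p∈R} I_c(p)`
  (identically *mean intensity × area*), a proxy for the amount of cell
  type *c* in region *R*, plus its regional percentage
  `100·ID_c(R) / (ID_c(core)+ID_c(outgrowth))`;
- **counts of single cells outside the core** (default: the macrophage
  channel), by multiscale Laplacian-of-Gaussian blob detection.

Per-condition averages, SD/SEM and fold changes against a reference
condition (ratio of condition means), plus per-batch paired tables for
repeated-measures designs, are aggregated from a simple CSV manifest.

## How it works

1. **Projection** — multi-channel confocal Z-stacks are collapsed to 2D by
   per-channel maximum-intensity projection (sum/mean optional); channels
   are never mixed.
2. **Pixel classification** — a seeded random-forest classifier with
   multiscale Gaussian/gradient/Laplacian features maps every pixel to
   {background, core, outgrowth}, trained from sparse annotations (label
   masks or polygon JSON). A deterministic global-threshold fallback (fixed
   or Otsu) plus morphological core extraction covers the classifier-free
   workflow.
3. **Region refinement** — the core is forced to a single 4-connected
   component (morphological opening, hole filling, largest-component
   selection with centroid tie-break); stray core islands become outgrowth;
   speckles are dropped; QC flags (empty core, multiple candidates, border
   contact) are recorded and empty-core images are excluded from ratio
   averages, never silently zeroed.
4. **Measurement** — areas (px² and µm² when calibrated), ratio, integrated
   densities, percentages, blob counts.

A built-in synthetic spheroid generator renders scenes — bright multi-channel
core, radiating FLS+EC sprouts, detached macrophage-channel cells, additive
and/or Poisson noise — with pixel-exact ground-truth masks, planted cell
coordinates and noiseless per-channel images, so the entire pipeline is
validated without any real microscopy data.

## Worked example (CLI)

```sh
cat > scenes.yaml <<'YAML'
scenes:
  demo_a: {noise_sigma: 8.0}
  demo_b: {n_sprouts: 36, noise_sigma: 8.0}
YAML
spheroidq simulate --config scenes.yaml --out sim --seed 5
spheroidq train --images sim --annotations ann --out model.bin --seed 0
spheroidq classify sim/demo_b.ome.tif --model model.bin --out labels_b.tif
spheroidq quantify --image sim/demo_b.ome.tif --labels labels_b.tif --out metrics.csv
spheroidq report --manifest manifest.csv --model model.bin --reference UNSTIM --out rep
```

Output of that session (annotations were 2%-subsampled truth labels;
`demo_b` doubles the sprout count of `demo_a`):

```
demo_a: wrote image + truth (seed=5)
demo_b: wrote image + truth (seed=6)
trained on 1 image(s); held-out accuracy estimate 0.983; saved model.bin
labels -> labels_b.tif; qc: none
outgrowth/core ratio: 2.5642914012738856
4 image(s) quantified -> rep
  STIM: ratio mean 2.564 (n=2), fold change vs UNSTIM: 1.838
  UNSTIM: ratio mean 1.395 (n=2), fold change vs UNSTIM: 1.000
```

The ratio 2.56 means the cell-covered area outside `demo_b`'s core is 2.56×
the core area; doubling the sprout count roughly doubles the outgrowth, so
the fold change vs the unstimulated condition lands near 1.8. The same
operations are available as a library (`spheroidq.render_scene`,
`train_classifier`, `measure_regions`, `run_pipeline`, ...).

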