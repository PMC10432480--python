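# gliomorph

Automated morphometry of the **gliovascular unit** in 2D fluorescence
micrographs.  During postnatal cortical development, astrocytes ramify,
tile the neuropil and wrap the growing microvasculature with endfeet
enriched in connexin-43 and aquaporin-4; quantifying that maturation
from maximum-intensity projections requires a reproducible measurement
chain rather than manual tracing.  `gliomorph` provides that chain for
anyone analyzing calibrated single-channel TIFFs of astrocyte, vessel,
connexin and neuron stains — plus a seeded synthetic-scene generator
with exact planted ground truth, so every stage of the pipeline is
testable without any imaging data.

## What it computes

Given images with a µm/pixel calibration, per sample:

* **Astrocytes** — somata are detected (pluggable detector; classical
  default), processes segmented by a strict adaptive threshold (pixel
  intensity > mean over a circular 20 µm window), filtered at 25 µm²,
  thinned to medial lines and stored per cell as a graph: a root node
  for the body, bifurcation nodes where the medial line has ≥ 3
  neighbours, terminations where it has 1, edges carrying arc length in
  µm (axial step = 1 px, diagonal = √2 px), and terminal spurs < 4 µm
  pruned.  Reported: density (cells/mm²), extension length density
  (µm/µm²), branching-point density (nodes of degree ≥ 3 per mm²), and
  the **process-angle entropy** — the Shannon entropy (bits, 18 bins
  over [0, π)) of local medial-line orientations fitted by total least
  squares in 4.5 µm windows; 0 when every process runs one way, high
  when no direction is preferred.
* **Vessels** — the same medial-line graph without a root; vessel
  length density, branching density, and a per-centerline-pixel local
  diameter from the exact Euclidean distance transform.
* **Connexin puncta** — blur, adaptive threshold, 15 µm² filter;
  **coverage** = punctate area within 6 µm of the vessel mask divided
  by vessel area, stratified by local vessel diameter ≤ 4.5 µm vs
  > 4.5 µm.
* **Neurons** — histogram equalization, multi-scale Laplacian-of-
  Gaussian detection (σ = 4.5–9 µm, scale-normalized response > 0.1),
  and density per 50 µm depth band below a traced cortical surface.
* **Relationships** — fraction of astrocytes with ≥ 1 process pixel on
  a vessel, and cell-body / astrocyte-signal densities in 1 µm annuli
  of distance from the vessel wall, normalized by the whole-sample
  density.

The model, defaults and numerical choices are documented in
[`docs/methods.md`](docs/methods.md).

## Worked example

```python
import gliomorph as gm

params = gm.SceneParams(seed=1, noise_sigma=0.0)   # 1 mm^2 benchmark field
scene = gm.generate_scene(params)
images = {ch: gm.render(scene, ch) for ch in ("astrocyte", "vessel", "puncta")}
result = gm.analyze_images(images)

rep = result.report
print(f"astrocytes:        {rep.astrocyte_density_mm2:.1f} cells/mm^2")
print(f"process length:    {rep.extension_length_density:.5f} um/um^2")
print(f"branch points:     {rep.branching_density_mm2:.1f} /mm^2")
print(f"angle entropy:     {rep.mean_angle_entropy_bits:.2f} bits")
print(f"vessel density:    {result.vessel_density:.5f} um/um^2")
print(f"contact fraction:  {result.fraction_contacting:.2f}")
print(f"Cx coverage <=4.5: {result.coverage.coverage_small:.3f}  "
      f">4.5 um: {result.coverage.coverage_large:.3f}")
```

prints

```
astrocytes:        50.0 cells/mm^2
process length:    0.00520 um/um^2
branch points:     78.0 /mm^2
angle entropy:     2.89 bits
vessel density:    0.00301 um/um^2
contact fraction:  0.12
Cx coverage <=4.5: 0.320  >4.5 um: 0.356
```

The scene planted 50 somata (recovered exactly), 0.00509 µm/µm² of
process centerline and 78 branch points (both recovered within a few
percent — arc lengths on a pixel grid carry a small, documented octile
bias), and 0.00321 µm/µm² of vessel centerline.  The entropy of ~2.9
bits reflects isotropically oriented processes; an aligned field scores
markedly lower.  Coverage values are the fraction of each vessel-
calibre stratum's area covered by vessel-associated connexin.

## Command line

```sh
gliomorph simulate --config scene.yaml --seed 4 --out sim/   # scene.json + per-channel TIFFs
gliomorph analyze  --config run.yaml                         # one report directory per sample
```

`run.yaml` holds a `RunConfig`: input paths per channel, the
calibration, and every threshold (all defaulting to the protocol values
above).  The report directory contains the summary and per-cell CSVs,
graph JSONs, mask TIFFs, profile CSVs and a `provenance.json` echoing
every applied parameter.  Exit codes: 0 success, 1 bad input, 2
internal error.

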