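# samsurf

Tissue-resolution 3D surface phenotyping of plant shoot apices from
confocal image stacks.

The shoot apical meristem (SAM) of *Arabidopsis* is a dome of stem cells
that continuously initiates flower primordia on a golden-angle spiral.
`samsurf` turns a confocal stack of a membrane- or surface-stained apex
into quantitative, organ-level phenotypes:

1. **Surface reconstruction** — preprocess the stack (isotropic
   resampling, CLAHE, Gaussian smoothing), segment the tissue solid with
   a morphological active contour (Chan-Vese, with an Otsu fallback),
   repair the mask, and extract a 2.5D epidermal surface mesh via
   marching cubes followed by ACVD-style uniform simplification, rim
   erosion and base clipping.
2. **Curvature** — per-vertex mean curvature from the cotangent
   Laplacian, conditioned by truncation, a sign-gated min-max filter and
   neighbourhood smoothing.
3. **Organ segmentation** — hill-climbing of the curvature field to its
   local maxima (attractors) partitions the mesh into basins; a cascade
   of merge rules (depth, engulfed, disconnected, distance, angle)
   collapses spurious basins; the inflorescence domain is identified by a
   vertical ray from the tissue centre of mass.
4. **Dome parameterisation** — least-squares fit of the paraboloid
   `z = p1·x² + p2·y² + p3·x + p4·y + p5`, giving the apex position,
   the tissue-level Gaussian curvature `p1·p2`, a dome-asymmetry ratio,
   and mesh-to-fit distances.
5. **Phenotypes** — per-organ surface area, curvature statistics and
   distances; divergence angles between successive primordia and their
   spread around the golden angle (137.5°); *CLV3*-style apex estimation
   from a reporter channel with a quantile ladder; apex-definition
   comparison; resolution sensitivity benchmarking; Mann-Whitney-Wilcoxon
   group comparisons with Bonferroni correction and significance stars.

A seeded synthetic generator (`samsurf.synthetic`) renders ground-truthed
apices — a paraboloid dome plus Gaussian primordium bumps on a golden
spiral — both as voxel stacks and as labelled meshes, so every stage can
be validated against known truth without binary fixtures.

## Quick start

```python
import numpy as np
from samsurf import (PipelineConfig, load_stack, reconstruct_surface,
                     prepare_curvature, segment_mesh, fit_paraboloid, apex)

vol = load_stack("apex.tif", spacing=(0.5, 0.25, 0.25))  # (z, y, x) in um
cfg = PipelineConfig(target_spacing=0.5)
mesh = reconstruct_surface(vol, cfg)

field = prepare_curvature(mesh)
seg = segment_mesh(mesh, field)           # organ labels + inflorescence
dome = fit_paraboloid(mesh.vertices[seg.labels == seg.inflorescence_label])
print("apex:", apex(dome))
```

Or from the command line:

```bash
samsurf simulate --bumps 5 --out apex.tif
samsurf surface apex.tif --out apex.ply
samsurf all apex.tif --out results/
```

## Worked example

`examples/` contains six short narrative scripts. Representative output
(`python examples/01_reconstruct_surface.py` and friends):

```
simulated stack: shape=(49, 121, 121), spacing=(0.5, 0.5, 0.5) um
mesh: 2187 vertices, 4194 faces
mean |error| vs analytic surface: 0.044 um (max 0.373)
```

Segmentation of a five-primordium golden-spiral apex recovers exactly
six domains (five organs + inflorescence); the paraboloid fit on a
reconstructed dome returns parameters within a fraction of a percent
(`p1` true −0.01500 → fit −0.01509) and Gaussian curvature 1.214×10⁻⁴
against a truth of 1.200×10⁻⁴. Divergence angles on an eight-organ
spiral deviate from 137.5° by at most 0.08°. Downsampling the stack
laterally by 2× and 4× degrades the surface by 1.4 and 4.3 μm mean
closest-point distance, and a 4-vs-4 simulated wild-type/mutant cohort
separates at p = 0.029 (`*`) in the Mann-Whitney-Wilcoxon test.

## Layout

- `src/samsurf/` — the library (`volume`, `contour`, `mesh`,
  `curvature`, `segmentation`, `paraboloid`, `phenotype`, `stats`,
  `synthetic`, `pipeline`, `cli`).
- `examples/` — six narrative scripts covering reconstruction,
  segmentation, paraboloid fitting, phyllotaxis, resolution
  benchmarking and batch processing.
- `tests/` — unit, property and acceptance tests; all fixtures are
  generated programmatically at test time.
- `docs/methods.md` — algorithms, parameter defaults and rationale.
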