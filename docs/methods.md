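# Methods

This document describes the algorithms implemented in `samsurf`, the
default parameters, and the reasoning behind the main design decisions.
All lengths are in micrometres (μm); stacks are indexed `(z, y, x)` and
meshes live in `(x, y, z)` world coordinates.

## 1. Volume preprocessing (`samsurf.volume`)

- **Loading** (`load_stack`): TIFF stacks via tifffile; multi-channel
  stacks are reduced to a single channel; voxel spacing is read from
  ImageJ metadata or given explicitly.
- **Isotropic resampling** (`resample_isotropic`, default target
  0.5 μm): cubic-spline interpolation. Confocal stacks are typically
  anisotropic (coarser in z); the contour, marching cubes and curvature
  stages all assume isotropic voxels.
- **Contrast equalisation** (`equalize_clahe`): CLAHE with clip limit
  0.01, applied volumetrically or slice-wise. Deep tissue is dimmer
  than the surface; adaptive equalisation keeps the contour from
  leaking where the signal fades.
- **Smoothing** (`smooth_gaussian`): Gaussian blur with sigma given in
  μm and converted per-axis to voxels.
- **Region restriction** (`crop_elliptic_cylinder`): zeroes intensity
  outside an elliptic cylinder around the apex, removing neighbouring
  organs that would otherwise join the contour.

## 2. Tissue contour (`samsurf.contour`)

The tissue solid is segmented with the morphological Chan-Vese active
contour (ACWE) from scikit-image (default 60 iterations, smoothing 1,
initialised from an Otsu threshold). ACWE needs no gradient and is
robust to the dim interior. If ACWE degenerates (empty or full mask) an
Otsu threshold is used as fallback (`contour_with_fallback`).

Mask repair before meshing:

- `fill_xy_holes`: per-slice binary hole filling, closing interior
  cavities that would create spurious inner surfaces;
- `extend_to_base`: extends the solid downward to the bottom of the
  stack so the mesh has a single open rim at the base rather than a
  closed bag.

## 3. Surface mesh (`samsurf.mesh`)

- **Extraction** (`extract_mesh`): the binary mask is smoothed with a
  Gaussian (sigma 1 voxel) and triangulated with the Lewiner marching
  cubes at iso-level 0.5. Axes are swapped from `(z, y, x)` voxel order
  to `(x, y, z)` world coordinates; this parity change makes the
  descent winding point outward without an extra flip.
- **Simplification** (`simplify_mesh`, default fraction 0.1): ACVD-style
  uniform remeshing — geodesic Voronoi clustering of vertices
  (multi-source Dijkstra, Morton-ordered seeds for an even spread)
  with Lloyd relaxation (8 iterations), then one vertex per cluster and
  re-triangulation from cluster adjacency. This yields the
  near-uniform vertex density the cotangent curvature and the
  unit-weight centroids assume.
- **Cleanup** (`clean_mesh`): merges duplicate vertices, drops
  degenerate faces, keeps the largest connected component.
- **Rim erosion** (`erode_boundary`, default 4 rings on the dense
  mesh): removes topological rings of vertices at the open boundary by
  breadth-first expansion. ACWE's curvature smoothing rounds the cut
  edges of the solid, so the reconstructed surface droops by several μm
  within a few voxels of the rim; measurements showed the artefact is
  confined to roughly 3–4 voxel rings, and eroding them removed a ~27%
  bias in downstream curvature fits.
- **Base clip** (`clip_base`): removes vertices below a z-margin above
  the stack floor (default twice the voxel spacing), discarding the
  artificial base produced by `extend_to_base`.
- **IO**: minimal in-house PLY (binary little-endian, with per-vertex
  scalar properties), VTP (XML PolyData) and OBJ writers, plus a PLY
  reader. These avoid heavyweight VTK dependencies.

## 4. Mean curvature (`samsurf.curvature`)

Per-vertex mean curvature uses the cotangent Laplacian with mixed
Voronoi areas: `H = sign · |Δx| / 2`, signed by the direction of the
Laplacian relative to the vertex normal, so convex bumps are positive.
At open-mesh boundaries the one-ring is incomplete and the formula is
unreliable; boundary vertices instead take the mean of their interior
neighbours' values (`_extrapolate_boundary`).

The raw field is conditioned (`prepare_curvature`) by a cascade:

1. **Truncation** to [−0.1, 0.1] μm⁻¹: caps spikes from slim triangles.
2. **Sign-gated min-max filter** (2 synchronous iterations):
   non-negative vertices take the maximum over their closed one-ring,
   negative vertices the minimum. This widens curvature plateaus so
   each organ carries a single attractor instead of a cluster.
3. **Neighbourhood smoothing** (20 iterations of closed one-ring
   averaging): removes the remaining voxel-scale ripple.

## 5. Organ segmentation (`samsurf.segmentation`)

**Attractors** (`attractor_segmentation`): every vertex hill-climbs to
its strictly-greater neighbour of highest value (ties broken toward the
lowest vertex index); local maxima are attractors and their basins are
the initial domains. The implementation vectorises the climb with
pointer jumping over a CSR adjacency, and is tested against a
brute-force per-vertex oracle including injected ties.

**Inflorescence identification** (`identify_inflorescence`): a vertical
ray is cast from the tissue centre of mass; the domain owning the hit
face is the inflorescence meristem. If the ray misses (strongly tilted
apices), the fallback is the domain with the most neighbouring domains.
The ray test is an in-house 2D point-in-triangle projection
(`vertical_ray_hits`), avoiding a spatial-index dependency.

**Merge cascade** — the inflorescence is identified *before* merging and
is protected from being absorbed; merges touching it instead absorb the
other domain. Rules run in a configurable order, default:

1. **Depth** (threshold 0.01 μm⁻¹): a domain whose attractor value
   exceeds its highest saddle to a neighbour by less than the threshold
   is merged into that neighbour — removes noise-level basins.
2. **Engulfed** (fraction default 1.0, strict `>` — i.e. disabled by
   default): a domain with more than the threshold fraction of its
   border shared with a single neighbour merges into it. The default
   disables the rule because a flower domain entirely surrounded by the
   meristem is a legitimate configuration, not an artefact; lower the
   fraction to enable it.
3. **Disconnected** (fraction default 0.05): a non-inflorescence domain
   whose border with the inflorescence is less than the threshold
   fraction of its total inter-domain border is merged into the
   neighbour with which it shares the largest border. The denominator
   counts only vertices bordering *other domains* — rim vertices say
   nothing about connectivity. The rule targets peripheral spurious
   domains that do not touch the meristem at all, so the default is a
   small tolerance for incidental contact rather than a large fraction.
4. **Distance** (threshold 10 μm): attractors closer than the threshold
   merge — splits of a single primordium.
5. **Angle** (threshold 20°): domains whose attractors subtend less
   than the threshold at the dome apex merge — radial splits of one
   organ.

## 6. Paraboloid dome fit (`samsurf.paraboloid`)

The inflorescence dome is parameterised by
`z = p1·x² + p2·y² + p3·x + p4·y + p5`, linear in its parameters, so
the least-squares fit is a closed-form `lstsq` (rank-checked, ≥5
points). Derived quantities:

- **Apex**: the stationary point
  `(−p3/(2p1), −p4/(2p2), z(·))`.
- **Gaussian-curvature proxy**: `p1·p2`, a tissue-level dome curvature.
- **Curvature ratio**: `p1/p2` (literal) and
  `max(|p1|,|p2|)/min(|p1|,|p2|)` (normalised) — dome asymmetry.
- **Fit quality** (`fit_distance`): the paraboloid is sampled as a mesh
  over the data's xy bounding box and closest-point distances are
  averaged.

## 7. Phenotypes (`samsurf.phenotype`)

- **Organ features** (`organ_features`): per-domain surface area
  (summed face areas, faces weighted by vertex membership), curvature
  median and standard deviation, distances to a reference point (mean
  and max), unit-weight vertex centroid and its azimuth about the apex.
- **Ordering** (`OrderingFile`): phyllotactic indices are assigned
  manually in practice; the ordering file maps organ label →
  contiguous index from 0 (oldest first) and records the spiral
  direction.
- **Divergence angles** (`divergence_angles`): azimuth differences of
  consecutive organ centroids about the dome apex, wrapped to [0, 360)
  in the spiral direction; `divergence_sd` is the RMS deviation from
  the golden angle 137.5° with wrap-around.
- **Reporter apex** (`clv3_apex`): centre of mass of voxels strictly
  above a quantile threshold, walking a ladder (99.99%, 99.9%, 99%)
  until a non-empty set is found — robust to saturated or sparse
  reporter signal.
- **Apex comparison** (`apex_comparison`): pairwise distances between
  the reporter centre of mass, the paraboloid apex and the mesh centre
  of mass, plus their projections along the dome axis onto the mesh.
- **Resolution benchmark** (`resolution_benchmark`): downsamples the
  stack along z or xy by given factors, reruns the surface pipeline,
  and reports mean closest-point distance to the full-resolution mesh.

## 8. Statistics (`samsurf.stats`)

Mann-Whitney-Wilcoxon (`mww_test`), exact when the combined sample size
is ≤ 12 and tie-free, otherwise the normal approximation with tie
correction; Bonferroni multiplication capped at 1. Star annotation
(inclusive bounds): ≤ 10⁻⁴ `****`, ≤ 10⁻³ `***`, ≤ 10⁻² `**`,
≤ 0.05 `*`, otherwise `ns`.

## 9. Synthetic generator (`samsurf.synthetic`)

Ground-truthed apices for validation: a paraboloid dome plus Gaussian
primordium bumps. `golden_spiral_spec(k)` places bump `j` at azimuth
`j·137.5°` and radius `40 + 5·j` μm (a true spiral — older primordia
sit further out; a constant-radius ring of many bumps would seal the
dome off from the periphery and is degenerate). `make_apex_volume`
renders the height field into a voxel solid with additive Gaussian
noise and returns the analytic height function and a truth labeller
(nearest bump within two widths, else dome). `make_apex_mesh`
triangulates the height field directly with per-vertex truth labels,
bypassing the imaging stage.

## 10. Pipeline and configuration (`samsurf.pipeline`)

`PipelineConfig` is a dataclass covering every stage parameter, with
YAML round-trip (unknown keys rejected) and a content hash recorded in
the output manifest. `run_pipeline` processes a batch of plants —
stack paths, in-memory volumes, or precomputed masks — writing per
plant a PLY and VTP mesh with curvature and label scalars, paraboloid
and organ CSV tables, plus `manifest.json` and `config.yaml`; failures
are recorded per plant without aborting the batch.

## Numerical and design notes

- Problem sizes in the examples and tests (stacks of ~10⁵–10⁶ voxels,
  meshes of 10³–3·10⁴ vertices) are chosen so the full validation suite
  runs in minutes on a laptop; all algorithms are vectorised and scale
  to realistic stacks.
- Organ centroids are unit-weight vertex means. On a watershed
  segmentation the basin boundaries bisect the inter-organ gaps, and
  because golden-angle gaps are unequal this biases centroid azimuths
  by up to ~(gap difference)/4 (≈ 8° for five organs). Divergence-angle
  validation therefore uses generator truth labels; on real data the
  same effect bounds the accuracy of centroid-based angles.
- No self-intersection repair is attempted; the 2.5D assumption (one
  surface point per xy position over the apex) makes intersections rare.
- The exact MWW permutation count grows combinatorially; the n ≤ 12
  cutoff keeps it instant while matching the asymptotic branch well
  beyond it.
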