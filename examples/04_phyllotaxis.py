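"""Extract divergence angles from an ordered organ segmentation.

Organ ordering is manual in practice (an ordering file maps each organ
label to its phyllotactic index and gives the spiral direction); here the
generator's ground-truth labels and ordering stand in for it.  The
divergence angle between consecutive organs of a wild-type spiral should
cluster at the golden angle, 137.5 degrees.
"""

import numpy as np

from samsurf import (
    GOLDEN_ANGLE,
    OrderingFile,
    Segmentation,
    apex,
    divergence_angles,
    divergence_sd,
    fit_paraboloid,
    golden_spiral_spec,
    make_apex_mesh,
    organ_features,
    prepare_curvature,
)

k = 8
spec = golden_spiral_spec(n_bumps=k, noise_sigma=0.0)
mesh, truth = make_apex_mesh(spec, resolution=1.0)

seg = Segmentation(truth.copy())
seg.inflorescence_label = 0
ordering = OrderingFile({b + 1: b for b in range(k)}, "counterclockwise")

field = prepare_curvature(mesh)
dome_apex = apex(fit_paraboloid(mesh.vertices[truth == 0]))
organs = organ_features(seg, mesh, field, reference=dome_apex, ordering=ordering)

angles = divergence_angles(organs, dome_apex, ordering.spiral_direction)
print(f"divergence angles (deg): {np.round(angles, 2)}")
print(f"golden angle: {GOLDEN_ANGLE} deg")
print(f"max |deviation|: {max(abs(a - GOLDEN_ANGLE) for a in angles):.3f} deg")
print(f"sd around golden angle: {divergence_sd(angles):.3f} deg")
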