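"""Fit the 5-parameter paraboloid to an inflorescence dome.

The dome model z = p1 x^2 + p2 y^2 + p3 x + p4 y + p5 is linear in its
parameters, so the least-squares fit is closed-form.  Derived phenotypes:
the apex (stationary point), the tissue-level Gaussian curvature p1*p2,
and the principal-curvature ratio measuring dome asymmetry.
"""

import numpy as np

from samsurf import (
    Paraboloid,
    PipelineConfig,
    SyntheticApexSpec,
    apex,
    curvature_ratio,
    fit_distance,
    fit_paraboloid,
    gaussian_curvature,
    make_apex_volume,
    reconstruct_surface,
)

true = Paraboloid(-0.015, -0.008, 0.2, -0.1, 42.0)
spec = SyntheticApexSpec(dome=true, spacing=1.0, noise_sigma=0.05, seed=11,
                         xy_halfwidth=30.0)
volume, _, _ = make_apex_volume(spec)
mesh = reconstruct_surface(volume, PipelineConfig(target_spacing=1.0, acwe_iterations=60))

fit = fit_paraboloid(mesh.vertices)
print("         p1        p2        p3        p4        p5")
print("true ", "  ".join(f"{v:+.5f}" for v in true.params))
print("fit  ", "  ".join(f"{v:+.5f}" for v in fit.params))

ax, ay, az = apex(fit)
K = gaussian_curvature(fit)
ratio = curvature_ratio(fit)
_, mean_dist = fit_distance(mesh, fit)
print(f"apex: ({ax:.2f}, {ay:.2f}, {az:.2f}) um")
print(f"Gaussian curvature p1*p2: {K:.3e} (truth {gaussian_curvature(true):.3e})")
print(f"curvature ratio (asymmetry): {ratio['normalised']:.3f}")
print(f"mean mesh-to-fit distance: {mean_dist:.3f} um")
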