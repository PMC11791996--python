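"""Fit the left-heart template to surface targets from a known warp.

Builds the idealized template, deforms it by a seeded smooth diffeomorphic
warp (the ground truth), samples target point clouds from the warped
surfaces, and recovers the deformation by minimizing the combined
chamfer + distortion + surface-regularizer objective.
"""

import valvemesh as vm
from valvemesh.quality import evaluate_mesh

spec = vm.FixtureSpec(seed=1)
template = vm.make_template(spec)
_, warped = vm.make_synthetic_warp(spec, template)

targets = {name: vm.sample_component_surface(warped, name, 1500,
                                             return_normals=True)
           for name in template.component_names}

pre = evaluate_mesh(template, warped, 1500).aggregate()
result = vm.fit_mesh_to_surfaces(template, targets,
                                 sim_iters=100, warp_iters=400)
post = evaluate_mesh(result.fitted_mesh, warped, 1500).aggregate()

print(f"chamfer before fit : {pre['cd_mm']:.3f} mm^2")
print(f"chamfer after fit  : {post['cd_mm']:.3f} mm^2 "
      f"({100 * (1 - post['cd_mm'] / pre['cd_mm']):.1f}% reduction)")
print(f"inverted elements  : {int(post['n_negative_jacobian'])}")
print(f"mean scaled Jacobian: {post['scaled_jacobian_mean']:.3f}")
# The chamfer numbers are component-weighted symmetric squared nearest-
# neighbour distances (halved); zero inverted elements confirms the
# diffeomorphic deformation kept every hexahedron valid.
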