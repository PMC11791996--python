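"""Two-stage segmentation-driven registration.

Rasterizes a warped template into five soft occupancy maps (the stand-in
for predicted multilabel segmentations), then runs the conventional
pipeline: similarity registration under an LV-weighted Dice loss, followed
by diffeomorphic b-spline refinement under Dice + bending + edge losses.
"""

import valvemesh as vm
from valvemesh.quality import evaluate_mesh

spec = vm.FixtureSpec(seed=2)
template = vm.make_template(spec)
_, warped = vm.make_synthetic_warp(spec, template)

lattice = vm.fixture_lattice(template, spacing_mm=1.25, margin_mm=10)
pred = vm.rasterize_mesh(warped, lattice)

sim = vm.fit_similarity_to_labels(template, pred, iters=300)
result = vm.fit_nonrigid_to_labels(template, pred, sim,
                                   iters=300, warm_start_iters=800)

pre = evaluate_mesh(template, warped, 1500).aggregate()["cd_mm"]
post = evaluate_mesh(result.fitted_mesh, warped, 1500).aggregate()["cd_mm"]
print(f"similarity scale recovered : {sim.scale.round(4)}")
print(f"chamfer before/after       : {pre:.3f} / {post:.3f} mm^2 "
      f"({100 * (1 - post / pre):.1f}% reduction)")
print(f"final loss breakdown       : "
      + ", ".join(f"{k}={v:.4f}" for k, v in result.breakdown.items()))
# Dice is the data term; bending and edge-length terms keep the b-spline
# velocity smooth and the mesh edge-length ratios close to the template's.
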