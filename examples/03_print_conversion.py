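"""Convert simulation components to watertight 3D-printable surfaces.

Runs the stencil -> SDF -> offset -> isosurface -> remesh -> smooth chain
for a leaflet (thickened to the printer minimum) and a calcification mask,
and writes binary STL files.
"""

import os

import valvemesh as vm
from valvemesh.printing import (component_surface_trimesh, convert_component,
                                measure_thickness, watertight_check)

spec = vm.FixtureSpec()
template = vm.make_template(spec)
os.makedirs("scratch", exist_ok=True)

leaf_surface = component_surface_trimesh(template, "leaflet1")
leaf = convert_component("leaflet", surface=leaf_surface,
                         target_thickness_mm=0.6, native_thickness_mm=0.9)
report = watertight_check(leaf.mesh, check_self_intersections=False)
print(f"leaflet: watertight={report.watertight}, "
      f"thickness={measure_thickness(leaf.mesh, 300):.2f} mm "
      f"(target {leaf.target_thickness_mm} mm), "
      f"{len(leaf.mesh.faces)} triangles")
leaf.export_stl("scratch/leaflet1.stl")

calc = vm.make_calcification(spec, template)
part = convert_component("calcification", segmentation=calc)
print(f"calcification: watertight={part.watertight}, "
      f"volume={part.mesh.volume:.1f} mm^3 "
      f"(voxel volume {calc.grid.values.sum() * 0.33**3:.1f} mm^3)")
part.export_stl("scratch/calcification.stl")
# Watertightness (every edge shared by exactly two faces, consistent
# winding) is the printability requirement; measured thickness is the
# ray-cast median wall thickness.
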