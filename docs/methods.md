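# Methods

## Problem and model

`valvemesh` reconstructs simulation-ready meshes of the calcified aortic
valve and left heart by template deformation: a fixed-topology reference
mesh — an LV myocardium modeled purely as a triangular surface shell, an
aortic wall as a hexahedral solid, and three valve leaflets as hexahedral
blocks with exactly three element layers through the thickness — is warped
onto patient-specific targets.  Because only node positions change, node
correspondence is guaranteed across patients and cardiac phases, which is
what makes downstream motion interpolation and multi-part 3D printing
tractable.

The deformation model has two parts, composed in a fixed order:

1. a similarity transform (axis-angle rotation, translation, anisotropic
   per-axis scaling about a fixed centre);
2. a stationary velocity field parameterized by cubic b-spline coefficients
   on a control lattice with isotropic spacing of 3 voxels of the reference
   grid, exponentiated by scaling and squaring (6 halvings, then 6
   self-compositions).  The exponential of a smooth stationary velocity is
   a diffeomorphism, so the displacement has positive Jacobian determinant
   everywhere and cannot fold mesh elements.

## Fitting objectives

**Surface-target fitting** minimizes, over the similarity parameters and
the control velocities,

    mean_n L_chamfer,n + 1·L_ARAP + 10·L_ASqrt + 10·L_normal + 10·L_lap + 1·L_edge

with per-component chamfer distance (symmetric mean squared
nearest-neighbour distance) as the data term; as-rigid-as-possible
distortion `mean_k ||F_k − R_k||²_F` over all solid elements (F from a
least-squares fit of centroid-referenced corner vectors, R its
special-orthogonal polar factor); the anisotropic square-root stretch
penalty `mean_k (||F_k d_k|| − 1)²` along each element's thickness
direction d_k; and surface regularizers (normal consistency, uniform
Laplacian smoothness, edge-length-ratio correspondence) on the LV shell.

Two operational choices matter for accuracy and are deliberate:

* **Point-to-plane data term during optimization.** The mesh→target leg of
  the chamfer residual is projected onto the target point's surface
  normal.  Against a *discrete* target point cloud, the raw point-to-point
  form has spurious minima in which nodes lock tangentially onto
  individual sample points, which distorts the surface at the scale of the
  sampling distance.  Projection removes the tangential component; the
  evaluation metric (reported chamfer) is always the plain printed form.
* **Preservation forms of the surface smoothness terms.** In the combined
  objective, normal consistency and Laplacian smoothness enter as squared
  *changes* relative to the template (change of adjacent-face normal
  agreement; change of uniform Laplacian coordinates).  The absolute forms
  are nonzero for any curved template, so their gradients at the identity
  deformation shrink or inflate the shell even when the targets are the
  template itself; the preservation forms are exactly zero at the identity,
  as a template-deformation regularizer must be, and reduce to the absolute
  forms for a flat reference.  The absolute forms remain available as
  standalone energies (and drive the two-phase merge, where absolute
  smoothing of the transition band is precisely the goal).

**Segmentation-driven two-stage registration** fits the template to five
potentially overlapping soft occupancy maps.  A similarity stage minimizes
a component-weighted soft Dice loss (LV weighted 5:1 so the largest
structure anchors the pose) with separate Adam optimizers for scale,
rotation and translation at learning rates 0.1, 0.1 and 1.  The non-rigid
stage minimizes uniform-weight Dice + 1e-2·bending energy + 1·edge-length
correspondence over the control velocities with Adam at learning rate 1e-2.

The template is coupled to the voxel lattice by a differentiable
rasterization: each component is covered by deterministic volume-weighted
sample points (regular sub-lattices per hexahedron; barycentric subdivision
with a nominal one-voxel thickness for the LV shell), splatted trilinearly
and clipped to [0, 1].  Deposited volumes are transported with the local
Jacobian determinant of the deformation, so occupancy density is invariant
under the warp and the Dice term cannot profit from spurious compression.
The gradient includes the transport path (a divergence-form adjoint of
d det(I + ∇u)/du); without it the omitted term leaves a residual
compression force that is not a descent direction and the optimizer drifts
uphill after converging.

**Warm start from isosurfaces.** Voxelized occupancy labels carry only
limited sub-voxel information, so the Dice objective has shallow spurious
optima around thin structures (the one-voxel LV shell, the 0.9 mm
leaflets).  The non-rigid stage therefore first fits the template to the
0.5-level isosurface point clouds of the predicted occupancies using the
full surface+distortion objective above, then refines with the Dice
objective.  Initialized near the geometry-faithful optimum, the Dice
descent stays in that basin (verified by holding experiments); from a zero
field it reliably converges to a reshaped solution with better Dice but
0.3–0.5 mm worse geometry.

## Numerical choices

* Velocity fields are integrated and gradients pulled back on a lattice
  decimated to the control spacing (the continuous field is identical;
  evaluation is ~27× cheaper).  Displacements are sampled with cubic
  interpolation on this lattice; the returned mesh is warped with exactly
  the displacement the optimizer evaluated.  The positive-Jacobian check of
  the final field runs at full lattice resolution.
* Gradients with respect to the control velocities use the first-order
  approximation d exp(v)/dv ≈ identity (standard stationary-velocity
  practice); losses are always *evaluated* through the full integration.
* All energy gradients are hand-derived and verified against central finite
  differences in the test suite.  The ARAP gradient uses the exact identity
  d||F − R(F)||²/dF = 2(F − R) (the polar-factor variation drops out).
* Adam (reimplemented in NumPy) with cosine learning-rate decay to ~2% of
  the base rate; parameter-recovery then settles to sub-voxel optima
  instead of jittering at a constant step.  The best-loss iterate is
  returned.  In the segmentation route, the control-lattice gradient is
  Gaussian-smoothed early in the schedule (annealed away by 60% of the
  iterations) to extend the capture range on thin structures.
* Bending energy uses central second differences with one-sided stencils at
  the boundary (exact for quadratics everywhere); mixed terms are doubly
  weighted.  Any globally affine field has exactly zero bending energy.
* Iteration counts at desk scale: similarity 300–500, isosurface warm start
  400–800, Dice refinement 300, surface-target fitting 400 (defaults are
  larger, with early stopping at 1e-6 relative loss change over a
  60-iteration window).  Registration label lattices default to 1.25 mm
  isotropic, the working resolution of the imaging pipeline the package
  mirrors.

## Print conversion

Simulation meshes become printable parts through a voxelgrid
signed-distance route: a dense deterministic surface sampling marks crossed
voxels, the exterior is flood-filled, boundary voxels are classified by the
nearest-sample normal, and the Euclidean distance transform gives the SDF
(corrected to near-exact point-cloud distances in a 2.5-voxel band, which
removes the half-voxel quantization of the binary stencil).  Isosurfaces at
a chosen level offset the surface to control thickness: leaflets are
thickened (or thinned) symmetrically to the printable target (default
0.6 mm minimum; requests below it are raised with a warning), walls become
shells between the inner surface and its outward offset (default 1.3 mm),
calcification is meshed at its native 0.33 mm grid.  Remeshing re-extracts
the surface from its own SDF at a resolution tuned to the requested vertex
count (watertight by construction); smoothing is Taubin λ/μ (bounded
shrinkage).  Marching cubes uses linear interpolation (deterministic).

The two-phase merge joins the systolic aorta to the diastolic LV: the
facing open rims are zipper-stitched by angular order, vertices within a
5 mm surface-geodesic band of the junction deform freely (Adam, lr 1e-3),
and each side otherwise moves as a rigid body (Adam, lr 3e-2) under
10·normal consistency + 1·Laplacian + 10·edge-length correspondence.  Edge
rest lengths for the synthetic band triangles are set to the rim's mean
edge length — the length they would have if the rims were already mated —
which is what lets the optimization close a lateral gap instead of
preserving it.

## Quality metrics and statistics

Reported chamfer is the symmetric squared-distance form halved (the
double-count normalization); a root-mean-square variant in plain mm is
available behind a flag since the squared form's unit is mm².  Scaled
Jacobian is the minimum normalized corner-frame determinant over the eight
hexahedron corners (1 for any rigidly moved, uniformly scaled cube;
negative for inversions); skew is the maximum absolute cosine between
normalized principal axes (0 for a cube).  Per-component metrics aggregate
by point/element-count weights.  Paired two-sided t-tests compare mesh
sets patient-by-patient; zero-variance nonzero differences report t = ±∞,
p = 0 rather than failing.

## Synthetic fixtures: what they do and do not show

The generator produces an idealized left heart: an ellipsoidal LV shell
(22×22×30 mm semi-axes), a cylindrical aortic wall (lumen radius 11 mm,
wall 2 mm, length 26 mm), and three 120°-sector leaflets (0.9 mm thick,
0.3 mm per layer) with per-element thickness directions — chosen for
analytic ground truth, not realism.  Ground-truth warps are seeded smooth
control-lattice velocities (6-voxel spacing, i.e. coarser than the fitting
lattice), integrated and scaled so the maximum template-node displacement
equals the requested amplitude (3 mm default); the warped template is
guaranteed inversion-free.  Occupancy maps are sharp per-voxel coverage
fractions (volume-unbiased); a trilinear-splat convention matching the
fitting forward model is available.  The cine applies periodic radial LV
contraction (30% linear, i.e. an ejection fraction of 1 − 0.7³ ≈ 65.7%)
with a leaflet opening modulation.  Calcification is seeded ellipsoidal
blobs (1.2–2.2 mm radii) attached to leaflet surfaces at 0.33 mm spacing.

Passing recovery tests on these fixtures shows that the objectives,
deformation model and optimizers recover smooth, representable warps from
clean targets at desk scale.  It does not show robustness to segmentation
error, image noise, topology mismatch between template and anatomy, or
pathology outside the template's shape space.

Two scale-dependent caveats.  First, recovery is measured as *relative*
chamfer reduction; warps whose maximum displacement is concentrated in a
small region have small pre-fit error, and a fixed relative threshold then
demands absolute accuracy beyond the information content of voxelized
labels (~a quarter voxel for thin shells).  In the bundled suite the
segmentation-driven route reaches ≥85% reduction on four of five seeds and
~74% on one such concentrated warp, at an absolute accuracy of ≤0.19 mm²
in every case; the surface-driven route reaches ≥85% on all five.  Second,
the fixture is smaller than adult anatomy, which raises surface curvature
and with it the pressure the smoothness regularizers exert at a given
weight.

## Known limitations

* No multi-resolution deformation pyramid and no time-varying velocity
  fields; each cine frame is fit independently.
* Self-intersection counting is a brute-force candidate-pair scan intended
  for fixture-scale meshes; coplanar overlaps are not detected.
* The smooth rasterization assumes approximately isotropic, axis-aligned
  label lattices (the NIfTI affines produced by the resampling step).
* The effective orifice area helper projects the leaflet free-edge polygon
  onto the annulus plane — an anatomic interpretation, not a hemodynamic
  (flow-derived) EOA.
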