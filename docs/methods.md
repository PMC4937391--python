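# Methods

`retractsim` simulates the surgical retraction of soft brain tissue: two
blades inserted along a fissure open a V-shaped path, creating a topological
discontinuity (a crack) and displacing the surrounding parenchyma.  The
package computes the resulting volumetric deformation field from tracked
blade-surface displacements and uses it to update the pre-retraction image,
so that image-guided navigation remains aligned with the deformed anatomy.

## Constitutive model

Brain parenchyma is modelled as a one-term Ogden hyper-viscoelastic solid.
The instantaneous strain energy in principal stretches λᵢ is

    W = (2 μ₀ / α²) (λ̄₁^α + λ̄₂^α + λ̄₃^α − 3) + (K/2)(J − 1)²,

with λ̄ᵢ = J^(−1/3) λᵢ the isochoric stretches, μ₀ the instantaneous shear
modulus, α a sign-free exponent, and a quadratic volumetric penalty.
Stress relaxation follows the Prony series

    μ(t) = μ₀ (1 − Σₖ gₖ (1 − e^(−t/τₖ))),

applied to the isochoric part of the second Piola–Kirchhoff stress via
internal variables with the standard exponential recursion (exact for a
piecewise-linear stress path inside each increment); the bulk response does
not relax.  Default parameters are the swine-brain values μ₀ = 842 Pa,
α = −4.7, (τ₁, g₁) = (0.5 s, 0.450), (τ₂, g₂) = (50 s, 0.365), so the
long-term/instantaneous modulus ratio is 1 − g₁ − g₂ = 0.185.

Only shear parameters are available for brain tissue, so compressibility is
a modelling choice: the bulk modulus comes from an equivalent Poisson ratio
(default ν = 0.49, near-incompressible but numerically benign); it is
exposed in the `material:` config block.  A Saint-Venant linear-elastic
material implements the same interface as a comparison plug-in.

Internal stress computations use PK2; Cauchy stress is obtained by
push-forward for reporting, which fixes the convention tests rely on.
The consistent material tangent dS/dC is computed by one batched
forward-difference sweep of the elastic stress parts (step 10⁻⁷ × |C|);
the Prony recursion is linear in the isochoric stress, so its contribution
enters through a closed-form scalar weight.  The result is symmetrised to
the major symmetry the energy Hessian possesses and agrees with central
finite differences of the residual to better than 10⁻⁴ (verified in tests).

## Mesh and crack representation

The organ mask is meshed with a uniform axis-aligned hexahedral grid
(octree-style, refined uniformly to the first level whose edge is ≤ the
requested size, default < 5 mm): this reproduces the uniform meshes used in
the intended application and makes every element share one parent geometry.
A cell is kept when at least one masked voxel centre falls inside it
(threshold configurable).  Voxel indices are 0-based and voxel-centred;
world coordinates are millimetres via the image affine.

The crack is carried by two level sets: φ (signed distance normal to the
crack surface) and ψ (signed distance ahead of the crack front); the crack
is {φ = 0, ψ ≤ 0}.  Planar cracks (plane plus optional planar front) cover
the retraction geometry; an arbitrary callable (φ, ψ) pair can be supplied
for non-planar surfaces.  Nodal level-set values within 10⁻⁶ × edge of zero
are shifted to +10⁻⁶ × edge — the standard guard against degenerate cuts;
this makes a crack coincident with a mesh face well-posed rather than an
error.

Elements whose nodal φ changes sign are *cut* when the crack extends past
them (all nodal ψ ≤ 0) and *tip* elements when the front lies inside.
Heaviside DOFs (aⱼ, 3 per node) are attached to the nodes of cut elements,
tip DOFs (b_m^l, 12 per node: four branch functions × 3 components) to the
nodes of tip elements; a through-going crack — the default, matching blades
inserted fully across the exposed region — has no tip set.  Total DOFs are
3|I| + 3|J| + 12|M|.

## XFEM discretisation and solver

The displacement field is the three-term XFEM expansion over trilinear hex
shape functions with the *shifted* enrichment basis (nodal enrichment value
subtracted), so standard DOFs keep their interpolation meaning at nodes and
crack-face boundary conditions stay expressible.  The four crack-tip branch
functions are the usual √r {sin θ/2, cos θ/2, sin θ/2 sin θ, cos θ/2 sin θ}
with θ = atan2(φ, ψ).  In blending elements ahead of a crack front the
Heaviside basis introduces the well-known transition approximation; through
cracks — the default retraction configuration — have no such elements.

Quadrature: 2×2×2 Gauss for uncut hexes; cut hexes are split into 6
tetrahedra, each tetrahedron is cut by the φ = 0 plane into one-sided
sub-tetrahedra (all pieces convex with planar faces, so the staircase
prism split is exact), and a 4-point rule is applied per sub-tet.

Boundary conditions are of two kinds: zero displacement in the brain-stem
region (all DOFs of those nodes, enriched ones included) and prescribed
crack-face displacements.  For a Heaviside node with face values u⁺, u⁻ the
jump DOF is constrained to aⱼ = (u⁺ − u⁻)/2 and the standard DOF to the
value on the node's *own* side of the crack — under the shifted basis this
reproduces both face values exactly, whereas the mean (u⁺ + u⁻)/2 would be
exact only for the unshifted convention.  Prescribed DOFs are imposed by
elimination, so they are satisfied to machine precision.

The quasi-static problem (internal forces only; the remaining surface is
traction-free) is solved by ramping the prescribed displacements over a
pseudo-time schedule — default 30 s in 10 increments, chosen so that both
Prony arms participate; T = 0 gives the instantaneous response — with full
Newton iterations per increment: relative residual tolerance 10⁻⁶ against
the increment's force scale (free residual or boundary-reaction norm,
whichever is larger), absolute 10⁻¹⁰ N, backtracking line search on
divergence.  Each linearised system is solved by GMRES preconditioned with
an LU factorisation that is refreshed only when the Krylov solve degrades;
a secant predictor extrapolates the previous two increments' solutions,
which reduces most increments to one or two Newton iterations.  Assembly is
vectorised: uncut elements share one parent-space gradient table and are
processed in stacked batches; enriched elements carry precomputed,
state-independent basis/quadrature tables.

## Boundary conditions from retractor tracking

The scanned retractor surface is extruded by the blade thickness (2.9 mm)
along its normals to reach the tissue-contact face.  Pre- and
post-retraction clouds are registered with coherent point drift (CPD): the
standard EM over a Gaussian mixture with a uniform outlier weight
(w = 0.1), rigid and affine modes.  The affine M-step is initialised from a
converged rigid pass — this guards against the shrinkage collapse the
affine update suffers under broad initial correspondences — and uses a
pseudo-inverse of the weighted scatter so planar clouds (blade faces) are
handled.  Registering one featureless plane onto another is fundamentally
ambiguous (the aperture problem), and flat-bladed phantoms exhibit exactly
that; the synthetic blades therefore carry a mild surface curvature
(0.35 mm default), as real scanned blades do.

Per-point displacements (matched position − source position) are
transferred to the crack-face nodes of elements containing cloud points by
inverse-distance weighting (power 2) after projecting the nodes onto the
crack surface — node-to-blade distance is otherwise dominated by the
off-surface offset.  The influence radius defaults to the element edge;
every selected node must be covered.  Nodes whose projection sits at the
edge of the blade patch inherit a boundary-extrapolation error of order
(taper rate × pitch); interior nodes reproduce the true face displacements
to the registration accuracy.

## Image update

The solved field is rasterised to a per-voxel displacement with each voxel
centre evaluated on its own side of the crack (voxels outside the mesh get
zero).  The predicted post-retraction image is produced by backward
mapping: each output voxel pulls intensity from its preimage under the
forward map, recovered by fixed-point iteration (5 iterations, tolerance
0.01 mm).  Voxels whose forward-mapped preimage misses the target by more
than a gap tolerance (0.25 mm default) lie in the opened crack, have no
material preimage, and receive a configurable background intensity
(default: image minimum).  Trilinear interpolation near the crack is
side-masked — only source voxels on the same side of φ as the sampled
point contribute, with renormalised weights — so no intensity bleeds
across the discontinuity.  These choices (pull mapping, fixed-point
inversion, gap handling) are the package's own; published descriptions of
crack-aware back-interpolation do not fix them.

## Evaluation metrics

Per landmark: forecast error = ‖predicted − measured‖ (mm); prediction
accuracy = 100 (1 − forecast error / ‖measured − pre‖) %.  The denominator
choice is not unambiguous in the literature this mirrors, so the predicted
displacement is available behind a switch; landmarks with zero measured
displacement are flagged and excluded from means.  Dice similarity
coefficient = 200 |A∩B| / (|A| + |B|) %; target registration error is the
per-landmark distance between two aligned images' landmarks.  Summaries use
the sample SD (n − 1; configurable) and report one decimal, rounded
half-up, keeping full precision internally.  The published seven-subject
study tables ship as package data so their aggregates (mean/max Dice
88.9 / 94.5 %, mean initial/updated TRE 2.3 / 1.1 mm, mean/max per-subject
forecast error 0.4 / 0.8 mm, minimum per-subject accuracy 71.5 %) are
recomputed, not transcribed, at evaluation time.

## Synthetic phantom

No in-vivo data are distributed, so a deterministic phantom generates every
input at the study's conditions: an ellipsoidal brain-like mask (default
semi-axes 28 × 22 × 18 mm on a 1 mm grid — swine scale, meshing to ~900
nodes at 5 mm, within the 2 018–4 622 node range of the application), a
vertical through crack slightly off the mesh symmetry plane, two 14 mm wide
and 2.9 mm thick blades inserted 15 mm from the top, V-opening with maximum
displacements 5.4 mm (right) and 2.8 mm (left) tapering linearly to zero at
the blade tip, pre/post blade clouds at 1 mm pitch with the curvature noted
above, and 14 bead landmarks (1.5 mm diameter, choosable 11–20) in three
lobe-like clusters, kept 1.5 mm clear of the crack.  All randomness flows
from one seed; identical configs are bitwise-reproducible.

"Measured" post-retraction bead positions and the reference mask come from
a fine-mesh solve (2.5 mm edge) driven by the same tracked boundary
conditions; coarse-mesh (5 mm) predictions are scored against them exactly
as the animal study scores against post-retraction CT.  What this does and
does not show: the phantom exercises discretisation error, the tracking
pipeline and the image update under known ground truth, but it shares the
constitutive model between truth and prediction, so it cannot probe model
error against real tissue, CT noise, segmentation error, or
registration-chain errors present in vivo.  Problem sizes (≈900 / 4 600
nodes) were chosen to mirror the application's mesh scale while keeping the
full pipeline in the minutes range on one CPU.

## Known limitations

- No contact or friction between crack faces: unloaded face regions may
  interpenetrate slightly.
- Tip enrichment is included and tested, but blending-element integration
  ahead of the front uses the standard (non-conforming) approximation.
- Ventricles, falx and the brain–skull gap are not modelled; the mesh is
  single-material.
- The affine CPD mode relies on surface structure; featureless planar
  clouds degrade to the aperture ambiguity discussed above.
- The brain-stem zero-displacement region is a geometric band in the
  phantom; in practice it is surgeon-selected.
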