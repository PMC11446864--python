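# Methods

This note documents the models and numerical choices behind `vrakit`:
what each stage computes, the defaults and why, what the synthetic
specimen generator emulates, and where the method's limits are.

## Working representation

All geometry is in millimetres.  Fragment meshes (STL/PLY) are reduced to
fixed-size point clouds before analysis (`subsample`, default 100 000
points, seeded; both area-weighted random and Poisson-disk-style
homogeneous modes are provided and the mode used should be reported —
density standardisation plausibly affects reconstruction accuracy).
Rigid motions are proper rotations plus translations, validated to SO(3)
at 1e−9 and closed under composition/inversion at that tolerance.

## CT segmentation

Bone is separated from soft tissue by a lower attenuation bound,
default **+300 HU** — above muscle/fat/fluid, below cortical and most
trabecular bone in standard CT; it is a configurable parameter, not a
calibration.  Segmentation is seeded region growing with 26-connectivity
(more permissive across thin cortical shells; 6-connectivity available).
Touching fragments are dissociated by *competitive* growth: all seeds
expand breadth-first simultaneously, each voxel claimed by the first
front to arrive, equidistant ties to the lower label index — a
deterministic, testable re-expression of an interactive "split" tool,
flagged as such in the mask provenance.  Label surfaces are extracted by
marching cubes at level 0.5 on the one-voxel-padded binary field; the
field is first smoothed with a 0.5-voxel Gaussian, which removes the
stair-step bias of binary iso-surfaces (a voxelized sphere's area is
otherwise ~8 % high; with anti-aliasing it is within ~4 %).  Labels too
small for the smoothed field to reach the iso-level fall back to the raw
binary field — a single isolated voxel therefore extracts as the
octahedron through its face-neighbour midpoints.

Fragment **length** is the largest extent along the principal axes of the
vertex set — rotation-invariant and closer to the anthropological notion
of length than a bounding-box diagonal.  The field-triage rule retains
fragments of length ≥ 20 mm.

## Fracture-surface extraction

Roughness of a point is its orthogonal distance to the least-squares
plane of its neighbours within a kernel radius, the query point excluded
from the fit (including it biases the value low).  Points with fewer than
three non-collinear neighbours get NaN, treated as below any threshold so
isolated outliers never enter a fracture surface.  The fracture surface
is the subset with roughness ≥ **1.0 mm** (threshold interpreted in cloud
units, i.e. mm — a documented assumption, exposed as a parameter).

The **kernel radius defaults to 5 mm**.  This choice is forced by a
geometric ceiling of the plane-fit definition: within a kernel disk of
radius *r* the in-plane variance is r²/4, so once the relief variance
exceeds it the fitted normal flips into the surface and the roughness
collapses; stable readings of relief with RMS amplitude *A* require
roughly r ≳ 3.3·A.  For mm-scale fracture relief (A ≈ 1.5 mm) a 2 mm
kernel can therefore never report values above ~1 mm, and 5 mm is the
smallest radius that resolves the 1.0 mm threshold with margin while
staying below fracture-face feature size.  The flip side, documented as a
limitation: within ~5 mm of face boundaries the neighbourhood mixes
perpendicular surfaces and the scalar is unreliable, so threshold
segmentation recovers the *interiors* of faces (roughly 25–50 % of face
points at the default relief) with near-perfect cortical specificity away
from the cuts, rather than a pixel-accurate face mask.  Downstream
registration is designed to work from these partial, both-sides-consistent
surfaces; a Jaccard-style overlap with exact face labels is reported by
the acceptance script for transparency and sits near 0.3–0.4.

## Registration and reassembly

Coarse alignment is the closed-form least-squares rigid fit (SVD of the
cross-covariance with determinant correction) to ≥ 3 operator landmark
pairs; degenerate (collinear) configurations are rejected.  Refinement is
trimmed ICP on the fracture surfaces: nearest-neighbour correspondences,
a distance gate (default 5 mm — the coarse fit is expected to bring
matching faces within a few mm), keep-best trimming (default fraction
0.8; match plans may override per step, e.g. to ~0.5 when only one of a
fragment's two broken faces can overlap the reference), and a re-solve on
the kept pairs.  The trimmed RMS is non-increasing when the gate is
inactive; because the gate can reshuffle the kept set, the implementation
tracks and returns the best pose seen.  Convergence: relative RMS change
below 1e−6 or 50 iterations.

Two options matter for accuracy at CT-like sampling density and are used
by the synthetic operator (both off in the bare defaults):

* **Point-to-plane polish** (`polish_gate`): a second pass with a tighter
  gate (1.5 mm) minimising distances to the reference surface's local
  tangent planes (normals from k = 10 PCA).  Point-to-point
  correspondences cannot observe the tilt of a nearly planar face at
  finite sampling density; the plane metric restores it.
* **Surface selection** (`surface_radius`, `surface_band`): the
  refinement uses only fracture points within 15 mm of the clicked
  landmarks and within ±3.5 mm of the landmarks' best-fit plane — the
  operator registers the two faces they matched, not every broken face of
  the fragment.

Reassembly follows the operator's plan order; after each success the
merged cloud becomes the reference and the moving fragment's pose chain
is stored explicitly.  Failed steps are recorded and the pipeline
continues — partial reconstruction is a valid outcome.  After the last
step, `refine_sweeps` (default 1; the validation experiment uses 2)
re-registers each placed fragment once against the rest of the assembly
at a 1.0 mm gate with the plane metric: a fragment initially placed via
one narrow face is then braced by *all* its interfaces.  This is the
operator's final adjustment pass, still strictly sequential — joint
pose-graph optimisation is deliberately out of scope.  Merging never
deduplicates points and never prevents interpenetration (the protocol's
registration is unconstrained); overlap shows up in the distance
diagnostics instead.

## Evaluation

A reconstruction is ICP-registered onto the intact reference cloud, and
per-point nearest-neighbour distances are computed in the
reconstruction → intact direction (reconstruction error is the
question).  Both the mean and the RMS are reported — the two are easy to
conflate and RMS ≥ mean always.  Coverage is the fraction of intact
points with a reconstruction point within ε (default 2 mm, a few CT
voxels); > 95 % counts as a full reconstruction.  For synthetic
specimens the compared reconstruction is the *exterior* (cortical)
surface: fracture faces are interior to the bone envelope, and a surface
scan of a physically reassembled bone sees only the outside.  Summary
statistics use the sample SD (n − 1); presentation rounding is half-up
and never applied to stored values.  Paired method comparisons use the
Pearson product-moment correlation, which is the estimator that
reproduces the published paired coefficients; one-way and two-way
single-measure intraclass forms are provided, labelled, for comparison.

## Synthetic specimens

`make_long_bone` builds a closed surface of revolution: cylindrical
shaft, smooth flares over the terminal 15 % of length, tangent-smooth
rounded tips (flat caps would create a sharp rim ring that reads as
spurious fracture surface), and optional < 0.05 mm seeded undulation.
Defaults (length 200 mm, shaft radius 12 mm, end radius 25 mm) are at
the scale of the porcine femurs used in the physical comparison.

`fracture` partitions the densely sampled surface with n − 1 seeded cut
planes through the shaft: transverse cuts (tilt ≤ 3°) divide the bone
into slabs and a longitudinal chord plane splits each slab — the mixed
pattern of a comminuted fracture.  This matters at study scale: ~29
all-transverse cuts on a 200 mm bone would produce 3–7 mm wafers thinner
than the fracture relief itself, a geometry no registration method could
recover; the mixed cuts yield chunky pieces with well-separated faces.
Each cut carries **one** continuous relief field — a band-limited sum of
random plane waves, ~64 % of the variance at 4–8 mm wavelengths (the
jaggedness a roughness threshold picks up) and the rest at 12–30 mm
(large-scale waviness that gives registration a single wide optimum) —
normalised to RMS 1.5 mm by default.  The two fragments adjoining a cut
sample that shared surface on their own jittered 0.5 mm grids, exactly as
two CT clouds of one physical fracture do; no point appears on both
sides.  Every fragment receives a random rigid scatter pose, recorded;
`loss_fraction` deletes interior fragments to emulate blast loss.  The
synthetic operator (`build_match_plan`) clicks four well-spread landmarks
per shared face with 0.25 mm Gaussian noise, orders steps as a
max-interface spanning tree grown from a central fragment, and sets the
per-step trim and surface-selection overrides described above.

What the generator does **not** emulate: hollow diaphyses (fragments are
solid, faces are disks/strips rather than cortical ribbons), plastic
deformation of fresh bone, soft tissue and cartilage on the faces,
segmentation bias from real CT physics, and operator misjudgement of
which fragments match.  Passing synthetic tests therefore demonstrates
the correctness and internal accuracy of the pipeline, not field
performance on fleshed, blast-damaged remains.

`voxelize` rasterises the analytic solid onto an HU grid (bone 1500 HU
with 3 % seeded noise, optional soft-tissue shell at 40 HU, air
−1000 HU), closing the loop with the CT segmentation stage.

## Measured accuracy at study scale

At the physical comparison's own scale (six bones, per-bone fragment
counts 26, 20, 31, 26, 26, 43 — 172 fragments, ~30 k surface samples per
bone), the full pipeline re-associates every fragment and reconstructs
the exterior surface to a mean distance of ~0.3–0.6 mm from the intact
bone with coverage ≥ 0.95, seed-dependent — alongside the ~1.0 mm
reported for physically glued femurs.  Recovered poses match ground truth
to a few tenths of a degree per interface; because merging is strictly
sequential, per-interface noise accumulates along the assembly tree, and
the worst pose over all 172 fragments is typically several degrees /
several mm (seed-dependent).  Sub-degree *global* pose recovery at this
fragment count would require the joint optimisation that the protocol —
and this package — deliberately omit.  Small fragment counts (≤ ~10,
larger faces) recover all poses to better than 0.2°/0.1 mm.

## Numerical details and conventions

* Vertex merge tolerance on mesh load: 1e−6 mm; binary STL's 32-bit
  floats are the storage precision floor.
* Roughness plane fits cap the neighbourhood at 64 evenly strided
  neighbours on dense clouds — a deterministic thinning that leaves the
  fitted plane statistically unchanged.
* Pose-recovery errors: rotation is the angle of the relative error
  rotation; translation is the mean displacement of the fragment's own
  points under the error transform (lever-arm aware; a bare ‖Δt‖ is
  origin-dependent).  Both are measured relative to the assembly's
  reference fragment, which fixes the gauge.
* All randomness is explicit: every generator, subsampler and plan
  builder takes a seed, and identical seeds give byte-identical outputs.
* Degenerate inputs fail loudly: empty meshes, collinear landmark sets,
  seeds below the HU threshold, zero-variance correlation series.
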