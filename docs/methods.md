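# Methods

## Deformation model

The segmentation is a closed triangle surface in world millimetres. It is
embedded in a trivariate Bernstein (Bezier) lattice: a parallelepiped
`X0 + sS + tT + uU`, `(s,t,u) ∈ [0,1]³`, carrying `(l+1)(m+1)(n+1)`
control points on the regular grid `P_ijk = X0 + (i/l)S + (j/m)T + (k/n)U`.
A vertex at local coordinates `(s,t,u)` maps to the tensor-product
Bernstein combination of the displaced control points. Two consequences
the test suite leans on: the weights are a partition of unity (uniform
control-point displacement is a pure translation), and Bernstein bases
reproduce affine functions (an affine map of the lattice applies that
exact affine map to every embedded vertex).

Local coordinates are obtained by inverting the lattice frame,
`(s,t,u) = (x − X0)·[S;T;U]⁻¹` — exact for any non-degenerate frame,
including sheared ones; the public grid constructors only build
axis-aligned frames, matching axis-aligned image volumes. Vertices with
any coordinate outside `[0,1]` (possible only in local mode) are flagged
non-embedded and are never moved; a ±1e−9 band absorbs float jitter at the
lattice faces, and grazing coordinates are snapped onto the face so all
weights stay non-negative.

## Inverse solve (direct manipulation)

A drag requests a displacement `ΔX` for one surface vertex. With `B` the
constrained vertices' Bernstein weight rows, the control-point update is
the minimum-norm least-squares solution of `B·ΔP = ΔX`, computed per
spatial component with `numpy.linalg.lstsq` (the three components share
`B`). A single interior constraint is always met exactly
(`ΔP = wᵀΔX/‖w‖²`); incompatible multi-constraint systems resolve in the
least-squares sense and emit a warning with the residual. No
regularization beyond minimum norm: per-drag behavior stays
parameter-free.

One point worth recording: the often-assumed bound "no vertex moves more
than the dragged one" is false in general. The single-constraint motion
factor at vertex v is `w_v·w_c/‖w_c‖²`; Cauchy–Schwarz only bounds it by
`‖w_v‖/‖w_c‖`, which exceeds 1 when the constrained vertex sits mid-lattice
(small `‖w_c‖`) while v sits near a lattice corner (`‖w_v‖ → 1`). On the
default sphere/grid configuration the overshoot stays ~2%; the tests
assert the correct bound and the practical falloff.

Each drag is stateless: the current mesh is re-embedded in a fresh
zero-displacement grid, solved, deformed, and the displacements are
discarded. Accumulating `ΔP` across drags would let later drags act
through stale embeddings of a surface that has already moved.

## Grids

* Global mode fits an axis-aligned box around the current mesh, expanded
  by `padding` (default 0.05, i.e. 5% of each extent per side) so boundary
  vertices sit strictly inside the lattice and outward drags have
  headroom.
* Local mode places a box of caller-chosen center/size with the *same*
  degrees: the control-point count — and hence per-drag cost — is
  unchanged while the spacing shrinks, and the region outside the box is
  bitwise protected.
* Default degrees (5,5,5) → 216 control points. Deform cost is
  `O(V · (l+1)(m+1)(n+1))`, linear in both factors, which is what keeps
  the editing loop interactive at this grid density.

## Interaction geometry

Slice planes are sagittal/coronal/axial (x/y/z of an axis-aligned volume)
or arbitrary point+normal planes. Canonical planes use the two remaining
world axes, in (x,y,z) order, as the in-plane basis, so 2D coordinates
are world millimetres and drags are isometric; arbitrary planes derive a
deterministic orthonormal basis from the normal (smallest-|component|
axis crossed with the normal). Contours are extracted by marching
triangles — every face with vertices on both sides of the plane yields a
segment on its two crossing edges, segments are linked by shared mesh
edges — so each contour point records its source edge, and watertight
meshes yield closed polylines. A drag constrains the mesh *vertex*
nearest the contour point nearest the cursor (ties to the lowest index):
constraint rows are then exactly the Bernstein weights of real embedded
vertices.

Rasterization marks a voxel foreground iff its center lies inside the
closed surface, by counting z-ray crossings per (x,y) voxel column. Ray
origins carry a fixed sub-voxel offset (≈4e−4 voxel) so rays never pass
through projected edges/vertices; the offset is defined relative to voxel
centers, which preserves translation consistency, and an odd-parity
column triggers a retry with the next offset in a fixed three-element
sequence before raising a numerical error.

## Metrics

Dice is computed on identical voxel grids only (mismatch is an error,
never a silent resample); empty∩empty is defined as 1. The Hausdorff
distance is surface-based: each mesh contributes its vertices plus
face-uniform samples (default 2000 total, seeded), measured against the
*exact* nearest point on the other mesh's triangles. The point-to-triangle
distance is a vectorized closest-point-on-triangle classification with
exact KD-tree pruning (candidate faces limited to a ball of radius
nearest-centroid distance + max centroid-to-vertex radius). A
voxel-surface variant exists for cross-checks; it agrees with the
surface-based route to within the voxel size.

## Synthetic phantoms and the scripted user

The fixtures emulate the geometric regimes of organ-segmentation
correction without MR data: ground truth is an ellipsoid (subdivided
icosphere, analytic voxel mask); the degraded initial segmentation is
produced by a global scale error (smooth, global misfit — the regime of a
shape-model undershoot/overshoot), a cosine-windowed radial bump
(localized error on an otherwise correct surface — the regime that
motivates local mode), or seeded random jitter of a degree-(2,2,2)
lattice. Perturbations that fold the surface (any face normal turning
inward on the star-shaped phantom) are rejected. The canonical case is a
20 mm sphere in a 64³/1 mm volume at icosphere subdivision 3 (642
vertices), inflated by 10%: nested-ball closed form gives an initial Dice
of `2/(1+1.1³) ≈ 0.859`.

The scripted user replaces the human in the correction protocol with a
deterministic policy: visit slices in a fixed axis-interleaved order
(axial/coronal/sagittal, stride 4 voxels, center outward); on each slice
extract the current and ground-truth contours, find the current-contour
point with the largest in-plane distance to the ground truth, and — if the
error exceeds 0.25 mm — drag it onto its nearest ground-truth contour
point, one drag per slice visit. Policy "local" precedes each drag with a
local grid centered at the drag point, sized 3× the local error per axis
with a 4-voxel floor. The loop stops at the Dice target (default 0.95) or
the interaction cap (default 150). Drags that decrease Dice are kept but
flagged, as a human would keep a misjudged drag in the count. Every run
emits a JSON trace whose replay routes through the identical code path
and reproduces the final mesh bit for bit.

What the phantoms do *not* model: image intensities (the method reads
only geometry), anatomical shape complexity (vertebra-adjacent muscle
boundaries, articular surfaces), and human behavior (slice choice,
satisfaction-based stopping). Passing tests therefore demonstrate the
correctness and convergence of the deformation machinery on smooth and
locally-perturbed shapes, not clinical editing performance.

## Numerical choices

* Embedding tolerance ±1e−9 on `[0,1]`; frame singularity rejected at
  |det| < 1e−12.
* Contour vertices exactly on a plane are nudged by 1e−14·scale so all
  crossings are transversal; segment endpoints merge at 1e−6 mm.
* `lstsq` with `rcond=None`; constraint residual above 1e−6 mm warns.
* Rasterizer ray offsets: (3.717e−4, 6.193e−4) voxels, then two fixed
  fallbacks.
* Problem sizes in tests and the acceptance script — 64³ volumes, 642- to
  10242-vertex spheres, ≤100 interactions — were chosen as the smallest
  sizes at which the analytic tolerances (2% volume, chordal contour
  bounds) are comfortably meaningful.

## Known limitations

* Bezier (global-support) lattices only; no B-spline local support and no
  adaptive control-point redistribution.
* Axis-aligned image orientations only; oblique *image* reformatting is
  out of scope (mesh re-slicing on arbitrary planes is supported).
* The global mode cannot fix localized errors on complex shapes without
  disturbing correct regions — that is precisely what local mode is for,
  and the bump-fixture test demonstrates the contrast.
* One vertex per drag; batch multi-drag optimization is out of scope.
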