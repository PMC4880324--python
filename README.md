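# ffdedit

Deformation-based correction of 3D segmentations: a single 2D drag of a
contour on an image slice becomes a smooth 3D correction of the whole
segmentation surface, via direct manipulation of a free-form deformation
(FFD) lattice.

Automatic segmentation methods for medical images (active shape models,
learning-based pipelines) routinely leave residual errors that a clinician
must fix. Slice-wise mask painting is accurate but painfully slow because
every slice must be touched. `ffdedit` implements the alternative: the
segmentation is a triangle surface embedded in a trivariate Bernstein
control lattice, the user drags the 2D contour where it is wrong, and one
inverse solve turns that drag into a 3D deformation that corrects many
neighboring slices at once.

## Method

The surface is embedded in a parallelepiped lattice spanned by
`X0 + sS + tT + uU` with `(s,t,u) ∈ [0,1]³` and `(l+1)(m+1)(n+1)` control
points `P_ijk`. Each vertex deforms as the Bernstein tensor product

```
x_ffd = Σ_i Σ_j Σ_k  C(l,i)(1−s)^(l−i) s^i · C(m,j)(1−t)^(m−j) t^j
                   · C(n,k)(1−u)^(n−k) u^k · (P_ijk + ΔP_ijk)
```

Dragging a contour point by `ΔX` poses the inverse problem: find
control-point displacements `ΔP` with `B·ΔP = ΔX`, where `B` holds the
vertex's Bernstein weights. The system is underdetermined; the
minimum-norm least-squares solution (Moore–Penrose pseudoinverse) is used,
which for a single drag is the closed form `ΔP_ijk = w_ijk ΔX / Σw²` and
satisfies the drag exactly. The default lattice is degree (5,5,5) — 216
control points. A *local* mode re-centers a lattice of the same degrees
onto a region of interest: finer deformation resolution at identical cost,
and everything outside the box is provably untouched.

The package also provides plane–mesh contour extraction, 2D→3D drag
lifting, voxel-center rasterization, Dice and surface Hausdorff metrics,
synthetic phantoms (ellipsoids with scale/bump/lattice-jitter
degradations), a deterministic scripted user that plays the correction
protocol, and JSON interaction traces with bit-exact replay.

## Worked example

```python
import ffdedit as fe

# a 20 mm sphere "organ" whose initial segmentation is inflated by 10%
fix = fe.make_fixture(fe.FixtureSpec())   # 64³ volume, 1 mm voxels

final, trace = fe.scripted_user(
    fix.initial_mesh, fix.gt_mask, fix.gt_mesh, fix.spec.geometry,
    policy="global", dice_target=0.95, max_interactions=100,
)
print(f"initial Dice {trace.initial_dice:.4f}")
print(f"final Dice   {trace.final_dice:.4f} after {trace.interactions} drags")
print(f"Hausdorff    {fe.hausdorff(final, fix.gt_mesh):.2f} mm")
```

prints

```
initial Dice 0.8637
final Dice   0.9535 after 7 drags
Hausdorff    1.55 mm
```

The initial Dice matches the closed form for nested balls,
`2/(1+1.1³) ≈ 0.859`, up to voxelization; seven contour drags recover the
ground-truth sphere to Dice 0.95. The same workflow is available from the
shell:

```
ffdedit make-fixtures --out case/
ffdedit simulate --case case/ --policy global --out trace.json
ffdedit correct --image case/gt.nii.gz --seg case/init.ply \
                --trace trace.json --out corrected.ply
ffdedit metrics --seg corrected.ply --gt case/gt.nii.gz --report report.json
```

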