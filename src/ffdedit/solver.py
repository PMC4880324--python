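"""Direct manipulation of FFD: the inverse solve.

Dragging a surface point is intuitive; moving control points is not.  Given
desired displacements dX for one or more embedded vertices, we solve for
control-point displacements dP such that the forward FFD realizes them.
With B the matrix of Bernstein weight rows for the constrained vertices,
the system ``B dP = dX`` is underdetermined; the minimum-norm least-squares
solution (Moore-Penrose pseudoinverse, Hsu's formulation) is taken per
spatial component.  For a single constraint this reduces to the closed form
``dP_ijk = w_ijk dX / sum(w^2)`` and the constraint is met exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh

from . import ffd
from .errors import InputError

__all__ = ["Constraint", "solve_displacements", "apply_drag"]

#: weight rows with squared norm below this are treated as "outside the grid"
_ZERO_ROW_TOL = 1e-300


@dataclass(frozen=True)
class Constraint:
    """One desired vertex displacement: move ``vertex_id`` by ``target`` mm."""

    vertex_id: int
    target: tuple[float, float, float]


def solve_displacements(
    grid: ffd.ControlGrid,
    coords: ffd.LocalCoords,
    constraints: list[Constraint],
) -> ffd.ControlGrid:
    """Fill the grid's displacements so the constraints are (best) met.

    Returns a copy of ``grid`` with ``displacements`` set to the minimum-
    norm least-squares solution; the input grid is not mutated.  Conflicting
    (rank-deficient, incompatible) constraints are resolved in the least-
    squares sense and a warning reports the residual.
    """
    if not constraints:
        raise InputError("at least one constraint is required")
    rows = []
    targets = []
    for c in constraints:
        vid = int(c.vertex_id)
        if vid < 0 or vid >= coords.stu.shape[0]:
            raise InputError(f"constraint references vertex {vid} outside the mesh")
        if not coords.embedded[vid]:
            raise InputError(
                f"vertex {vid} is not embedded in the active grid "
                "(outside the lattice)"
            )
        w = ffd.weight_matrix(grid, coords.stu[vid])[0]
        if w @ w <= _ZERO_ROW_TOL:
            raise InputError(f"vertex {vid} has an all-zero weight row")
        rows.append(w)
        targets.append(np.asarray(c.target, dtype=float).reshape(3))
    B = np.vstack(rows)  # (C, ncp)
    dX = np.vstack(targets)  # (C, 3)
    # lstsq returns the minimum-norm solution for underdetermined systems;
    # the three spatial components share the same weight matrix
    dP, *_ = np.linalg.lstsq(B, dX, rcond=None)
    residual = np.linalg.norm(B @ dP - dX, axis=1)
    if residual.size and residual.max() > 1e-6:
        warnings.warn(
            "incompatible drag constraints; residual "
            f"{residual.max():.3g} mm absorbed in least squares",
            stacklevel=2,
        )
    out = grid.copy()
    l, m, n = grid.degrees
    out.displacements = dP.reshape(l + 1, m + 1, n + 1, 3)
    return out


def apply_drag(
    mesh: trimesh.Trimesh,
    grid: ffd.ControlGrid,
    vertex_id: int,
    delta: np.ndarray,
) -> trimesh.Trimesh:
    """Drag one vertex by ``delta`` mm and deform the whole surface.

    Composition of :func:`solve_displacements` and :func:`ffd.deform`; the
    dragged vertex lands on its target (to solver precision) and the
    surrounding surface follows smoothly with Bernstein falloff.  Returns a
    new mesh; the input mesh and grid are untouched.
    """
    coords = ffd.embed(mesh, grid)
    delta = np.asarray(delta, dtype=float).reshape(3)
    solved = solve_displacements(
        grid, coords, [Constraint(vertex_id=int(vertex_id), target=tuple(delta))]
    )
    return ffd.deform(mesh, coords, solved)
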