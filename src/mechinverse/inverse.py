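"""The Mechanical Inverse: force-balance linear system and its solution.

Tensions and pressures enter the vertex force-balance conditions
linearly, so the observed geometry defines a rectangular linear system
``A q = b`` whose unknowns ``q`` are the mechanical parameters.  The
first ``2 x (balanced vertices)`` rows impose zero net force at each
balanced vertex; one final row fixes the arbitrary overall scale by
constraining the mean tension to one.  The system is solved by a
pseudo-inverse: the minimum-norm least-squares solution plus an
orthonormal basis of "zero modes" (null-space directions, i.e. parameter
combinations exerting no net force anywhere).

Three parameterizations are supported:

``full``
    one tension per edge and one pressure per cell (the exterior
    pressure is pinned to zero by omitting its column).
``constant_pressure``
    all cell pressures assumed equal: tension columns only.  The system
    becomes overdetermined and is solved in the least-squares sense.
``cortical``
    each edge tension is the sum of the two adjacent cells' constant
    cortical tensions; unknowns are one cortical tension and one
    pressure per cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .cell_array import EXTERIOR, CellArray
from .errors import SolverError, ValidationError
from .vertex_model import MechanicalState, _rot_cw

PARAMETERIZATIONS = ("full", "constant_pressure", "cortical")


@dataclass
class ConstraintSystem:
    """Assembled force-balance system ``A q = b``.

    ``column_map`` ties each column to its parameter as
    ``("tension", edge_id)``, ``("pressure", cell_id)`` or
    ``("cortical", cell_id)``; ``row_map`` ties each row to
    ``(vertex_id, "x"|"y")`` or ``"scale"`` (always the last row).
    """

    matrix: np.ndarray
    rhs: np.ndarray
    column_map: list[tuple[str, int]]
    row_map: list
    parameterization: str
    array: CellArray

    @property
    def balance_matrix(self) -> np.ndarray:
        """The homogeneous part (balance rows only, scale row dropped)."""
        return self.matrix[:-1]

    def tension_column_mask(self) -> np.ndarray:
        return np.array([kind in ("tension", "cortical")
                         for kind, _ in self.column_map])


@dataclass
class InverseSolution:
    """Pseudo-inverse solution of a :class:`ConstraintSystem`.

    ``particular`` is the minimum-norm least-squares parameter vector,
    orthogonal to every zero mode; ``zero_modes`` (p x k) spans the
    numerical null space; the returned ``state`` corresponds to
    ``particular + zero_modes @ amplitudes``.
    """

    particular: np.ndarray
    zero_modes: np.ndarray
    amplitudes: np.ndarray
    residual_norm: float
    state: MechanicalState
    cortical: dict[int, float] | None = None

    @property
    def n_zero_modes(self) -> int:
        return self.zero_modes.shape[1]


def _edge_rows(array: CellArray):
    """Per-edge geometry and (balanced) endpoint row offsets."""
    balanced = array.balanced_vertex_ids()
    row_of = {vid: 2 * k for k, vid in enumerate(balanced)}
    out = []
    for eid in array.edge_ids:
        e = array.edges[eid]
        i, j = e.vertex_pair
        u = array.edge_vector(eid)
        out.append((eid, e, row_of.get(i), row_of.get(j), u))
    return balanced, row_of, out


def assemble(array: CellArray, parameterization: str = "full",
             scale_value: float = 1.0) -> ConstraintSystem:
    """Assemble the force-balance system for an observed geometry.

    Rows: two per balanced vertex (x then y), plus the tension-scale
    row.  The matrix entries depend only on chord vectors, so the system
    is invariant under rigid translation of the array.

    Raises
    ------
    ValidationError
        If an open array has no interior vertex to balance.
    """
    if parameterization not in PARAMETERIZATIONS:
        raise ValueError(f"unknown parameterization {parameterization!r}")
    balanced, _row_of, edge_rows = _edge_rows(array)
    if not balanced:
        raise ValidationError("nothing to balance: no interior vertices")
    E = len(array.edge_ids)
    ecol = {eid: k for k, eid in enumerate(array.edge_ids)}
    ccol = {cid: k for k, cid in enumerate(array.cell_ids)}
    C = len(array.cell_ids)

    if parameterization == "full":
        column_map = [("tension", e) for e in array.edge_ids]
        column_map += [("pressure", c) for c in array.cell_ids]
    elif parameterization == "constant_pressure":
        column_map = [("tension", e) for e in array.edge_ids]
    else:
        column_map = [("cortical", c) for c in array.cell_ids]
        column_map += [("pressure", c) for c in array.cell_ids]

    n_rows = 2 * len(balanced) + 1
    n_cols = len(column_map)
    A = np.zeros((n_rows, n_cols))
    b = np.zeros(n_rows)
    p_offset = E if parameterization == "full" else C

    def tension_cols(e):
        """Columns (with weights) carrying this edge's tension coefficient."""
        if parameterization == "cortical":
            return [ccol[c] for c in e.cell_pair if c != EXTERIOR]
        return [ecol[e.id]]

    for eid, e, ri, rj, u in edge_rows:
        ell = float(np.hypot(u[0], u[1]))
        t_hat = u / ell
        ju = _rot_cw(u)
        a, bcell = e.cell_pair
        for row, sgn in ((ri, 1.0), (rj, -1.0)):
            if row is None:
                continue
            for col in tension_cols(e):
                A[row:row + 2, col] += sgn * t_hat
            if parameterization != "constant_pressure":
                # pressure force is identical at both endpoints
                if a != EXTERIOR:
                    A[row:row + 2, p_offset + ccol[a]] += 0.5 * ju
                if bcell != EXTERIOR:
                    A[row:row + 2, p_offset + ccol[bcell]] -= 0.5 * ju

    # scale row: mean (implied) tension equals scale_value
    scale = A[-1]
    for eid, e, _ri, _rj, _u in edge_rows:
        for col in tension_cols(e):
            scale[col] += 1.0 / E
    b[-1] = scale_value

    row_map: list = []
    for vid in balanced:
        row_map += [(vid, "x"), (vid, "y")]
    row_map.append("scale")
    return ConstraintSystem(A, b, column_map, row_map, parameterization, array)


def _state_from_q(system: ConstraintSystem, q: np.ndarray):
    """Translate a parameter vector into a MechanicalState (+ cortical map)."""
    array = system.array
    tensions: dict[int, float] = {}
    pressures: dict[int, float] = {c: 0.0 for c in array.cell_ids}
    cortical: dict[int, float] | None = None
    values = dict(zip(system.column_map, q))
    if system.parameterization == "cortical":
        cortical = {c: float(values[("cortical", c)]) for c in array.cell_ids}
        for eid in array.edge_ids:
            a, b = array.edges[eid].cell_pair
            tensions[eid] = sum(cortical[c] for c in (a, b) if c != EXTERIOR)
    else:
        tensions = {e: float(values[("tension", e)]) for e in array.edge_ids}
    if system.parameterization != "constant_pressure":
        pressures = {c: float(values[("pressure", c)]) for c in array.cell_ids}
    return MechanicalState(tensions, pressures), cortical


class _ScaleEliminator:
    """Householder elimination of the hard scale constraint ``s . q = c``.

    The scale row is enforced exactly (a soft row would let heavy noise
    shrink the whole solution towards zero, since the balance rows alone
    are homogeneous).  With v = s/|s| and the reflection H mapping v to
    e1, the feasible set is ``q = q_p + Z y`` where ``q_p = v c/|s|``
    and Z = H[:, 1:] spans the constraint's tangent space.
    """

    def __init__(self, s: np.ndarray, c: float):
        norm = float(np.linalg.norm(s))
        if norm == 0:
            raise SolverError("all-zero scale row")
        v = s / norm
        w = v.copy()
        w[0] -= 1.0
        wn = np.linalg.norm(w)
        self._w = None if wn < 1e-15 else w / wn
        self.q_p = v * (c / norm)

    def _reflect(self, X):
        if self._w is None:
            return X
        w = self._w
        if X.ndim == 1:
            return X - 2.0 * w * (w @ X)
        return X - 2.0 * np.outer(X @ w, w)

    def expand(self, y: np.ndarray) -> np.ndarray:
        """Map reduced coordinates y (p-1) to a mean-constrained q (p)."""
        u = np.concatenate([[0.0], y])
        return self._reflect(u)

    def reduce_matrix(self, A: np.ndarray) -> np.ndarray:
        """A @ Z for the (p x (p-1)) tangent basis Z."""
        return self._reflect(A)[:, 1:] if self._w is not None else A[:, 1:]


def solve(system: ConstraintSystem, rel_tol: float = 1e-8,
          amplitudes: np.ndarray | None = None) -> InverseSolution:
    """Pseudo-inverse solution with the scale constraint enforced exactly.

    Minimizes the force-balance residual over the affine set of
    parameter vectors whose mean (implied) tension equals the scale
    value, via SVD of the reduced system.  Singular values below
    ``rel_tol`` times the largest are treated as zero; the corresponding
    directions form the zero-mode basis (all of them scale-neutral).
    ``amplitudes`` (default all zero) selects a point in the solution
    family ``particular + zero_modes @ amplitudes``.
    """
    A, b = system.matrix, system.rhs
    if not np.any(A):
        raise SolverError("all-zero constraint matrix")
    elim = _ScaleEliminator(A[-1], float(b[-1]))
    A_bal = A[:-1]
    M = elim.reduce_matrix(A_bal)
    rhs = -A_bal @ elim.q_p  # balance rows are homogeneous
    U, s, Vt = np.linalg.svd(M, full_matrices=True)
    cutoff = rel_tol * s[0] if s.size else 0.0
    rank = int(np.sum(s > cutoff))
    coeff = (U[:, :rank].T @ rhs) / s[:rank]
    y = Vt[:rank].T @ coeff
    particular = elim.q_p + elim.expand(y)
    null_reduced = Vt[rank:]
    zero_modes = (
        np.stack([elim.expand(v) for v in null_reduced], axis=1)
        if len(null_reduced) else np.zeros((A.shape[1], 0))
    )
    if amplitudes is None:
        amplitudes = np.zeros(zero_modes.shape[1])
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.shape != (zero_modes.shape[1],):
        raise SolverError(
            f"expected {zero_modes.shape[1]} zero-mode amplitudes, "
            f"got shape {amplitudes.shape}"
        )
    q = particular + zero_modes @ amplitudes
    residual = float(np.linalg.norm(A @ q - b))
    state, cortical = _state_from_q(system, q)
    return InverseSolution(particular, zero_modes, amplitudes, residual,
                           state, cortical)


def solve_nonnegative(system: ConstraintSystem,
                      rel_tol: float = 1e-8) -> InverseSolution:
    """Least squares with tensions constrained to be non-negative.

    Quadratic programming (bounded linear least squares): tension and
    cortical columns are bounded below by zero, pressure columns are
    free.  When the unconstrained optimum is already non-negative this
    coincides with :func:`solve`; on noisy data it removes the small
    tail of negative inferred tensions the plain pseudo-inverse can
    produce.
    """
    A, b = system.matrix, system.rhs
    if not np.any(A):
        raise SolverError("all-zero constraint matrix")
    mask = system.tension_column_mask()
    lb = np.where(mask, 0.0, -np.inf)
    ub = np.full(A.shape[1], np.inf)
    # enforce the scale constraint effectively exactly via a heavy weight
    # (bounded least squares admits no equality constraints directly)
    w = 1e6 * max(1.0, float(np.abs(A[:-1]).max()))
    A = np.vstack([A[:-1], w * A[-1]])
    b = np.concatenate([b[:-1], [w * b[-1]]])
    res = optimize.lsq_linear(A, b, bounds=(lb, ub), method="trf",
                              tol=1e-14)
    if not res.success:
        raise SolverError(f"non-negative least squares failed: {res.message}")
    q = res.x
    implied = _implied_tensions(system, q)
    if abs(float(np.mean(implied)) - system.rhs[-1]) > 0.5 * abs(system.rhs[-1]):
        raise SolverError(
            "scale constraint infeasible under tension positivity"
        )
    residual = float(np.linalg.norm(system.matrix @ q - system.rhs))
    state, cortical = _state_from_q(system, q)
    return InverseSolution(q, np.zeros((system.matrix.shape[1], 0)),
                           np.zeros(0), residual, state, cortical)


def _implied_tensions(system: ConstraintSystem, q: np.ndarray) -> np.ndarray:
    state, _ = _state_from_q(system, q)
    return state.tension_vector(system.array)


def null_space_dimension(system: ConstraintSystem, rel_tol: float = 1e-8,
                         include_scale_row: bool = False) -> int:
    """Numerical null-space dimension of the assembled system.

    By default the homogeneous balance system (scale row excluded) is
    analysed, matching the counting argument in which the overall scale
    is one of the free constants.
    """
    A = system.matrix if include_scale_row else system.balance_matrix
    s = np.linalg.svd(A, compute_uv=False)
    if s.size == 0 or s[0] == 0:
        return A.shape[1]
    return int(A.shape[1] - np.sum(s > rel_tol * s[0]))
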