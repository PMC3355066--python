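"""Error propagation of the inverse: spectra and empirical noise curves.

A small perturbation dr of the vertex positions perturbs the balance
matrix and hence the inferred parameters to first order by

    dq = -pinv(A) . (dA/dr . dr) . q

The singular values of this linear error-response operator (with
displacements measured in mean edge lengths and parameters in mean
tensions, both dimensionless) quantify how strongly positional noise is
amplified into parameter noise.  The full tension+pressure problem shows
a substantial fraction of singular values above one; restricting the
parameter space (e.g. constant pressure) suppresses them, which is what
makes the partial inverse practically robust.

The empirical counterpart regenerates synthetic equilibrium tissues,
corrupts the vertices at a series of noise amplitudes, runs the partial
inverse and reports the mean true-vs-inferred tension correlation per
amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cell_array import CellArray, EXTERIOR
from .errors import SolverError
from .inverse import ConstraintSystem, _ScaleEliminator, assemble, solve
from .validation import recovery_scatter
from .vertex_model import (
    SimulationConfig,
    corrupt_vertices,
    generate_voronoi_tissue,
)

SEED_MODULUS = 2**31 - 1


@dataclass
class SensitivityReport:
    """Singular-value spectra before/after parameter reduction."""

    singular_values_full: np.ndarray
    singular_values_reduced: np.ndarray
    fraction_above_one_full: float
    fraction_above_one_reduced: float


def _error_response_matrix(system: ConstraintSystem, q: np.ndarray,
                           rel_tol: float = 1e-8) -> np.ndarray:
    """Dense first-order map from vertex displacements to parameter shifts.

    Differentiates the balance-matrix entries analytically with respect
    to every vertex coordinate, contracts with the solution ``q`` and
    left-multiplies by the pseudo-inverse of the (scale-augmented)
    matrix.  Output is dimensionless: rows in units of the mean tension
    (the scale row already fixes it to one), columns in units of the
    mean edge length.
    """
    array = system.array
    A = system.matrix
    V = len(array.vertex_ids)
    B = np.zeros((A.shape[0] - 1, 2 * V))  # balance rows only
    values = dict(zip(system.column_map, q))

    balanced = array.balanced_vertex_ids()
    row_of = {vid: 2 * k for k, vid in enumerate(balanced)}
    for eid in array.edge_ids:
        e = array.edges[eid]
        i, j = e.vertex_pair
        u = array.edge_vector(eid)
        ell = float(np.hypot(u[0], u[1]))
        t_hat = u / ell
        # d t_hat / d u  (2x2), and d(J u)/d u = J
        P = (np.eye(2) - np.outer(t_hat, t_hat)) / ell
        J = np.array([[0.0, 1.0], [-1.0, 0.0]])
        if system.parameterization == "cortical":
            q_T = sum(values[("cortical", c)] for c in e.cell_pair
                      if c != EXTERIOR)
        else:
            q_T = values[("tension", eid)]
        if system.parameterization == "constant_pressure":
            dq_p = 0.0
        else:
            a, b = e.cell_pair
            q_a = values[("pressure", a)] if a != EXTERIOR else 0.0
            q_b = values[("pressure", b)] if b != EXTERIOR else 0.0
            dq_p = q_a - q_b
        dof_i, dof_j = 2 * array.vertex_row(i), 2 * array.vertex_row(j)
        # d(coefficients . q)/du for the rows of each endpoint
        block_i = q_T * P + 0.5 * dq_p * J   # rows of vertex i
        block_j = -q_T * P + 0.5 * dq_p * J  # rows of vertex j
        for vid, block in ((i, block_i), (j, block_j)):
            row = row_of.get(vid)
            if row is None:
                continue
            B[row:row + 2, dof_j:dof_j + 2] += block
            B[row:row + 2, dof_i:dof_i + 2] -= block
    # response of the scale-constrained estimator:
    # dq = -Z pinv(A_bal Z) (dA_bal q), with Z the constraint tangent basis
    elim = _ScaleEliminator(A[-1], float(system.rhs[-1]))
    M = elim.reduce_matrix(A[:-1])
    pinv = np.linalg.pinv(M, rcond=rel_tol)
    resp_reduced = -(pinv @ B)
    resp = np.stack([elim.expand(col) for col in resp_reduced.T], axis=1)
    return resp * array.mean_edge_length()


def error_response_spectrum(array: CellArray, parameterization: str = "full",
                            rel_tol: float = 1e-8) -> np.ndarray:
    """Descending singular values of the error-response operator."""
    system = assemble(array, parameterization)
    sol = solve(system, rel_tol=rel_tol)
    M = _error_response_matrix(system, sol.particular, rel_tol=rel_tol)
    if not np.all(np.isfinite(M)):
        raise SolverError("singular system: error response is not finite")
    return np.linalg.svd(M, compute_uv=False)


def _fraction_above_one(s: np.ndarray) -> float:
    """Fraction of the positive spectrum exceeding one.

    Exact zeros are directions with no parameter response at all (the
    operator is rank-limited); they are not error modes and are excluded
    from the histogram statistic.
    """
    positive = s[s > 1e-9 * s[0]] if s.size else s
    return float(np.mean(positive > 1.0)) if positive.size else 0.0


def sensitivity_report(array: CellArray,
                       reduced: str = "constant_pressure",
                       rel_tol: float = 1e-8) -> SensitivityReport:
    """Compare error amplification of the full and reduced inverses."""
    s_full = error_response_spectrum(array, "full", rel_tol)
    s_red = error_response_spectrum(array, reduced, rel_tol)
    return SensitivityReport(
        singular_values_full=s_full,
        singular_values_reduced=s_red,
        fraction_above_one_full=_fraction_above_one(s_full),
        fraction_above_one_reduced=_fraction_above_one(s_red),
    )


def _derived_seed(*parts: int) -> int:
    """Deterministic child seed below 2**31 from integer parts."""
    ss = np.random.SeedSequence(list(parts))
    return int(ss.generate_state(1)[0] % SEED_MODULUS)


def empirical_noise_curve(config: SimulationConfig, noise_levels,
                          n_replicates: int = 10) -> pd.DataFrame:
    """Recovered-correlation curve of the partial inverse vs noise level.

    For each replicate a fresh equilibrium tissue is generated (seeds
    derived from ``config.seed``); for each noise level its vertices are
    corrupted at that r.m.s. fraction of the mean edge length, the
    constant-pressure inverse is solved, and the Pearson correlation
    between true and inferred tensions is recorded.  Replicates are
    paired across noise levels (same tissues) so level-to-level
    comparisons are low-variance.

    Returns a DataFrame with columns ``noise_level``, ``mean_r``,
    ``sd_r`` and ``n_replicates``.
    """
    noise_levels = [float(x) for x in noise_levels]
    if any(x < 0 for x in noise_levels):
        raise ValueError("noise levels must be >= 0")
    r_values = {lvl: [] for lvl in noise_levels}
    for rep in range(n_replicates):
        cfg = replace(config, seed=_derived_seed(config.seed, rep))
        array, true_state = generate_voronoi_tissue(cfg)
        for k, lvl in enumerate(noise_levels):
            noisy = corrupt_vertices(array, lvl,
                                     seed=_derived_seed(config.seed, rep, k))
            sol = solve(assemble(noisy, "constant_pressure"))
            r, _ = recovery_scatter(true_state, sol.state)
            r_values[lvl].append(r)
    rows = [
        (lvl, float(np.mean(rs)), float(np.std(rs, ddof=1)) if len(rs) > 1 else 0.0,
         len(rs))
        for lvl, rs in r_values.items()
    ]
    return pd.DataFrame(rows, columns=["noise_level", "mean_r", "sd_r",
                                       "n_replicates"])
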