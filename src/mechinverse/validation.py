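"""Downstream analyses of inferred mechanical states.

Covers the cross-checks a force-inference study runs after the inverse:
intercellular traction (shear) forces carried by adhesion molecules, the
Young-Laplace consistency check against independently measured interface
curvatures, orientation (e.g. AP-vs-DV) tension anisotropy statistics,
and the true-vs-inferred recovery scatter used on synthetic benchmarks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cell_array import EXTERIOR, CellArray
from .errors import ValidationError
from .vertex_model import MechanicalState


@dataclass
class TractionRecord:
    """Traction (shear) force transmitted across one interface.

    The traction is the net transfer of cortical tension from the left
    cell to the right cell along the edge, obtained from cortical-tension
    continuity at the two endpoint corners; it changes sign if the two
    cells' roles are swapped.
    """

    edge_id: int
    traction: float
    adjacent_tensions: dict[str, float] = field(default_factory=dict)


@dataclass
class LaplaceCheck:
    """Young-Laplace consistency: pressure jumps vs tension x curvature."""

    table: pd.DataFrame  # columns: edge_id, delta_p, t_kappa
    r: float
    slope: float
    degenerate: bool = False


@dataclass
class AnisotropyReport:
    """Tension statistics of axis-aligned vs transverse interfaces."""

    axis_angle: float
    threshold_angle: float
    aligned_mean: float
    transverse_mean: float
    aligned_count: int
    transverse_count: int
    ratio: float  # aligned mean / transverse mean
    statistic: float  # Mann-Whitney U
    p_value: float
    aligned_cdf: np.ndarray  # sorted tensions (empirical CDF support)
    transverse_cdf: np.ndarray


def _third_cell(array: CellArray, vertex_id: int, a: int, b: int):
    """The cell meeting cells a and b at a threefold vertex, or None."""
    incident = array.vertex_edges[vertex_id]
    if len(incident) != 3:
        return None
    cells = set()
    for eid in incident:
        cells.update(array.edges[eid].cell_pair)
    others = cells - {a, b}
    if len(others) != 1:
        return None
    (c,) = others
    return None if c == EXTERIOR else c


def _tension_between(array: CellArray, state: MechanicalState,
                     vertex_id: int, x: int, y: int) -> float:
    for eid in array.vertex_edges[vertex_id]:
        if set(array.edges[eid].cell_pair) == {x, y}:
            if eid not in state.tensions:
                raise ValidationError(f"missing tension for edge {eid}")
            return state.tensions[eid]
    raise ValidationError(
        f"no edge between cells {x} and {y} at vertex {vertex_id}"
    )


def compute_tractions(array: CellArray, state: MechanicalState
                      ) -> list[TractionRecord]:
    """Traction force across every fully interior threefold interface.

    For edge <ab> with third cells c (at the first endpoint) and d (at
    the second), continuity of each cell's cortical tension around its
    corners gives the cortical share of cell a at a corner as
    ``(T_ab + T_a. - T_b.)/2``; the traction is the difference of that
    share between the two ends:

        tau_ab = [(T_ad - T_bd) - (T_ac - T_bc)] / 2.

    Edges whose endpoints are rosettes or touch the exterior are
    skipped (the corner-continuity construction needs two threefold
    corners with real third cells).  Uniform tension gives zero traction
    everywhere.
    """
    records = []
    for eid in array.edge_ids:
        e = array.edges[eid]
        a, b = e.cell_pair
        if EXTERIOR in (a, b):
            continue
        if eid not in state.tensions:
            raise ValidationError(f"missing tension for edge {eid}")
        i, j = e.vertex_pair
        c = _third_cell(array, i, a, b)
        d = _third_cell(array, j, a, b)
        if c is None or d is None:
            continue
        t_ad = _tension_between(array, state, j, a, d)
        t_bd = _tension_between(array, state, j, b, d)
        t_ac = _tension_between(array, state, i, a, c)
        t_bc = _tension_between(array, state, i, b, c)
        tau = 0.5 * ((t_ad - t_bd) - (t_ac - t_bc))
        records.append(TractionRecord(
            eid, float(tau),
            {"T_ab": state.tensions[eid], "T_ac": t_ac, "T_bc": t_bc,
             "T_ad": t_ad, "T_bd": t_bd},
        ))
    return records


def laplace_check(array: CellArray, state: MechanicalState) -> LaplaceCheck:
    """Compare inferred pressure jumps with tension times measured curvature.

    Uses every edge carrying a curvature value.  Sign conventions:
    ``delta_p = P_left - P_right`` and curvature is positive when the
    interface bows away from the left cell, so perfect Young-Laplace
    agreement gives slope +1 and r = 1.
    """
    rows = []
    for eid in array.edge_ids:
        e = array.edges[eid]
        if e.curvature is None:
            continue
        a, b = e.cell_pair
        dp = state.pressure_of(a) - state.pressure_of(b)
        tk = state.tensions[eid] * e.curvature
        rows.append((eid, float(dp), float(tk)))
    if not rows:
        raise ValidationError(
            "no edge carries a curvature value; supply per-edge curvatures "
            "to run the Laplace check"
        )
    table = pd.DataFrame(rows, columns=["edge_id", "delta_p", "t_kappa"])
    x = table["delta_p"].to_numpy()
    y = table["t_kappa"].to_numpy()
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("non-finite Laplace entries")
    if len(rows) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return LaplaceCheck(table, float("nan"), float("nan"), degenerate=True)
    fit = stats.linregress(x, y)
    return LaplaceCheck(table, float(fit.rvalue), float(fit.slope))


def acute_angle_to_axis(direction: np.ndarray, axis_angle: float) -> float:
    """Acute angle (radians, in [0, pi/2]) between a chord and an axis."""
    theta = math.atan2(direction[1], direction[0]) - axis_angle
    theta = theta % math.pi
    return min(theta, math.pi - theta)


def anisotropy_report(array: CellArray, state: MechanicalState,
                      axis_angle: float = 0.0,
                      threshold_angle: float = math.pi / 4) -> AnisotropyReport:
    """Split interfaces by orientation and compare tension distributions.

    Edges whose acute angle to the supplied tissue axis is strictly
    below ``threshold_angle`` form the "aligned" group (e.g. AP-like);
    the rest -- including edges exactly at the threshold -- form the
    "transverse" group (e.g. DV-like).  Reports group means, their
    ratio, empirical CDF supports and a two-sample Mann-Whitney test.
    """
    aligned, transverse = [], []
    for eid in array.edge_ids:
        ang = acute_angle_to_axis(array.edge_vector(eid), axis_angle)
        # ties (within 1e-9 rad of the threshold) go to the transverse group
        (aligned if ang < threshold_angle - 1e-9 else transverse).append(
            state.tensions[eid]
        )
    if not aligned or not transverse:
        raise ValidationError("one orientation group is empty")
    aligned = np.sort(np.asarray(aligned, dtype=float))
    transverse = np.sort(np.asarray(transverse, dtype=float))
    mw = stats.mannwhitneyu(aligned, transverse, alternative="two-sided")
    return AnisotropyReport(
        axis_angle=axis_angle,
        threshold_angle=threshold_angle,
        aligned_mean=float(aligned.mean()),
        transverse_mean=float(transverse.mean()),
        aligned_count=len(aligned),
        transverse_count=len(transverse),
        ratio=float(aligned.mean() / transverse.mean()),
        statistic=float(mw.statistic),
        p_value=float(mw.pvalue),
        aligned_cdf=aligned,
        transverse_cdf=transverse,
    )


def recovery_scatter(true_state: MechanicalState,
                     inferred_state: MechanicalState
                     ) -> tuple[float, pd.DataFrame]:
    """Pearson correlation between true and inferred tensions.

    Both sets are rescaled to mean one (the inverse only determines
    tensions up to overall scale) and paired by edge id.
    """
    if set(true_state.tensions) != set(inferred_state.tensions):
        raise ValidationError("true and inferred states cover different edges")
    eids = sorted(true_state.tensions)
    t = np.array([true_state.tensions[e] for e in eids])
    h = np.array([inferred_state.tensions[e] for e in eids])
    t = t / t.mean()
    h = h / h.mean()
    r = float(stats.pearsonr(t, h).statistic)
    table = pd.DataFrame({"edge_id": eids, "true": t, "inferred": h})
    return r, table
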