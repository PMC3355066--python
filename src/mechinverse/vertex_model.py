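"""Forward vertex model: interface forces, energy, relaxation, synthesis.

The mechanical state of the sheet is a tension per interface and a
two-dimensional pressure per cell.  The force an interface exerts on one
of its endpoint vertices has a tension component of magnitude ``T``
directed along the chord towards the other endpoint, and a pressure
component ``(P_left - P_right)/2`` times the chord rotated clockwise by
90 degrees -- the Young-Laplace force on the half of the interface
adjacent to the vertex.  These per-edge forces sum, at each vertex, to
minus the gradient of the energy

    H = - sum_cells P_a A_a + sum_edges T_ab l_ab

with respect to that vertex's position.

Synthetic equilibrium tissues are produced by relaxing a periodic
Voronoi tessellation under a vertex-model energy with i.i.d. uniform
per-edge line tensions and a quadratic perimeter elasticity, but no
area term -- hence uniform pressure.  The effective interfacial tension
of each edge, read off the energy's differential, is the line tension
plus the perimeter-elasticity contributions of its two cells; these
effective tensions are the known ground truth of the benchmark, and the
relaxed geometry satisfies force balance in them to machine tolerance.
(A pure line-tension energy is not usable here: with straight edges the
junction angles are fixed by the tensions alone, so a generic i.i.d.
tension draw admits no equilibrium at any fixed topology -- relaxation
just collapses edges.  The perimeter term lets tensions co-adapt with
geometry, making equilibria generic.)
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, spatial

from .cell_array import (
    EXTERIOR,
    CellArray,
    Vertex,
    minimum_image,
)
from .errors import ConvergenceError, DegenerateEdgeError, ValidationError

@dataclass
class MechanicalState:
    """Per-edge tensions and per-cell pressures paired with a CellArray.

    Tensions are in force units, pressures in force/length (2-D
    pressure).  The exterior region's pressure is the reference and
    conventionally zero.
    """

    tensions: dict[int, float]
    pressures: dict[int, float]
    exterior_pressure: float = 0.0

    def check_pairing(self, array: CellArray) -> None:
        if set(self.tensions) != set(array.edge_ids):
            raise ValidationError("state tensions do not match the array's edges")
        if set(self.pressures) != set(array.cell_ids):
            raise ValidationError("state pressures do not match the array's cells")

    def tension_vector(self, array: CellArray) -> np.ndarray:
        return np.array([self.tensions[e] for e in array.edge_ids])

    def pressure_vector(self, array: CellArray) -> np.ndarray:
        return np.array([self.pressures[c] for c in array.cell_ids])

    def pressure_of(self, cell_id: int) -> float:
        if cell_id == EXTERIOR:
            return self.exterior_pressure
        return self.pressures[cell_id]

    @classmethod
    def uniform(cls, array: CellArray, tension: float = 1.0,
                pressure: float = 0.0) -> "MechanicalState":
        return cls({e: tension for e in array.edge_ids},
                   {c: pressure for c in array.cell_ids})


#: perimeter of the regular hexagon of unit area, the natural rest
#: perimeter for tissues generated at mean cell area one
HEX_PERIMETER = 6.0 * math.sqrt(2.0 / (3.0 * math.sqrt(3.0)))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic-tissue generator.

    ``tension_distribution`` is the uniform law of the i.i.d. per-edge
    line tensions Lambda; ``perimeter_elasticity`` (Gamma) and
    ``rest_perimeter`` (L0) control the per-cell quadratic perimeter
    term of the generator energy (see :func:`generate_voronoi_tissue`).
    ``convergence_tol`` is the admissible maximum net vertex force in
    units of the mean tension.
    """

    n_cells: int = 400
    tension_distribution: tuple[float, float] = (0.5, 1.5)
    perimeter_elasticity: float = 0.3
    rest_perimeter: float = HEX_PERIMETER
    seed: int = 0
    convergence_tol: float = 1e-6
    max_iterations: int = 150000
    box_aspect: float = 1.0

    def __post_init__(self):
        low, high = self.tension_distribution
        if low <= 0:
            raise ValueError("tension distribution lower bound must be > 0")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be > 0")
        if self.perimeter_elasticity < 0:
            raise ValueError("perimeter_elasticity must be >= 0")


def _rot_cw(u: np.ndarray) -> np.ndarray:
    """Rotate 2-vectors clockwise by 90 degrees: (x, y) -> (y, -x)."""
    return np.stack([u[..., 1], -u[..., 0]], axis=-1)


def interface_force(array: CellArray, state: MechanicalState, edge_id: int,
                    at_vertex: int) -> np.ndarray:
    """Force exerted by one interface on one of its endpoint vertices.

    The tension part pulls the vertex towards the other endpoint; the
    pressure part is perpendicular to the chord, pointing away from the
    higher-pressure side, with magnitude ``|P_left - P_right| * l / 2``.
    """
    e = array.edges[edge_id]
    u = array.edge_vector(edge_id, from_vertex=at_vertex)
    ell = float(np.hypot(u[0], u[1]))
    a, b = e.cell_pair
    if at_vertex == e.vertex_pair[1]:
        a, b = b, a  # left cell of the reversed chord
    dp = state.pressure_of(a) - state.pressure_of(b)
    return state.tensions[edge_id] * u / ell + 0.5 * dp * _rot_cw(u)


def net_vertex_force(array: CellArray, state: MechanicalState,
                     vertex_id: int) -> np.ndarray:
    """Sum of interface forces at a vertex (zero at equilibrium)."""
    total = np.zeros(2)
    for eid in array.vertex_edges[vertex_id]:
        total += interface_force(array, state, eid, vertex_id)
    return total


def energy(array: CellArray, state: MechanicalState) -> float:
    """Mechanical energy  H = -sum P_a A_a + sum T_ab l_ab."""
    state.check_pairing(array)
    T = state.tension_vector(array)
    P = state.pressure_vector(array)
    return float(T @ array.edge_lengths() - P @ array.cell_areas())


# ----------------------------------------------------------------------
# vectorized force assembly
# ----------------------------------------------------------------------

class _Frame:
    """Cached index arrays and fixed periodic-image shifts for one topology."""

    def __init__(self, array: CellArray):
        self.array = array
        self.rows_i = np.array(
            [array.vertex_row(array.edges[e].vertex_pair[0]) for e in array.edge_ids]
        )
        self.rows_j = np.array(
            [array.vertex_row(array.edges[e].vertex_pair[1]) for e in array.edge_ids]
        )
        raw = array.positions[self.rows_j] - array.positions[self.rows_i]
        wrapped = minimum_image(raw, array.box)
        # integer box shifts frozen at construction: keeps the energy
        # smooth during relaxation even if a chord crosses the half-box
        self.shift = wrapped - raw

    def chords(self, positions: np.ndarray) -> np.ndarray:
        return positions[self.rows_j] - positions[self.rows_i] + self.shift

    def forces(self, positions: np.ndarray, tensions: np.ndarray,
               dp: np.ndarray) -> np.ndarray:
        """Net per-vertex forces, (V, 2), for given coordinates."""
        u = self.chords(positions)
        ell = np.hypot(u[:, 0], u[:, 1])
        t_hat = u / ell[:, None]
        f_edge_i = tensions[:, None] * t_hat + 0.5 * dp[:, None] * _rot_cw(u)
        f_edge_j = -tensions[:, None] * t_hat + 0.5 * dp[:, None] * _rot_cw(u)
        out = np.zeros_like(positions)
        np.add.at(out, self.rows_i, f_edge_i)
        np.add.at(out, self.rows_j, f_edge_j)
        return out


def all_net_forces(array: CellArray, state: MechanicalState) -> np.ndarray:
    """Net force on every vertex, rows ordered like ``array.vertex_ids``."""
    state.check_pairing(array)
    frame = _Frame(array)
    T = state.tension_vector(array)
    dp = np.array([
        state.pressure_of(array.edges[e].cell_pair[0])
        - state.pressure_of(array.edges[e].cell_pair[1])
        for e in array.edge_ids
    ])
    return frame.forces(array.positions, T, dp)


def relax(array: CellArray, state: MechanicalState,
          config: SimulationConfig) -> CellArray:
    """Quasi-statically relax vertex positions at fixed topology.

    Minimizes the tension-only energy ``sum T_ab l_ab`` (the state's
    pressures must be uniform: with no area term every cell carries the
    same pressure, which exerts no net force).  Uses L-BFGS descent with
    the analytic gradient; terminates when the maximum net vertex force
    drops below ``convergence_tol`` times the mean tension.

    Raises
    ------
    ConvergenceError
        If the tolerance is not met within ``max_iterations``.
    DegenerateEdgeError
        If an edge collapses during descent (no T1 handling).
    """
    state.check_pairing(array)
    P = state.pressure_vector(array)
    if P.size and float(np.ptp(P)) > 1e-12 * (1.0 + float(np.abs(P).max())):
        raise ValidationError(
            "relax() requires uniform pressures (tension-only energy)"
        )
    if array.topology_kind != "toroidal":
        raise ValidationError(
            "relax() supports toroidal arrays only; open/closed arrays "
            "collapse under tension-only energy without pinned boundaries"
        )
    frame = _Frame(array)
    T = state.tension_vector(array)
    mean_T = float(T.mean())
    tol = config.convergence_tol * mean_T
    shape = array.positions.shape
    history: list[float] = []

    def objective(x):
        pos = x.reshape(shape)
        u = frame.chords(pos)
        ell = np.hypot(u[:, 0], u[:, 1])
        f = frame.forces(pos, T, np.zeros(len(T)))
        history.append(float(np.hypot(f[:, 0], f[:, 1]).max()))
        return float(T @ ell), -f.ravel()

    res = optimize.minimize(
        objective, array.positions.ravel(), jac=True, method="L-BFGS-B",
        options={"maxiter": config.max_iterations, "gtol": 0.1 * tol,
                 "ftol": 0.0, "maxfun": 4 * config.max_iterations},
    )
    pos = res.x.reshape(shape)
    f = frame.forces(pos, T, np.zeros(len(T)))
    residual = float(np.hypot(f[:, 0], f[:, 1]).max())
    u = frame.chords(pos)
    ell = np.hypot(u[:, 0], u[:, 1])
    if np.any(ell < 1e-6 * ell.mean()):
        raise DegenerateEdgeError(
            "an edge collapsed during relaxation (T1 transitions are not "
            "handled); the tension draw admits no equilibrium at this topology"
        )
    if residual > tol:
        raise ConvergenceError(
            f"relaxation stalled at max net force {residual:.3e} "
            f"(tolerance {tol:.3e})", residual_history=history,
        )
    if array.box is not None:
        pos = pos % np.asarray(array.box)
    return array.with_positions(pos)


# ----------------------------------------------------------------------
# synthetic tissue generation
# ----------------------------------------------------------------------

def _periodic_voronoi(seeds: np.ndarray, box) -> CellArray:
    """Toroidal cell array from the Voronoi diagram of seeds in a box."""
    n = len(seeds)
    Lx, Ly = box
    offsets = [
        np.array([ix * Lx, iy * Ly])
        for ix in (0, -1, 1) for iy in (0, -1, 1)
    ]
    tiled = np.concatenate([seeds + off for off in offsets])
    vor = spatial.Voronoi(tiled)
    # canonicalize Voronoi vertices of the central-copy cells modulo the box
    used = sorted({
        vid
        for i in range(n)
        for vid in vor.regions[vor.point_region[i]]
    })
    if -1 in used:
        raise ValidationError("unbounded Voronoi region in periodic tiling")
    coords = vor.vertices[used] % np.array([Lx, Ly])
    tree = spatial.cKDTree(coords, boxsize=[Lx, Ly])
    pairs = tree.query_pairs(r=1e-6 * min(Lx, Ly))
    parent = list(range(len(used)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    canon = {used[k]: find(k) for k in range(len(used))}
    roots = sorted(set(canon.values()))
    root_id = {r: i for i, r in enumerate(roots)}
    positions = {root_id[r]: coords[r] for r in roots}

    loops = {}
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        ids = []
        for vid in region:
            cid = root_id[canon[vid]]
            if not ids or ids[-1] != cid:
                ids.append(cid)
        if ids[0] == ids[-1]:
            ids.pop()
        # CCW order by angle around the seed (Voronoi cells are convex)
        rel = minimum_image(
            np.array([positions[v] for v in ids]) - seeds[i], (Lx, Ly)
        )
        order = np.argsort(np.arctan2(rel[:, 1], rel[:, 0]))
        loops[i] = [ids[k] for k in order]
    return CellArray.from_cell_loops(positions, loops, "toroidal", box=(Lx, Ly))


class _ElasticModel:
    """Vertex-model energy with line tension and perimeter elasticity.

        E = sum_e Lambda_e l_e + (Gamma/2) sum_a (L_a - L0)^2

    The effective (energy-conjugate) tension of edge e between cells a
    and b is  tau_e = Lambda_e + Gamma (L_a - L0) + Gamma (L_b - L0);
    with the rest perimeter L0 near the typical cell perimeter the
    perimeter contributions stay small, so tensions remain dominated by
    the i.i.d. line-tension draw while the quadratic term makes force
    balance generically attainable and resists cell collapse.  Provides
    exact value/gradient and Hessian-vector products for Newton-type
    minimization.
    """

    def __init__(self, array: CellArray, lam: np.ndarray, gamma: float,
                 rest_perimeter: float = 0.0, eps_fraction: float = 1e-9):
        self.frame = _Frame(array)
        self.lam = lam
        self.gamma = gamma
        self.l0 = rest_perimeter
        self.eps_fraction = eps_fraction
        cidx = {c: k for k, c in enumerate(array.cell_ids)}
        self.ea = np.array([cidx[array.edges[e].cell_pair[0]]
                            for e in array.edge_ids])
        self.eb = np.array([cidx[array.edges[e].cell_pair[1]]
                            for e in array.edge_ids])
        self.n_cells = len(array.cell_ids)
        # smoothing length for sqrt(l^2 + eps^2): a coarse eps keeps the
        # Hessian tame while collapsed edges are still being resolved
        self.eps = eps_fraction * array.mean_edge_length()

    def _geom(self, pos):
        u = self.frame.chords(pos)
        ell = np.sqrt(u[:, 0] ** 2 + u[:, 1] ** 2 + self.eps ** 2)
        perim = (np.bincount(self.ea, ell, self.n_cells)
                 + np.bincount(self.eb, ell, self.n_cells))
        return u, ell, perim

    def _tau(self, perim):
        dev = perim - self.l0
        return self.lam + self.gamma * (dev[self.ea] + dev[self.eb])

    def tensions(self, pos):
        _u, _ell, perim = self._geom(pos)
        return self._tau(perim)

    def forces(self, pos):
        u, ell, perim = self._geom(pos)
        tau = self._tau(perim)
        w = (tau / ell)[:, None] * u
        nv = len(pos)
        ri, rj = self.frame.rows_i, self.frame.rows_j
        f = np.stack([
            np.bincount(ri, w[:, 0], nv) - np.bincount(rj, w[:, 0], nv),
            np.bincount(ri, w[:, 1], nv) - np.bincount(rj, w[:, 1], nv),
        ], axis=1)
        return f

    def fg(self, x):
        pos = x.reshape(-1, 2)
        u, ell, perim = self._geom(pos)
        dev = perim - self.l0
        energy = float(self.lam @ ell + 0.5 * self.gamma * (dev @ dev))
        return energy, -self.forces(pos).ravel()

    def hessp(self, x, p):
        pos = x.reshape(-1, 2)
        u, ell, perim = self._geom(pos)
        tau = self._tau(perim)
        pv = p.reshape(-1, 2)
        dpv = pv[self.frame.rows_j] - pv[self.frame.rows_i]
        udot = (u * dpv).sum(axis=1) / (ell * ell)
        he = (tau / ell)[:, None] * (dpv - u * udot[:, None])
        # rank-one perimeter coupling: Gamma * sum_a (g_a . p) g_a
        dl = (u * dpv).sum(axis=1) / ell  # d l_e along p
        s = (np.bincount(self.ea, dl, self.n_cells)
             + np.bincount(self.eb, dl, self.n_cells))
        coef = self.gamma * (s[self.ea] + s[self.eb])
        he += (coef / ell)[:, None] * u
        nv = len(pv)
        ri, rj = self.frame.rows_i, self.frame.rows_j
        out = np.stack([
            np.bincount(rj, he[:, 0], nv) - np.bincount(ri, he[:, 0], nv),
            np.bincount(rj, he[:, 1], nv) - np.bincount(ri, he[:, 1], nv),
        ], axis=1)
        return out.ravel()


def _loops_of(array: CellArray) -> dict[int, list[int]]:
    return {c: list(array.cells[c].vertex_loop) for c in array.cell_ids}


def _half_edges_ok(loops) -> bool:
    half = set()
    for loop in loops.values():
        for i, j in zip(loop, loop[1:] + loop[:1]):
            if i == j or (i, j) in half:
                return False
            half.add((i, j))
    return all((j, i) in half for (i, j) in half)


def _rebuild(array, positions, loops, lam_by_vpair, rng, lam_dist):
    """CellArray + per-edge line tensions from surgered loops."""
    new = CellArray.from_cell_loops(positions, loops, "toroidal",
                                    box=array.box, validate=False)
    lam = {}
    for eid in new.edge_ids:
        key = frozenset(new.edges[eid].vertex_pair)
        val = lam_by_vpair.get(key)
        if val is None:  # interface created by the swap: fresh draw
            val = float(rng.uniform(*lam_dist))
        lam[eid] = val
    return new, lam


def _third_cell_at(array, vertex, a, b):
    cells = set()
    for k in array.vertex_edges[vertex]:
        cells.update(array.edges[k].cell_pair)
    others = cells - {a, b}
    return others.pop() if len(others) == 1 else None


def _t1_swap(array, lam, eid, rng, lam_dist, delta_frac=0.03,
             redraw=True):
    """Neighbour exchange on a collapsed edge; returns (array, lam) or None.

    With ``redraw=False`` the new interface inherits the smallest line
    tension among the four flanking interfaces (low tension favours the
    rotated edge's stability); otherwise it is drawn fresh.
    """
    e = array.edges[eid]
    i, j = e.vertex_pair
    a, b = e.cell_pair
    c = _third_cell_at(array, i, a, b)
    d = _third_cell_at(array, j, a, b)
    if c is None or d is None or c == d:
        return None
    loops = _loops_of(array)
    if len(loops[a]) <= 3 or len(loops[b]) <= 3:
        return None
    pos = {v: array.vertices[v].position.copy() for v in array.vertex_ids}
    u = array.edge_vector(eid)
    m = pos[i] + 0.5 * u
    uhat = u / np.linalg.norm(u)
    left = np.array([-uhat[1], uhat[0]])
    delta = delta_frac * array.mean_edge_length()
    pos[i] = m + delta * left  # stays with cell a
    pos[j] = m - delta * left  # stays with cell b
    loops[a].remove(j)
    loops[b].remove(i)
    # insert the new i-j interface into cells c and d; the insertion
    # side is fixed by requiring a consistent half-edge pairing
    for cb in (True, False):
        for db in (True, False):
            trial = {k: list(v) for k, v in loops.items()}
            kc = trial[c].index(i)
            trial[c].insert(kc if cb else kc + 1, j)
            kd = trial[d].index(j)
            trial[d].insert(kd if db else kd + 1, i)
            if _half_edges_ok(trial):
                key = {frozenset(array.edges[k].vertex_pair): lam[k]
                       for k in array.edge_ids}
                if redraw:
                    key.pop(frozenset((i, j)), None)  # fresh draw
                else:
                    flanking = [lam[k] for v in (i, j)
                                for k in array.vertex_edges[v] if k != eid]
                    key[frozenset((i, j))] = min(flanking)
                return _rebuild(array, pos, trial, key, rng, lam_dist)
    return None


def _t2_collapse(array, lam, cid, rng, lam_dist):
    """Remove a triangular cell, merging its three vertices into one."""
    loop = array.cells[cid].vertex_loop
    pos = {v: array.vertices[v].position.copy() for v in array.vertex_ids}
    keep = loop[0]
    pos[keep] = array.unwrapped_loop(cid).mean(axis=0) % np.asarray(array.box)
    loops = _loops_of(array)
    del loops[cid]
    for c2, lp in loops.items():
        merged = [keep if v in loop else v for v in lp]
        out = []
        for v in merged:
            if not out or out[-1] != v:
                out.append(v)
        if len(out) > 1 and out[0] == out[-1]:
            out.pop()
        loops[c2] = out
    for v in loop[1:]:
        del pos[v]
    key = {frozenset(array.edges[k].vertex_pair): lam[k]
           for k in array.edge_ids}
    return _rebuild(array, pos, loops, key, rng, lam_dist)


#: edges shorter than this fraction of the mean trigger a T1/T2 event
COLLAPSE_FRACTION = 0.02


def _relax_elastic(array, lam, config, rng, max_rounds=1200):
    """Minimize the elastic energy, resolving edge collapses by T1/T2.

    Returns (equilibrated array, per-edge line tensions).  Between
    Newton rounds, any edge driven below ``COLLAPSE_FRACTION`` of the
    mean edge length undergoes a neighbour exchange (or, for a
    collapsing triangular cell, cell removal); line tensions of newly
    created interfaces are drawn fresh from the configured distribution.
    """
    lam_dist = config.tension_distribution
    gamma = config.perimeter_elasticity
    total_iters = 0
    surgery_budget = 6 * len(array.cell_ids)
    surgery_count = 0
    for _round in range(max_rounds):
        lam_vec = np.array([lam[e] for e in array.edge_ids])
        model = _ElasticModel(array, lam_vec, gamma, config.rest_perimeter)
        tau = model.tensions(array.positions)
        tol = config.convergence_tol * float(tau.mean())
        res = optimize.minimize(
            model.fg, array.positions.ravel(), jac=True, hessp=model.hessp,
            method="trust-ncg",
            options={"gtol": 0.3 * tol, "maxiter": 400},
        )
        total_iters += res.nit
        # do not wrap into the box here: the frame's periodic-image
        # shifts are frozen per round, and wrapping would invalidate them
        array = array.with_positions(res.x.reshape(-1, 2), check=False)
        # one batch of surgeries per round on mutually non-adjacent
        # collapsed edges, shortest first
        ell = array.edge_lengths()
        thresh = COLLAPSE_FRACTION * ell.mean()
        short = np.nonzero(ell < thresh)[0]
        short = short[np.argsort(ell[short])]
        batch = []
        touched: set[int] = set()
        for k in short:
            e = array.edges[array.edge_ids[k]]
            i, j = e.vertex_pair
            a, b = e.cell_pair
            cells = {a, b,
                     _third_cell_at(array, i, a, b),
                     _third_cell_at(array, j, a, b)}
            if cells & touched:
                continue
            touched |= cells
            batch.append(tuple(sorted(e.vertex_pair)))
        surgeries = 0
        for vpair in batch:
            eid = next((k for k in array.edge_ids
                        if tuple(sorted(array.edges[k].vertex_pair)) == vpair),
                       None)
            if eid is None:
                continue
            e = array.edges[eid]
            a, b = e.cell_pair
            la = len(array.cells[a].vertex_loop)
            lb = len(array.cells[b].vertex_loop)
            if min(la, lb) == 3:
                cid = a if la == 3 else b
                array, lam = _t2_collapse(array, lam, cid, rng, lam_dist)
            else:
                out = _t1_swap(array, lam, eid, rng, lam_dist)
                if out is None:
                    continue  # leave for a later round
                array, lam = out
            surgeries += 1
        surgery_count += surgeries
        if surgery_count > surgery_budget:
            raise ConvergenceError(
                "persistent topology churn: the tension draw keeps "
                "collapsing edges faster than neighbour exchanges resolve them"
            )
        if surgeries:
            continue
        if short.size:
            raise ConvergenceError(
                "edge collapse in a configuration admitting no "
                "neighbour exchange"
            )
        f = model.forces(array.positions)
        residual = float(np.hypot(f[:, 0], f[:, 1]).max())
        if residual <= tol:
            # wrap into the box only now, and re-verify with fresh shifts
            array = array.with_positions(
                array.positions % np.asarray(array.box))
            fresh = _ElasticModel(array, lam_vec, gamma,
                                  config.rest_perimeter)
            f = fresh.forces(array.positions)
            if float(np.hypot(f[:, 0], f[:, 1]).max()) > tol:
                continue  # a chord crossed the half-box; one more round
            return array, lam
        if total_iters > config.max_iterations:
            raise ConvergenceError(
                f"relaxation stalled at max net force {residual:.3e} "
                f"(tolerance {tol:.3e})"
            )
    raise ConvergenceError("too many topology-fixing rounds during relaxation")


def generate_voronoi_tissue(
    config: SimulationConfig,
    anisotropy_epsilon: float = 0.0,
    axis_angle: float = 0.0,
) -> tuple[CellArray, MechanicalState]:
    """Relaxed random-tension tissue on a torus, with its true state.

    Seeds a periodic Voronoi tessellation of ``n_cells`` uniform random
    points (mean cell area 1), draws i.i.d. uniform line tensions, and
    relaxes the vertex-model energy (line tension + perimeter
    elasticity, no area term) to force balance.  Pressures are uniform
    (zero) because the energy has no area term.  The returned state
    carries the effective interfacial tensions -- line tension plus the
    perimeter contributions of the two adjacent cells -- evaluated at
    the relaxed geometry; these are the benchmark's ground truth.

    Edges driven to zero length during relaxation undergo T1 neighbour
    exchanges (collapsing triangles are removed), so the final cell
    count can be slightly below ``n_cells``.

    With ``anisotropy_epsilon > 0`` each drawn line tension is
    multiplied by ``1 + eps*cos 2(theta - axis_angle)`` where ``theta``
    is the edge's initial orientation: interfaces aligned with the axis
    get systematically higher tension, emulating planar-polarized
    contractility.
    """
    if config.n_cells < 16:
        raise ValueError("n_cells must be >= 16")
    rng = np.random.default_rng(config.seed)
    Lx = float(np.sqrt(config.n_cells * config.box_aspect))
    Ly = config.n_cells / Lx
    seeds = rng.random((config.n_cells, 2)) * np.array([Lx, Ly])
    try:
        array = _periodic_voronoi(seeds, (Lx, Ly))
    except spatial.QhullError:  # cocircular degeneracy: nudge and retry
        warnings.warn("degenerate Voronoi seeds; perturbing by 1e-9 and retrying")
        seeds = seeds + 1e-9 * rng.standard_normal(seeds.shape)
        array = _periodic_voronoi(seeds, (Lx, Ly))
    low, high = config.tension_distribution
    lam_vec = rng.uniform(low, high, size=len(array.edge_ids))
    if anisotropy_epsilon:
        u = np.array([array.edge_vector(e) for e in array.edge_ids])
        theta = np.arctan2(u[:, 1], u[:, 0])
        lam_vec = lam_vec * (1.0 + anisotropy_epsilon
                             * np.cos(2.0 * (theta - axis_angle)))
        if np.any(lam_vec <= 0):
            raise ValueError("anisotropy modulation produced non-positive "
                             "line tension")
    lam = dict(zip(array.edge_ids, map(float, lam_vec)))
    array, lam = _relax_elastic(array, lam, config, rng)
    model = _ElasticModel(
        array, np.array([lam[e] for e in array.edge_ids]),
        config.perimeter_elasticity, config.rest_perimeter,
    )
    tau = model.tensions(array.positions)
    if np.any(tau <= 0):
        raise ConvergenceError(
            "relaxation produced a non-positive effective tension; "
            "reduce the perimeter elasticity or narrow the tension draw"
        )
    state = MechanicalState(
        dict(zip(array.edge_ids, map(float, tau))),
        {c: 0.0 for c in array.cell_ids},
    )
    # re-validate the surgered topology before handing it out
    array = CellArray(
        array.vertices.values(), array.edges.values(), array.cells.values(),
        "toroidal", box=array.box,
    )
    return array, state


def generate_planar_array(n_cells: int, seed: int = 0,
                          topology_kind: str = "closed") -> CellArray:
    """Random finite planar cell array (closed island or open patch).

    Builds the Voronoi diagram of ``n_cells`` random seeds; unbounded
    cells are closed off by clipping their two infinite ridges at a large
    radius and joining the clip points with a single outer edge against
    the exterior region.  Every vertex is threefold.  With
    ``topology_kind="open"`` the same tiling is treated as a
    field-of-view patch (perimeter vertices unbalanced).
    """
    if n_cells < 4:
        raise ValueError("n_cells must be >= 4")
    rng = np.random.default_rng(seed)
    L = float(np.sqrt(n_cells))
    pts = rng.random((n_cells, 2)) * L
    vor = spatial.Voronoi(pts)
    center = pts.mean(axis=0)
    radius = 2.0 * L
    positions = {k: v for k, v in enumerate(map(np.asarray, vor.vertices))}
    next_id = len(vor.vertices)
    far_of_ridge = {}
    for (p1, p2), simplex in zip(vor.ridge_points, vor.ridge_vertices):
        simplex = np.asarray(simplex)
        if -1 not in simplex:
            continue
        k = simplex[simplex >= 0][0]
        t = pts[p2] - pts[p1]
        t = t / np.linalg.norm(t)
        nrm = np.array([-t[1], t[0]])
        midpoint = 0.5 * (pts[p1] + pts[p2])
        direction = np.sign(np.dot(midpoint - center, nrm)) * nrm
        positions[next_id] = vor.vertices[k] + direction * radius
        far_of_ridge[frozenset((p1, p2))] = next_id
        next_id += 1
    fars_of_point: dict[int, list[int]] = {}
    for key, fid in far_of_ridge.items():
        for p in key:
            fars_of_point.setdefault(p, []).append(fid)
    loops = {}
    for i in range(n_cells):
        region = [v for v in vor.regions[vor.point_region[i]] if v != -1]
        region += fars_of_point.get(i, [])
        rel = np.array([positions[v] for v in region]) - pts[i]
        order = np.argsort(np.arctan2(rel[:, 1], rel[:, 0]))
        loops[i] = [region[k] for k in order]
    used = {v for loop in loops.values() for v in loop}
    positions = {k: v for k, v in positions.items() if k in used}
    return CellArray.from_cell_loops(positions, loops, topology_kind)


def corrupt_vertices(array: CellArray, rms_fraction: float,
                     seed: int = 0) -> CellArray:
    """Displace every vertex by isotropic Gaussian positional noise.

    The per-coordinate standard deviation is chosen so the r.m.s.
    displacement magnitude equals ``rms_fraction`` times the mean edge
    length (sigma = rms * l_mean / sqrt(2)).  Topology is unchanged.
    """
    if rms_fraction < 0:
        raise ValueError("rms_fraction must be >= 0")
    if rms_fraction == 0:
        return array
    rng = np.random.default_rng(seed)
    sigma = rms_fraction * array.mean_edge_length() / np.sqrt(2.0)
    noise = rng.normal(0.0, sigma, size=array.positions.shape)
    return array.with_positions(array.positions + noise)
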