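"""Traction forces, Laplace cross-check, anisotropy and recovery stats."""

import math

import numpy as np
import pytest

import mechinverse as mi
from mechinverse.errors import ValidationError
from mechinverse.validation import acute_angle_to_axis


def corner_continuity_oracle(array, state, edge_id):
    """Independent traction evaluation by solving the corner systems.

    At each threefold vertex with cells (a, b, c) the cortical tensions
    gamma satisfy  gamma_a + gamma_b = T_ab  (one equation per incident
    interface); the traction on <ab> is the change of cell a's cortical
    share between the edge's two corners.
    """
    e = array.edges[edge_id]
    a, b = e.cell_pair

    def gamma_a_at(vertex):
        cells = set()
        for k in array.vertex_edges[vertex]:
            cells.update(array.edges[k].cell_pair)
        cells = sorted(cells)
        assert len(cells) == 3
        idx = {c: i for i, c in enumerate(cells)}
        M = np.zeros((3, 3))
        rhs = np.zeros(3)
        for row, k in enumerate(array.vertex_edges[vertex]):
            x, y = array.edges[k].cell_pair
            M[row, idx[x]] += 1.0
            M[row, idx[y]] += 1.0
            rhs[row] = state.tensions[k]
        return np.linalg.solve(M, rhs)[idx[a]]

    i, j = e.vertex_pair
    return gamma_a_at(j) - gamma_a_at(i)


class TestTractions:
    def test_uniform_tension_gives_zero_traction(self, hex64):
        state = mi.MechanicalState.uniform(hex64, tension=1.7)
        records = mi.compute_tractions(hex64, state)
        assert len(records) == len(hex64.edges)
        assert all(r.traction == 0.0 for r in records)

    def test_matches_corner_continuity_oracle(self, hex64):
        rng = np.random.default_rng(2)
        state = mi.MechanicalState(
            {e: float(t) for e, t in zip(
                hex64.edge_ids, rng.uniform(0.5, 1.5, len(hex64.edge_ids)))},
            {c: 0.0 for c in hex64.cell_ids},
        )
        records = mi.compute_tractions(hex64, state)
        for r in records[:40]:
            oracle = corner_continuity_oracle(hex64, state, r.edge_id)
            assert abs(r.traction - oracle) < 1e-12

    def test_linear_in_tension_scale(self, hex64):
        rng = np.random.default_rng(3)
        t = {e: float(x) for e, x in zip(
            hex64.edge_ids, rng.uniform(0.5, 1.5, len(hex64.edge_ids)))}
        p = {c: 0.0 for c in hex64.cell_ids}
        base = mi.compute_tractions(hex64, mi.MechanicalState(t, p))
        scaled = mi.compute_tractions(
            hex64, mi.MechanicalState({e: 2.5 * v for e, v in t.items()}, p))
        for rb, rs in zip(base, scaled):
            assert np.isclose(rs.traction, 2.5 * rb.traction)

    def test_antisymmetric_under_cell_swap(self, hex64):
        """Swapping which cell is "a" and which is "b" negates the traction;
        the equivalent re-orientation (j,i,b,a) leaves it unchanged."""
        rng = np.random.default_rng(4)
        state = mi.MechanicalState(
            {e: float(t) for e, t in zip(
                hex64.edge_ids, rng.uniform(0.5, 1.5, len(hex64.edge_ids)))},
            {c: 0.0 for c in hex64.cell_ids},
        )
        cells_swapped = mi.CellArray(
            [mi.Vertex(v.id, v.position, v.is_interior)
             for v in hex64.vertices.values()],
            [mi.Edge(e.id, e.vertex_pair,
                     (e.cell_pair[1], e.cell_pair[0]), e.curvature)
             for e in hex64.edges.values()],
            list(hex64.cells.values()), "toroidal", box=hex64.box,
            validate=False)
        reoriented = mi.CellArray(
            [mi.Vertex(v.id, v.position, v.is_interior)
             for v in hex64.vertices.values()],
            [mi.Edge(e.id, (e.vertex_pair[1], e.vertex_pair[0]),
                     (e.cell_pair[1], e.cell_pair[0]), e.curvature)
             for e in hex64.edges.values()],
            list(hex64.cells.values()), "toroidal", box=hex64.box,
            validate=False)
        base = {r.edge_id: r.traction
                for r in mi.compute_tractions(hex64, state)}
        swap = {r.edge_id: r.traction
                for r in mi.compute_tractions(cells_swapped, state)}
        same = {r.edge_id: r.traction
                for r in mi.compute_tractions(reoriented, state)}
        for eid, tau in base.items():
            assert np.isclose(swap[eid], -tau, atol=1e-14)
            assert np.isclose(same[eid], tau, atol=1e-14)

    def test_missing_tension_raises(self, hex64):
        state = mi.MechanicalState.uniform(hex64)
        del state.tensions[hex64.edge_ids[0]]
        with pytest.raises(ValidationError, match="missing tension"):
            mi.compute_tractions(hex64, state)


def laplace_fixture(seed=0, noise=0.0):
    """Hex tissue with random state and curvatures built as dp/T."""
    array = mi.hexagonal_lattice(8, 10)  # 240 edges
    rng = np.random.default_rng(seed)
    state = mi.MechanicalState(
        {e: float(t) for e, t in zip(
            array.edge_ids, rng.uniform(0.8, 1.2, len(array.edge_ids)))},
        {c: float(p) for c, p in zip(
            array.cell_ids, rng.uniform(-0.5, 0.5, len(array.cell_ids)))},
    )
    for eid in array.edge_ids:
        e = array.edges[eid]
        dp = state.pressure_of(e.cell_pair[0]) - state.pressure_of(e.cell_pair[1])
        kappa = dp / state.tensions[eid]
        if noise:
            kappa *= 1.0 + noise * rng.standard_normal()
        e.curvature = kappa
    return array, state


class TestLaplace:
    def test_constructed_consistency_is_exact(self):
        array, state = laplace_fixture()
        check = mi.laplace_check(array, state)
        assert abs(check.r - 1.0) < 1e-9
        assert abs(check.slope - 1.0) < 1e-9
        assert not check.degenerate

    def test_noisy_curvatures_stay_correlated(self):
        array, state = laplace_fixture(seed=1, noise=0.2)
        check = mi.laplace_check(array, state)
        assert len(check.table) >= 200
        assert 0.9 < check.r < 1.0

    def test_zero_variance_flagged_degenerate(self, hex64):
        for e in hex64.edges.values():
            e.curvature = 0.0
        state = mi.MechanicalState.uniform(hex64)
        check = mi.laplace_check(hex64, state)
        assert check.degenerate
        assert math.isnan(check.r)
        for e in hex64.edges.values():
            e.curvature = None

    def test_no_curvatures_raises(self, tissue64):
        array, state = tissue64
        with pytest.raises(ValidationError, match="curvature"):
            mi.laplace_check(array, state)


class TestAnisotropy:
    def test_acute_angle_and_tie_break(self):
        assert np.isclose(acute_angle_to_axis(np.array([1.0, 1.0]), 0.0),
                          math.pi / 4)
        assert np.isclose(acute_angle_to_axis(np.array([-1.0, 1.0]), 0.0),
                          math.pi / 4)
        assert np.isclose(acute_angle_to_axis(np.array([-2.0, 0.0]), 0.0), 0.0)

    def test_exact_threshold_goes_to_transverse_group(self, hex64):
        # with the tissue axis at 45 degrees, the lattice's vertical edge
        # family sits at exactly the 45-degree threshold and must land in
        # the transverse ("at or above threshold") group
        state = mi.MechanicalState.uniform(hex64)
        rep = mi.anisotropy_report(hex64, state, axis_angle=math.pi / 4)
        angles = [acute_angle_to_axis(hex64.edge_vector(e), math.pi / 4)
                  for e in hex64.edge_ids]
        ties = sum(1 for a in angles if abs(a - math.pi / 4) < 1e-9)
        strictly_below = sum(1 for a in angles if a < math.pi / 4 - 1e-9)
        assert ties > 0
        assert rep.aligned_count == strictly_below
        assert rep.transverse_count == len(angles) - strictly_below

    def test_isotropic_tissue_ratio_near_one(self, tissue64):
        array, state = tissue64
        rep = mi.anisotropy_report(array, state, axis_angle=0.0)
        assert abs(rep.ratio - 1.0) < 0.12
        assert rep.aligned_count + rep.transverse_count == len(array.edges)

    def test_empty_group_raises(self):
        array = mi.hexagonal_lattice(4, 4)
        state = mi.MechanicalState.uniform(array)
        # threshold so small every edge is "transverse"
        with pytest.raises(ValidationError, match="empty"):
            mi.anisotropy_report(array, state, threshold_angle=1e-6)


class TestRecoveryScatter:
    def test_identical_states_give_r_one(self, tissue64):
        _, state = tissue64
        r, table = mi.recovery_scatter(state, state)
        assert np.isclose(r, 1.0)
        np.testing.assert_allclose(table["true"], table["inferred"])

    def test_independent_states_uncorrelated(self):
        rng = np.random.default_rng(0)
        eids = range(200)
        a = mi.MechanicalState({e: float(x) for e, x in
                                zip(eids, rng.uniform(0.5, 1.5, 200))}, {})
        b = mi.MechanicalState({e: float(x) for e, x in
                                zip(eids, rng.uniform(0.5, 1.5, 200))}, {})
        r, _ = mi.recovery_scatter(a, b)
        assert abs(r) < 0.2

    def test_mean_one_rescaling(self, tissue64):
        _, state = tissue64
        doubled = mi.MechanicalState(
            {e: 2.0 * t for e, t in state.tensions.items()}, {})
        r, table = mi.recovery_scatter(state, doubled)
        assert np.isclose(r, 1.0)
        assert np.isclose(table["inferred"].mean(), 1.0)

    def test_edge_set_mismatch_raises(self, tissue64):
        _, state = tissue64
        other = mi.MechanicalState(
            {e: t for e, t in list(state.tensions.items())[:-1]}, {})
        with pytest.raises(ValidationError, match="different edges"):
            mi.recovery_scatter(state, other)


class TestBenchmarkCorrelations:
    def test_weak_tension_length_correlation(self, tissue400):
        """Inferred tension shows at most a weak negative trend with edge
        length on the synthetic benchmark: high-tension interfaces shrink
        a little during relaxation, but length never predicts tension."""
        array, _ = tissue400
        sol = mi.solve(mi.assemble(array, "constant_pressure"))
        T = sol.state.tension_vector(array)
        r = np.corrcoef(T, array.edge_lengths())[0, 1]
        assert -0.45 < r < 0.05
        # length explains under a fifth of the tension variance
        assert r * r < 0.2
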