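"""FEM core: energy assembly, analytic forces, FD Hessian, equilibration."""

import numpy as np
import pytest
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from cellstretch import MaterialParams
from cellstretch.solver import (FemModel, LoadCase, SolverOptions,
                                apply_dirichlet, equilibrate,
                                generalized_forces, hessian, reaction_forces,
                                total_energy)
from cellstretch.template import flat_sheet


class TestTotalEnergy:
    def test_zero_at_rest_without_load(self, two_cell_model):
        u = np.zeros((two_cell_model.n_nodes, 3))
        assert total_energy(two_cell_model, u, LoadCase()) == pytest.approx(
            0.0, abs=1e-9)

    def test_pressure_term_is_minus_p_times_volume(self, two_cell_model):
        # at u = 0 the elastic part vanishes, leaving -P * total volume
        u = np.zeros((two_cell_model.n_nodes, 3))
        E = total_energy(two_cell_model, u, LoadCase(pressure=0.5))
        assert E == pytest.approx(-0.5 * 2 * 8000.0, rel=1e-9)

    def test_uniform_stretch_closed_form_on_sheet(self, iso_material):
        # 10% uniaxial stretch of a flat sheet, lam = 0:
        # Pi = mu * eps^2 * (total wall volume)
        sheet = flat_sheet(width=50.0, height=30.0, spacing=10.0, thickness=2.0)
        model = FemModel(sheet, iso_material)
        eps = 0.10
        u = np.zeros((model.n_nodes, 3))
        u[:, 0] = eps * model.verts0[:, 0]
        mu = iso_material.lame[1]
        expected = mu * eps**2 * (50.0 * 30.0 * 2.0)
        assert total_energy(model, u, LoadCase()) == pytest.approx(expected,
                                                                   rel=1e-9)

    def test_inverted_element_reports_error(self, two_cell_model):
        u = np.zeros((two_cell_model.n_nodes, 3))
        # collapse the mesh onto a plane -> degenerate elements
        u[:, 0] = -two_cell_model.verts0[:, 0]
        with pytest.raises(FloatingPointError):
            total_energy(two_cell_model, u, LoadCase())


class TestGeneralizedForces:
    def test_zero_at_rest_without_load(self, two_cell_model):
        u = np.zeros((two_cell_model.n_nodes, 3))
        assert np.allclose(generalized_forces(two_cell_model, u, LoadCase()),
                           0.0, atol=1e-9)

    def test_rigid_translation_leaves_forces_unchanged(self, two_cell_model, rng):
        u = rng.normal(0, 0.02, (two_cell_model.n_nodes, 3))
        load = LoadCase(pressure=0.3)
        g0 = generalized_forces(two_cell_model, u, load)
        g1 = generalized_forces(two_cell_model, u + np.array([3.0, -2.0, 1.0]),
                                load)
        assert np.allclose(g0, g1, atol=1e-9)

    @pytest.mark.parametrize("measure", ["biot", "green"])
    def test_matches_central_differences(self, two_cells, rng, measure):
        # mandatory consistency check of the analytic gradient
        mat = MaterialParams.isotropic(100.0, 0.0, strain_measure=measure)
        model = FemModel(two_cells, mat)
        u = rng.normal(0, 0.03, (model.n_nodes, 3))
        load = LoadCase(pressure=0.3)
        g = generalized_forces(model, u, load).ravel()
        h = 1e-6
        max_rel = 0.0
        for k in rng.choice(3 * model.n_nodes, size=40, replace=False):
            up, um = u.ravel().copy(), u.ravel().copy()
            up[k] += h
            um[k] -= h
            fd = (total_energy(model, up.reshape(-1, 3), load)
                  - total_energy(model, um.reshape(-1, 3), load)) / (2 * h)
            denom = max(np.abs(g).max(), 1e-8)
            max_rel = max(max_rel, abs(fd - g[k]) / denom)
        assert max_rel < 1e-5

    def test_anisotropic_forces_match_differences(self, two_cells, rng):
        mat = MaterialParams.transversely_isotropic(30.0, 100.0)
        model = FemModel(two_cells, mat)
        u = rng.normal(0, 0.03, (model.n_nodes, 3))
        load = LoadCase(pressure=0.1)
        g = generalized_forces(model, u, load).ravel()
        h = 1e-6
        for k in rng.choice(3 * model.n_nodes, size=20, replace=False):
            up, um = u.ravel().copy(), u.ravel().copy()
            up[k] += h
            um[k] -= h
            fd = (total_energy(model, up.reshape(-1, 3), load)
                  - total_energy(model, um.reshape(-1, 3), load)) / (2 * h)
            assert fd == pytest.approx(g[k], rel=1e-4, abs=1e-6)

    def test_numba_and_numpy_routes_agree(self, two_cell_model, rng):
        u = rng.normal(0, 0.05, (two_cell_model.n_nodes, 3))
        load = LoadCase(pressure=0.4)
        E1, g1 = two_cell_model.energy_and_grad(u, load, use_numba=True)
        E2, g2 = two_cell_model.energy_and_grad(u, load, use_numba=False)
        assert E1 == pytest.approx(E2, rel=1e-12)
        assert np.allclose(g1, g2, rtol=1e-10, atol=1e-10)


class TestHessian:
    def test_matches_dense_differences_of_gradient(self, two_cell_model, rng):
        u = rng.normal(0, 0.02, (two_cell_model.n_nodes, 3))
        load = LoadCase(pressure=0.2)
        h = 1e-5
        H = hessian(two_cell_model, u, load, h).toarray()
        g0 = generalized_forces(two_cell_model, u, load).ravel()
        n3 = 3 * two_cell_model.n_nodes
        Hd = np.zeros((n3, n3))
        for k in range(n3):
            up = u.ravel().copy()
            up[k] += h
            Hd[:, k] = (generalized_forces(two_cell_model, up.reshape(-1, 3),
                                           load).ravel() - g0) / h
        Hd = 0.5 * (Hd + Hd.T)
        assert np.abs(H - Hd).max() <= 1e-9 * max(1.0, np.abs(Hd).max())

    def test_nearly_symmetric_before_symmetrization(self, two_cell_model, rng):
        u = rng.normal(0, 0.02, (two_cell_model.n_nodes, 3))
        load = LoadCase(pressure=0.2)
        g0 = generalized_forces(two_cell_model, u, load).ravel()
        h = 1e-5
        n3 = 3 * two_cell_model.n_nodes
        Hraw = np.zeros((n3, n3))
        for k in range(n3):
            up = u.ravel().copy()
            up[k] += h
            Hraw[:, k] = (generalized_forces(two_cell_model,
                                             up.reshape(-1, 3), load).ravel()
                          - g0) / h
        assert (np.abs(Hraw - Hraw.T).max()
                / max(np.abs(Hraw).max(), 1e-12)) < 1e-3

    def test_sparsity_within_node_adjacency(self, two_cell_model, rng):
        u = rng.normal(0, 0.02, (two_cell_model.n_nodes, 3))
        H = hessian(two_cell_model, u, LoadCase(pressure=0.2)).tocoo()
        nbh, _ = two_cell_model._adjacency()
        allowed = {(int(a), int(b)) for a in range(two_cell_model.n_nodes)
                   for b in nbh[a]}
        for r, c, v in zip(H.row, H.col, H.data):
            if v != 0.0:
                assert (r // 3, c // 3) in allowed


class TestDirichlet:
    def test_prescribed_values_applied_exactly(self, two_cell_model):
        load = LoadCase()
        load.fix([0, 1], 0, [0.5, -0.25])
        u = apply_dirichlet(np.zeros(3 * two_cell_model.n_nodes), load,
                            two_cell_model.n_nodes)
        assert u[0, 0] == 0.5
        assert u[1, 0] == -0.25

    def test_conflicting_prescriptions_rejected(self):
        load = LoadCase()
        load.fix([3], 1, 0.1)
        with pytest.raises(ValueError, match="conflicting"):
            load.fix([3], 1, 0.2)

    def test_invalid_node_rejected(self, two_cell_model):
        load = LoadCase()
        load.fix([10 ** 6], 0, 0.0)
        with pytest.raises(ValueError, match="invalid node"):
            load.constrained(two_cell_model.n_nodes)

    def test_reactions_balance_on_stretched_sheet(self, iso_material):
        sheet = flat_sheet(width=60.0, height=30.0, spacing=10.0, thickness=1.0)
        model = FemModel(sheet, iso_material)
        load = LoadCase()
        left, right = sheet.boundary_nodes["left"], sheet.boundary_nodes["right"]
        load.fix(left, 0, 0.0)
        load.fix(right, 0, 6.0)
        load.fix(np.arange(model.n_nodes), 2, 0.0)   # planar problem
        load.fix([0], 1, 0.0)
        state = equilibrate(model, load)
        assert state.converged
        g = generalized_forces(model, state.u, load)
        f_left = g[left, 0].sum()
        f_right = g[right, 0].sum()
        assert f_right == pytest.approx(-f_left, rel=1e-6)


class TestEquilibrate:
    def test_immediate_return_at_equilibrium(self, two_cell_model):
        state = equilibrate(two_cell_model, LoadCase())
        assert state.converged
        assert state.iterations == 0

    def test_small_pressure_inflates_cells(self, two_cell_model):
        state = equilibrate(two_cell_model, LoadCase(pressure=0.05),
                            options=SolverOptions(tol=1e-3))
        V0 = two_cell_model.template.cell_volumes()
        V = two_cell_model.cell_volumes(state.u)
        assert np.all(V > V0)

    def test_energy_non_increasing_over_accepted_steps(self, two_cell_model):
        state = equilibrate(two_cell_model, LoadCase(pressure=0.05),
                            options=SolverOptions(tol=1e-3))
        E = np.array(state.energy_history)
        assert np.all(np.diff(E) <= 1e-9 * (1 + np.abs(E[:-1])))

    def test_unloaded_state_recovered_from_small_guess(self, two_cell_model, rng):
        u0 = rng.normal(0, 1e-4, (two_cell_model.n_nodes, 3))
        load = LoadCase()
        load.fix([0], 0, 0.0)
        load.fix([0], 1, 0.0)
        load.fix([0], 2, 0.0)
        state = equilibrate(two_cell_model, load, u0=u0)
        assert state.converged
        assert np.abs(state.u).max() < 1e-3

    def test_large_dt_update_approaches_newton_step(self, iso_material, rng):
        # one increment of the printed update with dt -> inf equals -H^{-1} g
        sheet = flat_sheet(width=30.0, height=20.0, spacing=10.0, thickness=1.0)
        model = FemModel(sheet, iso_material)
        u = np.zeros((model.n_nodes, 3))
        u[:, 0] = 0.05 * model.verts0[:, 0]
        u += rng.normal(0, 1e-3, u.shape)
        load = LoadCase()
        free = np.zeros(3 * model.n_nodes, dtype=bool)
        free[0::3] = True   # planar in-plane x only
        free[3 * sheet.boundary_nodes["left"]] = False  # anchor: H is PD
        g = generalized_forces(model, u, load).ravel()[free]
        H = hessian(model, u, load)[free][:, free].tocsc()
        newton = spla.spsolve(H, g)
        dt = 1e12
        A = sp.identity(int(free.sum()), format="csc") + dt * H
        step = dt * spla.splu(A).solve(g)
        assert np.allclose(step, newton, rtol=1e-4, atol=1e-10)


class TestReactionForces:
    def test_reactions_in_constraint_order(self, iso_material):
        sheet = flat_sheet(width=30.0, height=20.0, spacing=10.0, thickness=1.0)
        model = FemModel(sheet, iso_material)
        load = LoadCase()
        load.fix(sheet.boundary_nodes["left"], 0, 0.0)
        load.fix(sheet.boundary_nodes["right"], 0, 3.0)
        load.fix(np.arange(model.n_nodes), 2, 0.0)
        load.fix([0], 1, 0.0)
        state = equilibrate(model, load)
        r = reaction_forces(model, state.u, load)
        dofs, _ = load.constrained(model.n_nodes)
        assert r.shape == dofs.shape
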