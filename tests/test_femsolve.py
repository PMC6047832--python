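"""FEM verification: patch test, decay recursion, FD Jacobian, conservation,
manufactured-solution convergence, Newton behaviour, time-step adaptation."""

import numpy as np
import pytest
import scipy.sparse.linalg as spla

from blastosim import (
    ActiveParams,
    DiffusionParams,
    MaterialParams,
    ReactionParams,
    build_shell_mesh,
    compute_cell_frames,
)
from blastosim.femsolve import (
    CoupledAssembler,
    FemSpace,
    NewtonReport,
    ScaledLU,
    SolverControls,
    SystemState,
    TimeStepper,
    advance_time,
    newton_step,
    second_difference_coeffs,
)
from blastosim.shellmesh import ShellMesh


def _box_mesh(nx=2, ny=2, nz=2):
    """Axis-aligned unit-cube mesh posing as a ShellMesh (patch tests)."""
    xs = [np.linspace(0, 1, n + 1) for n in (nx, ny, nz)]
    X, Y, Z = np.meshgrid(*xs, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    nid = np.arange(nodes.shape[0]).reshape(nx + 1, ny + 1, nz + 1)
    conn = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                conn.append(
                    [
                        nid[i, j, k], nid[i + 1, j, k],
                        nid[i + 1, j + 1, k], nid[i, j + 1, k],
                        nid[i, j, k + 1], nid[i + 1, j, k + 1],
                        nid[i + 1, j + 1, k + 1], nid[i, j + 1, k + 1],
                    ]
                )
    conn = np.array(conn, dtype=np.int64)
    return ShellMesh(
        node_coords=nodes, hex_connectivity=conn,
        bio_cell_id=np.zeros(len(conn), dtype=np.int64),
        patch_id=np.zeros(len(conn), dtype=np.int64),
        outer_surface_faces=np.empty((0, 4), dtype=np.int64),
        inner_surface_faces=np.empty((0, 4), dtype=np.int64),
        r_outer=1.0, r_inner=0.5, n_face=1, refine=1,
    )


@pytest.fixture(scope="module")
def box_space():
    return FemSpace(_box_mesh(), order=1)


# ------------------------------------------------------------- basics


def test_space_dof_counts(small_space, small_mesh):
    assert small_space.n_dofs == 4 * small_mesh.n_nodes
    assert small_space.n_u_dofs == 3 * small_mesh.n_nodes


def test_quadrature_weights_positive_and_sum_to_volume(box_space):
    assert np.all(box_space.wdet > 0)
    assert box_space.volume == pytest.approx(1.0, rel=1e-12)


def test_q2_space_counts_and_volume(small_mesh):
    sp2 = FemSpace(small_mesh, order=2)
    # doubled surface lattice, half radial layers
    m2 = 2 * small_mesh.n_face * small_mesh.refine
    assert sp2.n_nodes == (6 * m2 * m2 + 2) * (2 * small_mesh.refine + 1)
    assert sp2.connectivity.shape == (small_mesh.n_elements, 27)
    from blastosim.shellmesh import shell_volume

    # curved Q2 geometry approximates the shell volume better than Q1
    v_exact = shell_volume(150.0, 135.0)
    err1 = abs(FemSpace(small_mesh, order=1).volume - v_exact) / v_exact
    err2 = abs(sp2.volume - v_exact) / v_exact
    assert err2 < err1 / 5


def test_second_difference_exact_for_quadratics():
    dt, dtp = 0.7, 0.3
    f = lambda t: 2.0 + 1.5 * t - 0.8 * t**2
    t = 5.0
    c0, c1, c2 = second_difference_coeffs(dt, dtp)
    acc = c0 * f(t) + c1 * f(t - dt) + c2 * f(t - dt - dtp)
    assert acc == pytest.approx(-1.6, rel=1e-10)


# ------------------------------------------------------------- residual


def test_zero_state_zero_residual(coupled_assembler, small_space):
    n = small_space.n_nodes
    r = coupled_assembler.residual(np.zeros(3 * n), np.zeros(n),
                                   C_old=np.zeros(n), dt=1.0)
    assert np.allclose(r, 0.0, atol=1e-12)


def test_structural_patch_test(box_space, material):
    """Affine displacement, Fa = I: interior structural residual vanishes
    and the stress is constant across elements."""
    asm = CoupledAssembler(box_space, material)
    A = np.array([[0.02, 0.01, 0.0], [0.0, -0.01, 0.005], [0.0, 0.0, 0.015]])
    u = (box_space.node_coords @ A.T).ravel()
    C = np.zeros(box_space.n_nodes)
    r = asm.residual(u, C)
    ru = r[: box_space.n_u_dofs].reshape(-1, 3)
    interior = np.all(
        (box_space.node_coords > 1e-9) & (box_space.node_coords < 1 - 1e-9), axis=1
    )
    assert interior.sum() == 1
    assert np.allclose(ru[interior], 0.0, atol=1e-10)
    kin = asm.kinematics(u, C)
    P = kin["P"].reshape(-1, 9)
    assert np.allclose(P, P[0], atol=1e-10)  # constant stress state


def test_rigid_rotation_equilibrium(small_space, material):
    """A stress-free state rigidly rotated remains at equilibrium."""
    th = 0.3
    R = np.array(
        [[np.cos(th), -np.sin(th), 0.0], [np.sin(th), np.cos(th), 0.0], [0, 0, 1.0]]
    )
    asm = CoupledAssembler(small_space, material)
    u = (small_space.node_coords @ R.T - small_space.node_coords).ravel()
    r = asm.residual(u, np.zeros(small_space.n_nodes))
    scale = material.young_E * asm.h_elem**2
    assert np.abs(r[: small_space.n_u_dofs]).max() < 1e-9 * scale


def test_pure_decay_matches_closed_form(small_space, small_frames, material):
    """D = 0, u stays zero, I3 = 1: implicit Euler gives C = C0/(1+k1 dt)^n."""
    k1 = 3e-3
    asm = CoupledAssembler(
        small_space, material,
        diffusion=DiffusionParams(0.0, 0.0),
        reaction=ReactionParams(k1, 1e-9, 2.0),
        stab_density=1.0,
    )
    ctrl = SolverControls(dt_initial=10.0, dt_target=10.0, newton_tol=1e-12,
                          newton_abs_tol=1e-14, predictor=False)
    stepper = TimeStepper(asm, ctrl)
    rng = np.random.default_rng(3)
    C0 = rng.uniform(0.5, 1.5, small_space.n_nodes)
    state = SystemState.initial(small_space, C0)
    for _ in range(5):
        state, rep = stepper.step(state, 10.0)
        assert rep.converged
    expected = C0 / (1.0 + k1 * 10.0) ** 5
    assert np.allclose(state.C, expected, rtol=1e-9)
    assert np.abs(state.u).max() < 1e-12


# ------------------------------------------------------------- jacobian


def test_jacobian_matches_finite_differences(coupled_assembler, small_space, rng):
    asm = coupled_assembler
    n = small_space.n_nodes
    u = 0.4 * rng.standard_normal(3 * n)
    C = rng.uniform(0.0, 2.0, n)
    C_old = rng.uniform(0.0, 2.0, n)
    kw = dict(C_old=C_old, dt=7.0, u_prev=0.05 * rng.standard_normal(3 * n),
              u_prev2=0.05 * rng.standard_normal(3 * n), dt_prev=5.0)
    J = asm.jacobian(u, C, **kw)
    x0 = np.concatenate([u, C])

    def res(x):
        return asm.residual(x[: 3 * n], x[3 * n :], **kw)

    h = 1e-6
    for _ in range(3):
        d = rng.standard_normal(4 * n)
        d /= np.linalg.norm(d)
        fd = (res(x0 + h * d) - res(x0 - h * d)) / (2 * h)
        an = J @ d
        assert np.linalg.norm(fd - an) / np.linalg.norm(an) < 1e-5


def test_jacobian_sparsity_symmetric_and_mesh_local(coupled_assembler, small_space):
    J = coupled_assembler.jacobian(
        np.zeros(small_space.n_u_dofs),
        np.full(small_space.n_nodes, 0.5),
        C_old=np.full(small_space.n_nodes, 0.5),
        dt=5.0,
    ).tocsr()
    import scipy.sparse as sp

    pat = sp.csr_matrix(
        (np.ones_like(J.data), J.indices, J.indptr), shape=J.shape
    )  # stored-entry pattern (explicit zeros included)
    assert (pat != pat.T).nnz == 0  # structurally symmetric
    # dof coupling only between nodes sharing an element
    n = small_space.n_nodes
    adj = {i: set() for i in range(n)}
    for el in small_space.connectivity:
        for a in el:
            adj[a].update(el)
    coo = J.tocoo()
    node_of = lambda d: d // 3 if d < 3 * n else d - 3 * n
    for r, c in zip(coo.row[::97], coo.col[::97]):  # sampled check
        assert node_of(c) in adj[node_of(r)]


def test_decoupled_blocks_vanish_without_coupling(small_space, material):
    """With no active coupling and no reaction, at the uniform steady state
    both mechanochemical off-diagonal blocks are exactly zero."""
    asm = CoupledAssembler(small_space, material,
                           diffusion=DiffusionParams(1.0, 0.01))
    n = small_space.n_nodes
    C = np.full(n, 0.7)
    J = asm.jacobian(np.zeros(3 * n), C, C_old=C, dt=4.0).tocsr()
    KuC = J[: 3 * n, 3 * n :]
    KCu = J[3 * n :, : 3 * n]
    assert abs(KuC).max() == 0.0  # no Fa(C) dependence at all
    # the transport-vs-u block sees only the (roundoff) gradient of the
    # uniform field; exact zero up to machine precision of grad(C)
    assert abs(KCu).max() < 1e-12 * abs(J).max()


# ------------------------------------------------------------- conservation


def test_mass_conservation_without_reaction(small_space, small_frames, material):
    asm = CoupledAssembler(
        small_space, material,
        diffusion=DiffusionParams(1.0, 0.01),
        stab_density=1.0,
    )
    ctrl = SolverControls(dt_initial=50.0, dt_target=50.0, newton_tol=1e-12,
                          newton_abs_tol=1e-14)
    stepper = TimeStepper(asm, ctrl)
    rng = np.random.default_rng(7)
    state = SystemState.initial(small_space, rng.uniform(0, 1, small_space.n_nodes))
    m0 = asm.total_mass(state.u, state.C)
    for _ in range(10):
        state, rep = stepper.step(state, 50.0)
        assert rep.converged
        m = asm.total_mass(state.u, state.C)
        assert abs(m - m0) / m0 < 1e-8
        m0 = m


def test_radial_mobility_blocks_lateral_transport(material):
    """D_T = 0: transport cannot move mass between radially separated
    columns; a field constant per column stays put."""
    mesh = build_shell_mesh(2, 1, 150.0, 135.0)
    space = FemSpace(mesh, order=1)
    asm = CoupledAssembler(space, material, diffusion=DiffusionParams(1.0, 0.0),
                           stab_density=1.0)
    ctrl = SolverControls(dt_initial=100.0, dt_target=100.0, newton_tol=1e-12,
                          newton_abs_tol=1e-14)
    stepper = TimeStepper(asm, ctrl)
    # radially constant, laterally varying field (function of the unit
    # direction only): radial flux is zero and with D_T = 0 the field is
    # already in (neutral) equilibrium
    xhat = mesh.node_coords[:, 0] / np.linalg.norm(mesh.node_coords, axis=1)
    C0 = np.cos(3.0 * xhat)
    state = SystemState.initial(space, C0)
    for _ in range(3):
        state, _ = stepper.step(state, 100.0)
    assert np.allclose(state.C, C0, atol=1e-10)


# ------------------------------------------------------------- convergence order


from manufactured import manufactured_problem as _manufactured_problem


def test_manufactured_solution_converges_at_second_order(convergence_errors):
    """L2 error of the steady anisotropic-diffusion solve is O(h^2)."""
    errs = convergence_errors
    rate1 = np.log2(errs[0] / errs[1])
    rate2 = np.log2(errs[1] / errs[2])
    assert rate2 > 1.8  # asymptotic O(h^2)
    assert rate1 > 1.5


def test_manufactured_radial_flux_is_neumann_compatible():
    """The manufactured solution has zero radial flux at both shell walls."""
    diff = DiffusionParams(1.0, 0.25)
    mesh = build_shell_mesh(2, 1, 150.0, 135.0)
    space = FemSpace(mesh, order=1)
    exact, _ = _manufactured_problem(space, diff, 1e-3)
    h = 1e-6
    for r in (135.0, 150.0):
        X = np.array([0.3, -0.5, 0.8])
        X = r * X / np.linalg.norm(X)
        N = X / r
        dCdr = (exact(X * (1 + h)) - exact(X * (1 - h))) / (2 * r * h)
        assert abs(dCdr) < 1e-7  # radial derivative -> zero flux D_N * dC/dr


# ------------------------------------------------------------- newton


def test_newton_linear_problem_single_iteration(small_space, material):
    """The decoupled small-strain problem is solved in one Newton step."""
    asm = CoupledAssembler(small_space, material,
                           diffusion=DiffusionParams(1.0, 0.01), stab_density=1.0)
    n = small_space.n_nodes
    C_old = np.random.default_rng(0).uniform(0, 1, n)
    kw = dict(C_old=C_old, dt=20.0)
    x0 = np.zeros(4 * n)
    x0[3 * n :] = C_old

    def rfn(x):
        return asm.residual(x[: 3 * n], x[3 * n :], **kw)

    def jfn(x):
        return asm.jacobian(x[: 3 * n], x[3 * n :], **kw)

    ctrl = SolverControls(newton_tol=1e-10, newton_abs_tol=1e-13, dt_initial=20.0,
                          dt_target=20.0)
    x, rep, _ = newton_step(rfn, jfn, x0, ctrl,
                            norm_fn=lambda r: asm.scaled_norm(r, dt=20.0))
    assert rep.converged and rep.iterations == 1


def test_newton_quadratic_convergence(coupled_assembler, small_space, rng):
    """Residual norms contract quadratically on a smooth nonlinear state."""
    asm = coupled_assembler
    n = small_space.n_nodes
    C_old = rng.uniform(0.5, 1.5, n)
    kw = dict(C_old=C_old, dt=500.0)
    x0 = np.zeros(4 * n)
    x0[3 * n :] = C_old

    def rfn(x):
        return asm.residual(x[: 3 * n], x[3 * n :], **kw)

    def jfn(x):
        return asm.jacobian(x[: 3 * n], x[3 * n :], **kw)

    ctrl = SolverControls(newton_tol=1e-13, newton_abs_tol=1e-16,
                          newton_max_iter=12, jacobian_reuse=False,
                          dt_initial=500.0, dt_target=500.0)
    x, rep, _ = newton_step(rfn, jfn, x0, ctrl,
                            norm_fn=lambda r: asm.scaled_norm(r, dt=500.0))
    norms = rep.residual_norms
    assert len(norms) >= 3
    # quadratic contraction: log-residual gaps grow geometrically
    drops = [norms[i + 1] / norms[i] for i in range(len(norms) - 1) if norms[i] > 1e-14]
    assert min(drops) < 5e-3


def test_newton_rollback_on_inadmissible_state(coupled_assembler, small_space):
    """An inadmissible start state yields a failure report, state unchanged."""
    asm = coupled_assembler
    n = small_space.n_nodes
    x0 = np.zeros(4 * n)
    x0[3 * n :] = 1e6  # inverts the active map everywhere
    kw = dict(C_old=np.zeros(n), dt=1.0)

    def rfn(x):
        return asm.residual(x[: 3 * n], x[3 * n :], **kw)

    def jfn(x):
        return asm.jacobian(x[: 3 * n], x[3 * n :], **kw)

    ctrl = SolverControls(dt_initial=1.0, dt_target=1.0)
    x, rep, _ = newton_step(rfn, jfn, x0, ctrl)
    assert not rep.converged
    assert rep.failure_reason
    assert x is x0


# ------------------------------------------------------------- time adaptivity


def _rep(iters, converged=True):
    return NewtonReport(converged, iters, [1.0])


def test_dt_startup_then_geometric_growth():
    ctrl = SolverControls(dt_initial=1.0, dt_target=32.0, n_startup_steps=20,
                          dt_growth=2.0)
    dt = ctrl.dt_initial
    hist = []
    for step in range(25):
        dt = advance_time(dt, _rep(2), step, ctrl)
        hist.append(dt)
    assert all(d == 1.0 for d in hist[:19])  # startup hold
    assert hist[-1] == 32.0  # 5 doublings after startup
    assert max(hist) <= ctrl.dt_target


def test_dt_halves_on_slow_convergence():
    ctrl = SolverControls(dt_initial=1.0, dt_target=32.0)
    assert advance_time(16.0, _rep(ctrl.slow_iters), 100, ctrl) == 8.0
    assert advance_time(16.0, _rep(3, converged=False), 100, ctrl) == 8.0
    assert advance_time(1.0, _rep(20, converged=False), 100, ctrl) == 1.0  # floor
    assert advance_time(32.0, _rep(2), 100, ctrl) == 32.0  # clamp at target


def test_stabilization_vanishes_at_stationarity(coupled_assembler, small_space):
    n = small_space.n_nodes
    u = np.random.default_rng(1).standard_normal(3 * n)
    state = SystemState(u=u, C=np.zeros(n), u_prev=u.copy(), u_prev2=u.copy(),
                        dt_prev=5.0)
    assert coupled_assembler.stabilization_residual_norm(state, 5.0) < 1e-14


def test_scaled_lu_solves_accurately(coupled_assembler, small_space, rng):
    n = small_space.n_nodes
    C = rng.uniform(0, 1, n)
    J = coupled_assembler.jacobian(np.zeros(3 * n), C, C_old=C, dt=10.0)
    b = rng.standard_normal(4 * n)
    x = ScaledLU(J).solve(b)
    assert np.linalg.norm(J @ x - b) / np.linalg.norm(b) < 1e-10
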