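"""Finite-element discretisation and solution of the coupled system.

Unknowns are the displacement u (vector, Lagrangian) and the morphogen
concentration C (scalar), both continuous Q1 (optionally Q2) isoparametric
fields on the hexahedral shell.  The monolithic residual stacks

* the quasi-static structural equation  -div(F Sigma) = 0 with zero-traction
  (homogeneous Neumann) boundaries, weak form  int grad(phi) : (F Sigma) dX,
  plus a pseudo-inertial stabilisation term  rho_stab * u_tt  discretised by
  a three-level (two-step) second difference — this regularises the six
  rigid-body modes of the pure-Neumann problem and damps the start-up
  transient while vanishing as the solution becomes stationary; and
* the implicit-Euler Lagrangian transport equation
  int phi J (C - C_old)/dt + int grad(phi) . (J F^{-1} D F^{-T}) grad(C)
  - int phi J R(I3(F), C) dX.

The Newton linearisation is consistent: the structural block, the transport
block, and both coupling blocks (structure w.r.t. C through the active
tensor Fa(C); transport w.r.t. u through J, F and I3(F)).

Assembly is vectorised over all elements and quadrature points; the linear
systems are solved by sparse direct factorisation, with optional
factorisation reuse across Newton iterations and time steps (chord Newton)
for the long pattern-formation runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _hex
from .chemcore import diffusion_tensor
from .errors import ElementInversionError, InvertedActiveMapError, ValidationError
from .shellmesh import _surface_lattice

_I3 = np.eye(3)


def _inv_det_3x3(A):
    """Batched analytic inverse and determinant of (..., 3, 3) arrays.

    One pass over the cofactors; noticeably faster than separate
    ``np.linalg.inv`` / ``np.linalg.det`` calls in the assembly hot path.
    """
    a00, a01, a02 = A[..., 0, 0], A[..., 0, 1], A[..., 0, 2]
    a10, a11, a12 = A[..., 1, 0], A[..., 1, 1], A[..., 1, 2]
    a20, a21, a22 = A[..., 2, 0], A[..., 2, 1], A[..., 2, 2]
    c00 = a11 * a22 - a12 * a21
    c01 = a12 * a20 - a10 * a22
    c02 = a10 * a21 - a11 * a20
    det = a00 * c00 + a01 * c01 + a02 * c02
    inv = np.empty_like(A)
    inv[..., 0, 0] = c00
    inv[..., 1, 0] = c01
    inv[..., 2, 0] = c02
    inv[..., 0, 1] = a02 * a21 - a01 * a22
    inv[..., 1, 1] = a00 * a22 - a02 * a20
    inv[..., 2, 1] = a01 * a20 - a00 * a21
    inv[..., 0, 2] = a01 * a12 - a02 * a11
    inv[..., 1, 2] = a02 * a10 - a00 * a12
    inv[..., 2, 2] = a00 * a11 - a01 * a10
    with np.errstate(divide="ignore", invalid="ignore"):
        inv /= det[..., None, None]
    return inv, det


# --------------------------------------------------------------------------
# function space
# --------------------------------------------------------------------------


def _q2_nodes_and_connectivity(mesh):
    """Isoparametric Q2 nodes/elements regenerated from the mesh chart.

    Mid-edge/face/volume nodes are placed exactly by the cube-to-sphere
    chart (doubled surface lattice, half radial layers), so Q2 elements are
    genuinely curved.  Element ordering matches ``mesh.hex_connectivity``.
    """
    n_face, refine = mesh.n_face, mesh.refine
    m2 = 2 * n_face * refine
    keys, grids = _surface_lattice(m2)
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    n_surf = uniq.shape[0]
    sid = inverse[grids]  # (6, m2+1, m2+1)
    dirs = uniq.astype(float) / m2
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radii = np.linspace(mesh.r_inner, mesh.r_outer, 2 * refine + 1)
    nodes = (radii[:, None, None] * dirs[None, :, :]).reshape(-1, 3)

    conn = np.empty((mesh.n_elements, 27), dtype=np.int64)
    # local node ordering is lexicographic: xi0 (u) fastest, then xi1 (v),
    # then xi2 (radial); element ordering mirrors build_shell_mesh.
    e = 0
    for f in range(6):
        for ci in range(n_face):
            for cj in range(n_face):
                for kr in range(refine):
                    for li in range(refine):
                        for lj in range(refine):
                            i0 = 2 * (ci * refine + li)
                            j0 = 2 * (cj * refine + lj)
                            l0 = 2 * kr
                            for c in range(3):
                                for b in range(3):
                                    for a in range(3):
                                        conn[e, c * 9 + b * 3 + a] = (
                                            (l0 + c) * n_surf
                                            + sid[f, i0 + a, j0 + b]
                                        )
                            e += 1
    assert e == mesh.n_elements
    return nodes, conn


@dataclass
class FemSpace:
    """Scalar/vector function space on the shell mesh.

    Precomputes tabulated basis functions, physical basis gradients ``B``,
    quadrature weights ``wdet`` (> 0 on a valid mesh) and quadrature-point
    coordinates ``Xq`` for the whole mesh.
    """

    mesh: object
    order: int = 1
    n_gauss: int = None

    def __post_init__(self):
        if self.order not in (1, 2):
            raise ValidationError("element order must be 1 or 2")
        if self.n_gauss is None:
            self.n_gauss = self.order + 1
        if self.order == 1:
            self.node_coords = self.mesh.node_coords
            self.connectivity = self.mesh.hex_connectivity
        else:
            self.node_coords, self.connectivity = _q2_nodes_and_connectivity(self.mesh)
        qp, qw, N, dN = _hex.tabulate(self.order, self.n_gauss)
        self.qpoints, self.qweights, self.N, self.dN = qp, qw, N, dN
        B, wdet, detJ = _hex.element_geometry(
            self.node_coords, self.connectivity, dN, qw
        )
        if np.any(detJ <= 0.0):
            bad = np.unique(np.where(detJ <= 0.0)[0])
            raise ElementInversionError(
                f"non-positive geometric Jacobian in elements {bad[:5]}",
                elements=bad,
            )
        self.B, self.wdet = B, wdet
        self.Xq = np.einsum("qa,eai->eqi", N, self.node_coords[self.connectivity])

    @property
    def n_nodes(self):
        return self.node_coords.shape[0]

    @property
    def n_u_dofs(self):
        return 3 * self.n_nodes

    @property
    def n_c_dofs(self):
        return self.n_nodes

    @property
    def n_dofs(self):
        return 4 * self.n_nodes

    @property
    def volume(self):
        return float(self.wdet.sum())


# --------------------------------------------------------------------------
# solver controls / state
# --------------------------------------------------------------------------


@dataclass
class SolverControls:
    """Newton, linear-solver and time-step controls.

    ``dt`` values are seconds of model time.  The start-up phase holds the
    small ``dt_initial`` for ``n_startup_steps`` accepted steps (the initial
    conditions u = 0, C = C0 are mutually incompatible), after which dt
    grows geometrically by ``dt_growth`` per fast-converging step up to
    ``dt_target``; slow convergence halves dt (never below ``dt_initial``).
    """

    newton_tol: float = 1e-6
    newton_abs_tol: float = 1e-10
    newton_max_iter: int = 25
    max_backtracks: int = 6
    linear_solver: str = "direct"
    jacobian_reuse: bool = True
    reuse_max_iter: int = 6
    refresh_every: int = 50
    predictor: bool = True
    dt_initial: float = 1.0
    dt_target: float = 20.0
    n_startup_steps: int = 20
    dt_growth: float = 2.0
    slow_iters: int = 8
    stab_density: float = 0.0

    def __post_init__(self):
        if self.newton_tol <= 0 or self.newton_abs_tol <= 0:
            raise ValidationError("tolerances must be positive")
        if self.dt_initial > self.dt_target:
            raise ValidationError("dt_initial must be <= dt_target")
        if self.linear_solver not in ("direct", "iterative"):
            raise ValidationError("linear_solver must be 'direct' or 'iterative'")


@dataclass
class SystemState:
    """Discrete state: displacement/concentration dofs and two history levels."""

    u: np.ndarray
    C: np.ndarray
    u_prev: np.ndarray = None
    u_prev2: np.ndarray = None
    t: float = 0.0
    step: int = 0
    dt_prev: float = None

    @classmethod
    def initial(cls, space, C0):
        n = space.n_nodes
        C0 = np.asarray(C0, dtype=float)
        if C0.shape != (n,):
            raise ValidationError("C0 length must equal the number of nodes")
        return cls(u=np.zeros(3 * n), C=C0.copy())


def second_difference_coeffs(dt, dt_prev):
    """Coefficients (c0, c1, c2) of the variable-step second difference.

    ``u_tt ~ c0 u^n + c1 u^{n-1} + c2 u^{n-2}``; exact for quadratics in t.
    """
    if dt_prev is None:
        dt_prev = dt
    c0 = 2.0 / (dt * (dt + dt_prev))
    c1 = -2.0 / (dt * dt_prev)
    c2 = 2.0 / (dt_prev * (dt + dt_prev))
    return c0, c1, c2


# --------------------------------------------------------------------------
# coupled assembler
# --------------------------------------------------------------------------


class CoupledAssembler:
    """Vectorised residual/Jacobian assembly for the coupled problem.

    Parameters
    ----------
    space : FemSpace
    material : MaterialParams
    diffusion : DiffusionParams or None (radially anisotropic tensor field)
    reaction : ReactionParams or None (R = 0)
    active : ActiveParams or None (Fa = I)
    frames : list of CellFrame, required when ``active`` is given
    stab_density : pseudo-inertial stabilisation coefficient (mass-like,
        per unit volume; Pa s^2 / um^2 in the package unit system)
    diffusion_field : optional callable X -> (3, 3) tensor overriding
        ``diffusion`` (used for verification problems on non-shell meshes)
    """

    def __init__(
        self,
        space,
        material,
        diffusion=None,
        reaction=None,
        active=None,
        frames=None,
        stab_density=0.0,
        stab_damping=1.0,
        diffusion_field=None,
    ):
        self.space = space
        self.material = material
        self.diffusion = diffusion
        self.reaction = reaction
        self.active = active
        self.stab_density = float(stab_density)
        # dimensionless damping weight on the backward velocity difference;
        # suppresses ringing of the soft (long-wavelength) elastic modes that
        # the pure second difference leaves under-damped.  Both stabilisation
        # terms vanish identically at stationarity.
        self.stab_damping = float(stab_damping)

        B, wdet, N, Xq = space.B, space.wdet, space.N, space.Xq
        ne, nq, na, _ = B.shape
        self.ne, self.nq, self.na = ne, nq, na

        if diffusion_field is not None:
            D = np.apply_along_axis(lambda X: np.asarray(diffusion_field(X)), -1, Xq)
            self.D_qp = D.reshape(ne, nq, 3, 3)
        elif diffusion is not None:
            self.D_qp = diffusion_tensor(Xq, diffusion)
        else:
            self.D_qp = np.zeros((ne, nq, 3, 3))

        if active is not None:
            if frames is None:
                raise ValidationError("active coupling requires cell frames")
            mesh = space.mesh
            Qarr = np.stack([f.Q for f in frames])[mesh.bio_cell_id]  # (e,3,3)
            marr = np.stack([f.m for f in frames])[mesh.bio_cell_id]
            Xhat = np.einsum("eij,eqj->eqi", Qarr, Xq - marr[:, None, :])
            Bm = np.zeros((ne, nq, 3, 3))
            Bm[..., 0, 0] = Xhat[..., 2]
            Bm[..., 1, 1] = Xhat[..., 2]
            Bm[..., 0, 2] = Xhat[..., 0]
            Bm[..., 1, 2] = Xhat[..., 1]
            k = active.k_couple
            # Fa = I + C * Ahat in reference coordinates
            self.Ahat = k * np.einsum("eji,eqjk,ekl->eqil", Qarr, Bm, Qarr)
            self.kx2 = k * Xhat[..., 2]
            self._cell_of_element = mesh.bio_cell_id
        else:
            self.Ahat = None

        self._last_kin = None

        # consistent element mass matrices (used by stabilisation & transport)
        self.Me = np.einsum("eq,qa,qb->eab", wdet, N, N)

        # global dof maps: u dofs node-major (3*node + i), C dofs offset 3*n
        conn = space.connectivity
        self.udofs = (3 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(
            ne, 3 * na
        )
        self.cdofs = 3 * space.n_nodes + conn
        self.edofs = np.concatenate([self.udofs, self.cdofs], axis=1)  # (e, 4*na)
        self._coo_rows = np.repeat(self.edofs, 4 * na, axis=1).ravel()
        self._coo_cols = np.tile(self.edofs, (1, 4 * na)).ravel()

        # residual scales for a dimensionless convergence norm
        h3 = wdet.sum() / ne
        self.h_elem = h3 ** (1.0 / 3.0)
        self.ru_scale = material.young_E * self.h_elem**2
        self.rc_scale_base = h3

    # -- kinematics -------------------------------------------------------

    def _active_fields(self, Cq):
        """Fa, H = Fa^-1, Ja, dFa/dC at all quadrature points."""
        ne, nq = self.ne, self.nq
        if self.Ahat is None:
            shape = (ne, nq, 3, 3)
            eye = np.broadcast_to(_I3, shape)
            return eye, eye, np.ones((ne, nq)), None
        if self.active.volume_preserving:
            Ceff = Cq
            wmask = None  # dFa/dC = Ahat everywhere
        else:
            mask = (Cq * self.kx2) < 0.0  # constricting side only
            Ceff = np.where(mask, Cq, 0.0)
            wmask = mask.astype(float)
        tang = 1.0 + Ceff * self.kx2
        if np.any(tang <= 0.0):
            e_bad = int(np.argwhere(tang <= 0.0)[0][0])
            raise InvertedActiveMapError(
                "active map inverted (1 + k C X2 <= 0) in biological cell "
                f"{self._cell_of_element[e_bad]}",
                cell_id=int(self._cell_of_element[e_bad]),
            )
        Fa = _I3 + Ceff[..., None, None] * self.Ahat
        # closed-form inverse: in the cell frame Fa_hat - I is nilpotent up
        # to the tangential scaling, giving Fa^-1 = I - (C/tang) * Ahat
        H = _I3 - (Ceff / tang)[..., None, None] * self.Ahat
        Ja = tang**2  # det Fa, exact for this upper-triangular-structured form
        dFa = self.Ahat if wmask is None else wmask[..., None, None] * self.Ahat
        return Fa, H, Ja, dFa

    def kinematics(self, u, C):
        """All per-quadrature-point kinematic/constitutive fields."""
        sp_ = self.space
        u3 = np.asarray(u, dtype=float).reshape(-1, 3)
        Ce = np.asarray(C, dtype=float)[sp_.connectivity]
        ue = u3[sp_.connectivity]
        B, N = sp_.B, sp_.N
        # batched-BLAS forms of the basis contractions (hot path)
        F = _I3 + np.swapaxes(ue, 1, 2)[:, None, :, :] @ B
        Finv, J = _inv_det_3x3(F)
        if np.any(J <= 0.0):
            bad = np.unique(np.argwhere(J <= 0.0)[:, 0])
            raise ElementInversionError(
                f"element inversion (det F <= 0) in elements {bad[:5]}",
                elements=bad,
            )
        Cq = Ce @ N.T
        gradC = (Ce[:, None, None, :] @ B)[:, :, 0, :]
        Fa, H, Ja, dFa = self._active_fields(Cq)
        Fe = F @ H
        Ee = 0.5 * (np.swapaxes(Fe, -1, -2) @ Fe - _I3)
        lam, mu = self.material.lame_lambda, self.material.lame_mu
        trEe = np.trace(Ee, axis1=-2, axis2=-1)
        Se = lam * trEe[..., None, None] * _I3 + 2.0 * mu * Ee
        Sigma = Ja[..., None, None] * (H @ Se @ np.swapaxes(H, -1, -2))
        P = F @ Sigma
        return dict(
            ue=ue, Ce=Ce, F=F, J=J, Finv=Finv, Cq=Cq, gradC=gradC,
            Fa=Fa, H=H, Ja=Ja, dFa=dFa, Fe=Fe, Ee=Ee, Se=Se, Sigma=Sigma, P=P,
        )

    def _reaction_terms(self, J, Cq):
        """R, dR/dJ and the production-slope factor at quadrature points."""
        if self.reaction is None:
            z = np.zeros_like(J)
            return z, z
        k1 = self.reaction.k1_degradation
        k2 = self.reaction.k2_max_production
        km = self.reaction.km_michaelis
        s = np.maximum(J - 1.0, 0.0)
        R = k2 * s / (km + s) - k1 * Cq
        dR_dJ = np.where(J > 1.0, k2 * km / (km + s) ** 2, 0.0)
        return R, dR_dJ

    # -- residual ---------------------------------------------------------

    def residual(
        self,
        u,
        C,
        *,
        C_old=None,
        dt=None,
        u_prev=None,
        u_prev2=None,
        dt_prev=None,
        source=None,
        kin=None,
    ):
        """Stacked weak-form residual (3 n_nodes + n_nodes vector).

        ``dt=None`` assembles the stationary problem (no transport mass
        term, no stabilisation).  ``source`` is an optional callable
        X -> volumetric morphogen source, used by verification problems.
        """
        sp_ = self.space
        B, N, wdet = sp_.B, sp_.N, sp_.wdet
        if kin is None:
            kin = self.kinematics(u, C)
        self._last_kin = kin  # reused by cheap post-step diagnostics
        ru_el = (
            (B @ np.swapaxes(kin["P"], -1, -2)) * wdet[:, :, None, None]
        ).sum(axis=1)

        if dt is not None and self.stab_density > 0.0:
            c0, c1, c2 = second_difference_coeffs(dt, dt_prev)
            up1 = np.zeros_like(u) if u_prev is None else u_prev
            up2 = up1 if u_prev2 is None else u_prev2
            uf = np.asarray(u, dtype=float)
            gam = self.stab_damping / dt**2
            acc = (
                (c0 + gam) * uf + (c1 - gam) * up1 + c2 * up2
            ).reshape(-1, 3)
            acce = acc[sp_.connectivity]
            ru_el += self.stab_density * (self.Me @ acce)

        J, Cq, gradC, Finv = kin["J"], kin["Cq"], kin["gradC"], kin["Finv"]
        Kmob = J[..., None, None] * (
            Finv @ self.D_qp @ np.swapaxes(Finv, -1, -2)
        )
        flux = (Kmob @ gradC[..., None])[..., 0]
        rc_el = (B @ (wdet[..., None] * flux)[..., None])[..., 0].sum(axis=1)
        R, _ = self._reaction_terms(J, Cq)
        vol_term = -J * R
        if dt is not None:
            if C_old is None:
                raise ValidationError("time-dependent residual requires C_old")
            Cq_old = np.asarray(C_old, dtype=float)[sp_.connectivity] @ N.T
            vol_term = vol_term + J * (Cq - Cq_old) / dt
        if source is not None:
            vol_term = vol_term - source(sp_.Xq)
        rc_el += (wdet * vol_term) @ N

        r = np.zeros(sp_.n_dofs)
        np.add.at(r, self.udofs.ravel(), ru_el.reshape(self.ne, -1).ravel())
        np.add.at(r, self.cdofs.ravel(), rc_el.ravel())
        return r

    # -- jacobian ---------------------------------------------------------

    def jacobian(
        self,
        u,
        C,
        *,
        C_old=None,
        dt=None,
        u_prev=None,
        u_prev2=None,
        dt_prev=None,
        kin=None,
    ):
        """Consistent tangent of :meth:`residual` as a sparse CSC matrix."""
        sp_ = self.space
        B, N, wdet = sp_.B, sp_.N, sp_.wdet
        ne, nq, na = self.ne, self.nq, self.na
        if kin is None:
            kin = self.kinematics(u, C)
        F, J, Finv = kin["F"], kin["J"], kin["Finv"]
        H, Ja, Fe, Se, Sigma = kin["H"], kin["Ja"], kin["Fe"], kin["Se"], kin["Sigma"]
        Cq, gradC, dFa = kin["Cq"], kin["gradC"], kin["dFa"]
        lam, mu = self.material.lame_lambda, self.material.lame_mu

        # ---- structural block: dP_ij/dF_kl contracted with basis gradients.
        # dP/dF = delta_ik Sigma_lj + F_im D2_mjkl with
        # D2 = Ja [ lam G_kl Y_mj + mu (Z_mk Y_lj + Y_ml Z_jk) ]; every term
        # is separable in the (aj)/(bl) basis indices, so the element
        # stiffness is built from small rank-structured products instead of
        # a materialised rank-6 tensor.
        Ht = np.swapaxes(H, -1, -2)
        Y = H @ Ht
        G = Fe @ Ht                      # G_kl = Fe_kp H_lp
        Z = H @ np.swapaxes(Fe, -1, -2)  # Z_mk = H_mp Fe_kp
        JaL = lam * Ja
        JaM = mu * Ja
        FY = F @ Y
        FZ = F @ Z
        BS = np.einsum("eqbl,eqlj->eqbj", B, Sigma)      # geometric term
        S0 = np.einsum("eqaj,eqbj->eqab", B, BS)
        P1 = np.einsum("eqaj,eqij->eqai", B, FY)
        P2 = np.einsum("eqbl,eqkl->eqbk", B, G)
        BY = np.einsum("eqaj,eqlj->eqal", B, Y)
        T2 = np.einsum("eqal,eqbl->eqab", BY, B)
        BZ = np.einsum("eqaj,eqjk->eqak", B, Z)
        P3 = np.einsum("eqbl,eqil->eqbi", B, FY)
        Kuu = np.einsum("eq,eqai,eqbk->eaibk", wdet * JaL, P1, P2)
        Kuu += np.einsum("eq,eqab,eqik->eaibk", wdet * JaM, T2, FZ)
        Kuu += np.einsum("eq,eqak,eqbi->eaibk", wdet * JaM, BZ, P3)
        geo = np.einsum("eq,eqab->eab", wdet, S0)
        for i in range(3):
            Kuu[:, :, i, :, i] += geo
        if dt is not None and self.stab_density > 0.0:
            c0, _, _ = second_difference_coeffs(dt, dt_prev)
            stab = self.stab_density * (c0 + self.stab_damping / dt**2)
            for i in range(3):
                Kuu[:, :, i, :, i] += stab * self.Me

        # ---- coupling: structure w.r.t. concentration ----
        if dFa is not None:
            dH = -H @ dFa @ H
            trHdFa = np.einsum("eqij,eqji->eq", H, dFa)
            dJa = Ja * trHdFa
            dFe = F @ dH
            dEe = 0.5 * (
                np.swapaxes(Fe, -1, -2) @ dFe + np.swapaxes(dFe, -1, -2) @ Fe
            )
            trdEe = np.trace(dEe, axis1=-2, axis2=-1)
            dSe = lam * trdEe[..., None, None] * _I3 + 2.0 * mu * dEe
            dSigma = (
                dJa[..., None, None] * (H @ Se @ Ht)
                + Ja[..., None, None]
                * (dH @ Se @ Ht + H @ dSe @ Ht + H @ Se @ np.swapaxes(dH, -1, -2))
            )
            dP = F @ dSigma
            KuC = np.einsum("eq,eqij,eqaj,qb->eaib", wdet, dP, B, N)
        else:
            KuC = np.zeros((ne, na, 3, na))

        # ---- transport block and its u-coupling ----
        D = self.D_qp
        Kmob = J[..., None, None] * (Finv @ D @ np.swapaxes(Finv, -1, -2))
        KCC = np.einsum("eq,eqai,eqij,eqbj->eab", wdet, B, Kmob, B)
        R, dR_dJ = self._reaction_terms(J, Cq)
        if self.reaction is not None:
            k1 = self.reaction.k1_degradation
            KCC += np.einsum("eq,qa,qb->eab", wdet * J * k1, N, N)
        if dt is not None:
            KCC += np.einsum("eq,qa,qb->eab", wdet * J / dt, N, N)

        W = B @ Finv  # W[e,q,b,j] = B_bl Finv_lj   (dJ/dF direction weights)
        Kg = np.einsum("eqij,eqj->eqi", Kmob, gradC)
        FTg = np.einsum("eqji,eqj->eqi", Finv, gradC)  # (F^{-T} gradC)
        v1 = np.einsum("eqij,eqj->eqi", D, FTg)
        s1 = np.einsum("eqbj,eqj->eqb", W, v1)
        Dw = np.einsum("eqij,eqbj->eqbi", D, W)
        v2 = np.einsum("eqij,eqbj->eqbi", Finv, Dw)
        dKg = (
            np.einsum("eqbj,eqi->eqbji", W, Kg)
            - J[..., None, None, None]
            * (
                np.einsum("eqij,eqb->eqbji", Finv, s1)
                + np.einsum("eqbi,eqj->eqbji", v2, FTg)
            )
        )
        KCu = np.einsum("eq,eqai,eqbji->eabj", wdet, B, dKg, optimize=True)
        coeff_r = J * (R + J * dR_dJ)  # d(J R)/dF contracted with J F^{-T}
        KCu -= np.einsum("eq,qa,eqbj->eabj", wdet * coeff_r, N, W)
        if dt is not None:
            Cq_old = np.einsum(
                "qa,ea->eq", N, np.asarray(C_old, dtype=float)[sp_.connectivity]
            )
            coeff_m = J * (Cq - Cq_old) / dt
            KCu += np.einsum("eq,qa,eqbj->eabj", wdet * coeff_m, N, W)

        # ---- element matrix and global scatter ----
        ndof = 4 * na
        Kel = np.zeros((ne, ndof, ndof))
        Kel[:, : 3 * na, : 3 * na] = Kuu.reshape(ne, 3 * na, 3 * na)
        Kel[:, : 3 * na, 3 * na :] = KuC.reshape(ne, 3 * na, na)
        Kel[:, 3 * na :, : 3 * na] = KCu.reshape(ne, na, 3 * na)
        Kel[:, 3 * na :, 3 * na :] = KCC
        K = sp.coo_matrix(
            (Kel.ravel(), (self._coo_rows, self._coo_cols)),
            shape=(sp_.n_dofs, sp_.n_dofs),
        )
        return K.tocsc()

    # -- diagnostics ------------------------------------------------------

    def scaled_norm(self, r, dt=None):
        """Dimensionless residual norm mixing the two physical blocks."""
        nu = 3 * self.space.n_nodes
        ru = r[:nu]
        rc = r[nu:]
        rc_scale = self.rc_scale_base * max(
            self.reaction.k1_degradation if self.reaction else 0.0,
            1.0 / dt if dt else 0.0,
            1e-12,
        )
        return float(
            np.sqrt(
                np.mean((ru / self.ru_scale) ** 2) + np.mean((rc / rc_scale) ** 2)
            )
        )

    def total_mass(self, u, C, kin=None, reuse_last=False):
        """Deformed-configuration morphogen mass  int_Omega J C dX.

        ``reuse_last=True`` reuses the kinematic fields of the most recent
        residual evaluation (valid right after an accepted step).
        """
        if kin is None:
            kin = self._last_kin if reuse_last else self.kinematics(u, C)
        return float(np.einsum("eq,eq,eq->", self.space.wdet, kin["J"], kin["Cq"]))

    def stabilization_residual_norm(self, state, dt):
        """Norm of the stabilisation term alone (vanishes at stationarity)."""
        if self.stab_density == 0.0 or state.u_prev is None:
            return 0.0
        c0, c1, c2 = second_difference_coeffs(dt, state.dt_prev)
        gam = self.stab_damping / dt**2
        up2 = state.u_prev if state.u_prev2 is None else state.u_prev2
        acc = (
            (c0 + gam) * state.u + (c1 - gam) * state.u_prev + c2 * up2
        ).reshape(-1, 3)
        acce = acc[self.space.connectivity]
        rstab = self.stab_density * np.einsum("eab,ebi->eai", self.Me, acce)
        r = np.zeros(self.space.n_u_dofs)
        np.add.at(
            r,
            self.udofs.ravel(),
            rstab.reshape(self.ne, -1).ravel(),
        )
        return float(np.sqrt(np.mean((r / self.ru_scale) ** 2)))


# -- spec-style functional wrappers ---------------------------------------


def assemble_coupled_residual(assembler, state, dt, source=None):
    """Residual at a :class:`SystemState` (convenience wrapper)."""
    return assembler.residual(
        state.u,
        state.C,
        C_old=getattr(state, "C_old", state.C),
        dt=dt,
        u_prev=state.u_prev,
        u_prev2=state.u_prev2,
        dt_prev=state.dt_prev,
        source=source,
    )


def assemble_jacobian(assembler, state, dt):
    """Consistent tangent at a :class:`SystemState` (convenience wrapper)."""
    return assembler.jacobian(
        state.u,
        state.C,
        C_old=getattr(state, "C_old", state.C),
        dt=dt,
        u_prev=state.u_prev,
        u_prev2=state.u_prev2,
        dt_prev=state.dt_prev,
    )


# --------------------------------------------------------------------------
# Newton solver
# --------------------------------------------------------------------------


class ScaledLU:
    """Sparse LU of a symmetrically equilibrated matrix.

    The coupled Jacobian mixes stress-scale (structural) and
    concentration-scale (transport) rows; symmetric diagonal scaling before
    factorisation keeps SuperLU's pivoting on the diagonal so the
    fill-reducing ordering survives.  Solves are accurate to machine
    precision on the tested problems (the scaling is exact arithmetic).
    """

    def __init__(self, K):
        K = K.tocsc()
        d = np.abs(K.diagonal())
        d[d == 0.0] = 1.0
        self._s = 1.0 / np.sqrt(d)
        S = sp.diags(self._s)
        self._lu = spla.splu(
            (S @ K @ S).tocsc(),
            permc_spec="MMD_AT_PLUS_A",
            options=dict(SymmetricMode=True, DiagPivotThresh=0.01),
        )

    def solve(self, b):
        return self._s * self._lu.solve(self._s * b)


@dataclass
class NewtonReport:
    """Outcome of one nonlinear solve."""

    converged: bool
    iterations: int
    residual_norms: list
    refactorizations: int = 0
    failure_reason: str = None

    @property
    def slow(self):
        return (not self.converged) or self.iterations > 3


def newton_step(residual_fn, jacobian_fn, x0, controls, *, norm_fn=None, lu=None):
    """Damped (backtracking) Newton iteration with optional factorisation reuse.

    Returns ``(x, report, lu)``.  On failure the returned ``x`` is the
    unmodified ``x0`` (rollback contract) and ``report.converged`` is False;
    the report carries the residual history so a driver can distinguish slow
    convergence from breakdown.  Inadmissible trial states (element
    inversion, inverted active map) are rejected by the line search; an
    inadmissible ``x0`` fails immediately.
    """
    if norm_fn is None:
        norm_fn = lambda r: float(np.linalg.norm(r))
    x = np.array(x0, dtype=float)
    try:
        r = residual_fn(x)
    except (ElementInversionError, InvertedActiveMapError) as exc:
        return x0, NewtonReport(False, 0, [], failure_reason=str(exc)), lu
    norm = norm_fn(r)
    norms = [norm]
    tol = max(controls.newton_tol * norm, controls.newton_abs_tol)
    if norm <= controls.newton_abs_tol:
        return x, NewtonReport(True, 0, norms), lu
    refact = 0
    fresh = False  # True while `lu` was factorised at the current iterate
    it = 0
    while it < controls.newton_max_iter:
        it += 1
        if lu is None or not controls.jacobian_reuse:
            lu = ScaledLU(jacobian_fn(x))
            refact += 1
            fresh = True
        du = lu.solve(r)
        alpha = 1.0
        accepted = False
        for _ in range(controls.max_backtracks + 1):
            try:
                r_new = residual_fn(x - alpha * du)
            except (ElementInversionError, InvertedActiveMapError):
                alpha *= 0.5
                continue
            norm_new = norm_fn(r_new)
            if norm_new < norm or norm_new <= tol:
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            if not fresh:
                lu = None  # stale factorisation: refresh and retry
                it -= 1
                continue
            return (
                x0,
                NewtonReport(
                    False, it, norms, refact, failure_reason="line search failed"
                ),
                lu,
            )
        x = x - alpha * du
        r, norm = r_new, norm_new
        norms.append(norm)
        if norm <= tol:
            return x, NewtonReport(True, it, norms, refact), lu
        if not fresh and norms[-1] / norms[-2] > 0.85:
            lu = None  # chord iteration near-stagnant: force refactorisation
        fresh = False
    return (
        x0,
        NewtonReport(
            False,
            controls.newton_max_iter,
            norms,
            refact,
            failure_reason="maximum Newton iterations reached",
        ),
        lu,
    )


def advance_time(dt, report, step_index, controls):
    """Next time step from the last convergence report.

    Holds ``dt_initial`` during start-up, then grows dt geometrically on
    fast convergence (<= 3 iterations) up to ``dt_target``; halves (not
    below ``dt_initial``) on slow convergence.  Deterministic given the
    report sequence.
    """
    if (not report.converged) or report.iterations >= controls.slow_iters:
        return max(dt / 2.0, controls.dt_initial)
    if step_index < controls.n_startup_steps:
        return dt
    if report.iterations <= 3:
        return min(dt * controls.dt_growth, controls.dt_target)
    return dt


# --------------------------------------------------------------------------
# time stepper
# --------------------------------------------------------------------------


class TimeStepper:
    """Implicit time marching of the coupled system with LU reuse."""

    def __init__(self, assembler, controls):
        self.assembler = assembler
        self.controls = controls
        self._lu = None
        self._lu_dt = None
        self._lu_age = 0
        self._prev_x = None  # pre-step dof vector of the last accepted step

    def _invalidate_if_needed(self, dt):
        if self._lu is None:
            return
        if self._lu_dt != dt or self._lu_age >= self.controls.refresh_every:
            self._lu = None

    def step(self, state, dt):
        """Attempt one implicit step of size dt; returns (new_state, report)."""
        asm = self.assembler
        ctrl = self.controls
        nu = asm.space.n_u_dofs
        x0 = np.concatenate([state.u, state.C])
        kw = dict(
            C_old=state.C,
            dt=dt,
            u_prev=state.u,
            u_prev2=state.u_prev,
            dt_prev=state.dt_prev,
        )

        def residual_fn(x):
            return asm.residual(x[:nu], x[nu:], **kw)

        def jacobian_fn(x):
            return asm.jacobian(x[:nu], x[nu:], **kw)

        self._invalidate_if_needed(dt)
        if not ctrl.jacobian_reuse:
            self._lu = None
        # linear extrapolation of the previous step as the Newton start guess
        x_start = x0
        if (
            ctrl.predictor
            and self._prev_x is not None
            and state.dt_prev is not None
        ):
            x_start = x0 + (dt / state.dt_prev) * (x0 - self._prev_x)
        norm_fn = lambda r: asm.scaled_norm(r, dt=dt)
        x, report, lu = newton_step(
            residual_fn, jacobian_fn, x_start, ctrl, norm_fn=norm_fn, lu=self._lu
        )
        if not report.converged and x_start is not x0:
            x, report, lu = newton_step(
                residual_fn, jacobian_fn, x0, ctrl, norm_fn=norm_fn, lu=lu
            )
        if ctrl.jacobian_reuse:
            self._lu = lu
            if report.refactorizations:
                self._lu_dt, self._lu_age = dt, 0
            else:
                self._lu_age += 1
            if report.iterations > ctrl.reuse_max_iter:
                self._lu = None
        if not report.converged:
            return state, report
        self._prev_x = x0
        new = SystemState(
            u=x[:nu],
            C=x[nu:],
            u_prev=state.u.copy(),
            u_prev2=None if state.u_prev is None else state.u_prev.copy(),
            t=state.t + dt,
            step=state.step + 1,
            dt_prev=dt,
        )
        return new, report


# --------------------------------------------------------------------------
# verification helpers
# --------------------------------------------------------------------------


def solve_steady_transport(space, diffusion=None, k1=0.0, source=None,
                           diffusion_field=None):
    """Solve  -div(D grad C) + k1 C = f  on the reference mesh (u = 0).

    A linear scalar solve used by the manufactured-solution convergence
    study; ``k1 > 0`` removes the pure-Neumann nullspace.
    """
    B, N, wdet, Xq = space.B, space.N, space.wdet, space.Xq
    if diffusion_field is not None:
        D = np.apply_along_axis(lambda X: np.asarray(diffusion_field(X)), -1, Xq)
        D = D.reshape(B.shape[0], B.shape[1], 3, 3)
    elif diffusion is not None:
        D = diffusion_tensor(Xq, diffusion)
    else:
        raise ValidationError("a diffusion model is required")
    KCC = np.einsum("eq,eqai,eqij,eqbj->eab", wdet, B, D, B)
    KCC += np.einsum("eq,qa,qb->eab", wdet * k1, N, N)
    fe = np.einsum("eq,qa,eq->ea", wdet, N, source(Xq))
    conn = space.connectivity
    na = conn.shape[1]
    rows = np.repeat(conn, na, axis=1).ravel()
    cols = np.tile(conn, (1, na)).ravel()
    K = sp.coo_matrix((KCC.ravel(), (rows, cols)), shape=(space.n_nodes,) * 2)
    rhs = np.zeros(space.n_nodes)
    np.add.at(rhs, conn.ravel(), fe.ravel())
    return spla.spsolve(K.tocsc(), rhs)


def l2_error(space, C, exact):
    """Quadrature L2 norm of (C_h - exact) over the mesh."""
    Ce = np.asarray(C)[space.connectivity]
    Cq = np.einsum("qa,ea->eq", space.N, Ce)
    diff = Cq - exact(space.Xq)
    return float(np.sqrt(np.einsum("eq,eq->", space.wdet, diff**2)))
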