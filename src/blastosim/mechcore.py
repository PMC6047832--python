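"""Pointwise continuum-mechanics kernels.

The tissue is a compressible, isotropic Saint-Venant-Kirchhoff solid with a
multiplicative split of the deformation gradient, F = Fe Fa: the active part
Fa maps to a stress-free intermediate configuration (morphogen-induced
apical or basal constriction of a biological cell), and only the elastic
accommodation Fe generates stress,

    Ee      = (Fe^T Fe - I) / 2
    Sigma_e = lambda tr(Ee) I + 2 mu Ee
    Sigma   = Ja Fa^{-1} Sigma_e Fa^{-T}
    P       = F Sigma.

The active tensor is defined per biological cell in the cell's local frame
(third axis radially outward, origin at the cell centroid):

    Fa_hat = [[1 + k C X2, 0,          k C X0],
              [0,          1 + k C X2, k C X1],
              [0,          0,          1     ]]

i.e. the gradient of the map (X0 (1 + k C X2), X1 (1 + k C X2), X2).
With the radially-outward convention, k > 0 shrinks the tangential extent
on the lumen-facing side (X2 < 0): apical constriction; k < 0 constricts
the outward-facing side: basal constriction.  det(Fa_hat) = (1 + k C X2)^2,
so the cell-integrated active volume change cancels at first order in kC
(the centroid sits at the local origin); the residual defect is of order
(kC h / 2)^2 with h the cell's radial extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvertedActiveMapError, ValidationError

_I3 = np.eye(3)


def lame_constants(young_E, poisson_nu):
    """Convert (E, nu) to the Lame constants (lambda, mu)."""
    if young_E <= 0.0:
        raise ValidationError("Young's modulus must be positive")
    if not (-1.0 < poisson_nu < 0.5):
        raise ValidationError(
            "Poisson's ratio must lie in (-1, 0.5); the incompressible limit "
            "nu = 0.5 is not supported by this compressible model"
        )
    lam = young_E * poisson_nu / ((1.0 + poisson_nu) * (1.0 - 2.0 * poisson_nu))
    mu = young_E / (2.0 * (1.0 + poisson_nu))
    return lam, mu


@dataclass
class MaterialParams:
    """Isotropic Saint-Venant-Kirchhoff material (stresses in Pa)."""

    young_E: float
    poisson_nu: float
    lame_lambda: float = field(default=None)
    lame_mu: float = field(default=None)

    def __post_init__(self):
        lam, mu = lame_constants(self.young_E, self.poisson_nu)
        if self.lame_lambda is None:
            self.lame_lambda = lam
        if self.lame_mu is None:
            self.lame_mu = mu
        if not (
            np.isclose(self.lame_lambda, lam, rtol=1e-10)
            and np.isclose(self.lame_mu, mu, rtol=1e-10)
        ):
            raise ValidationError("Lame constants inconsistent with (E, nu)")


@dataclass
class ActiveParams:
    """Morphogen -> constriction coupling.

    ``k_couple`` has units 1 / (um * unit concentration); its sign selects
    the constricted side (k > 0 apical/lumen-facing, k < 0 basal/outward).
    ``volume_preserving`` selects the two-sided constriction/expansion form;
    if False, the one-sided variant is used (constriction without active
    expansion of the other cell side, det Fa <= 1 where active).
    """

    k_couple: float
    volume_preserving: bool = True

    def __post_init__(self):
        if not np.isfinite(self.k_couple):
            raise ValidationError("k_couple must be finite")


def _shear_basis(X_hat):
    """B with Fa_hat = I + k C B; B = d/dC [grad of the constriction map] / k."""
    x0, x1, x2 = X_hat
    return np.array([[x2, 0.0, x0], [0.0, x2, x1], [0.0, 0.0, 0.0]])


def active_tensor_local(X_hat, C, params, cell_id=None):
    """Local constriction tensor Fa_hat(X_hat, C) (volume-preserving form)."""
    X_hat = np.asarray(X_hat, dtype=float)
    kc = params.k_couple * C
    if 1.0 + kc * X_hat[2] <= 0.0:
        raise InvertedActiveMapError(
            f"active map inverted: 1 + k C X2 = {1.0 + kc * X_hat[2]:.3g} <= 0"
            + (f" in biological cell {cell_id}" if cell_id is not None else ""),
            cell_id=cell_id,
        )
    return _I3 + kc * _shear_basis(X_hat)


def active_tensor_local_nonpreserving(X_hat, C, params, cell_id=None):
    """One-sided constriction: the actively expanding cell side stays passive.

    Tangential diagonal entries are min(1 + k C X2, 1) with the matching
    shear column, so det(Fa_hat) <= 1 wherever constriction is engaged and
    Fa_hat = I on the other side of the cell.
    """
    X_hat = np.asarray(X_hat, dtype=float)
    kc = params.k_couple * C
    if kc * X_hat[2] >= 0.0:
        return _I3.copy()
    return active_tensor_local(X_hat, C, params, cell_id=cell_id)


def active_tensor(X, C, frame, params):
    """Active tensor in reference coordinates: Fa = Q^T Fa_hat(Q X - Q m, C) Q.

    Piecewise-defined: discontinuous across biological-cell boundaries.
    """
    X = np.asarray(X, dtype=float)
    X_hat = frame.Q @ X - frame.Q @ frame.m
    local = (
        active_tensor_local
        if params.volume_preserving
        else active_tensor_local_nonpreserving
    )
    Fa_hat = local(X_hat, C, params, cell_id=frame.cell_id)
    return frame.Q.T @ Fa_hat @ frame.Q


@dataclass
class DeformationState:
    """Kinematic and constitutive tensors at one material point."""

    F: np.ndarray
    Fa: np.ndarray
    Fe: np.ndarray
    C_right: np.ndarray
    Ee: np.ndarray
    Sigma_e: np.ndarray
    Sigma: np.ndarray
    P: np.ndarray
    J: float
    Ja: float


def svk_stress(F, Fa, mat):
    """Full constitutive evaluation from (F, Fa).

    Computes Fe = F Fa^{-1}, the elastic Green-Lagrange strain, the elastic
    and pulled-back second Piola-Kirchhoff stresses and the first
    Piola-Kirchhoff stress P = F Sigma.
    """
    F = np.asarray(F, dtype=float)
    Fa = np.asarray(Fa, dtype=float)
    Ja = np.linalg.det(Fa)
    if abs(Ja) < 1e-300:
        raise ValidationError("active tensor Fa is not invertible")
    H = np.linalg.inv(Fa)
    Fe = F @ H
    Ee = 0.5 * (Fe.T @ Fe - _I3)
    Se = mat.lame_lambda * np.trace(Ee) * _I3 + 2.0 * mat.lame_mu * Ee
    Sigma = Ja * H @ Se @ H.T
    return DeformationState(
        F=F,
        Fa=Fa,
        Fe=Fe,
        C_right=F.T @ F,
        Ee=Ee,
        Sigma_e=Se,
        Sigma=Sigma,
        P=F @ Sigma,
        J=float(np.linalg.det(F)),
        Ja=float(Ja),
    )


def tensor_invariants(T):
    """Principal invariants (I1, I2, I3) = (tr T, (tr^2 T - tr T^2)/2, det T)."""
    T = np.asarray(T, dtype=float)
    i1 = np.trace(T)
    i2 = 0.5 * (i1 * i1 - np.trace(T @ T))
    i3 = np.linalg.det(T)
    return float(i1), float(i2), float(i3)
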