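"""Morphogen transport and reaction kernels.

Diffusion is anisotropic in the Lagrangian frame: fast along the radial
(intracellular, apico-basal) direction and slow tangentially (across
biological-cell boundaries),

    D(X) = D_N N N^T + D_T (I - N N^T),      N = X / |X|.

Transport is formulated on the reference domain; the mobility pulled back
through a deformation F is J F^{-1} D F^{-T}.

The reaction couples tissue stretch to morphogen production through
saturating Michaelis-Menten kinetics of the volume-change invariant
I3(F) = det F,

    R = k2 s / (km + s) - k1 C,   s = max(I3(F) - 1, 0),

so production is off under compression, reaches k2/2 at s = km and
saturates at k2 under extreme stretch; k1 is a uniform degradation rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .shellmesh import radial_direction

_I3 = np.eye(3)


@dataclass
class DiffusionParams:
    """Diffusion coefficients in um^2/s (radial/intracellular vs lateral)."""

    D_normal: float = 1.0
    D_tangential: float = 0.01

    def __post_init__(self):
        if self.D_normal < 0.0 or self.D_tangential < 0.0:
            raise ValidationError("diffusion coefficients must be >= 0")


@dataclass
class ReactionParams:
    """Stretch-gated Michaelis-Menten production and linear degradation."""

    k1_degradation: float = 1e-4
    k2_max_production: float = 0.01
    km_michaelis: float = 2.0

    def __post_init__(self):
        if min(self.k1_degradation, self.k2_max_production, self.km_michaelis) <= 0.0:
            raise ValidationError("reaction constants must be positive")


@dataclass
class MorphogenField:
    """Continuous nodal concentration on the reference mesh (O(1) units)."""

    nodal_values: np.ndarray
    timestamp: float = 0.0


def diffusion_tensor(X, params):
    """Anisotropic diffusion tensor at reference point(s) X (projector form).

    Accepts a single 3-vector or an (..., 3) array; returns (..., 3, 3).
    """
    N = radial_direction(X)
    nn = N[..., :, None] * N[..., None, :]
    return params.D_normal * nn + params.D_tangential * (_I3 - nn)


def diffusion_tensor_rotation(X, params, tangent_basis=None):
    """Equivalent rotation-matrix construction R^T diag(D_N, D_T, D_T) R.

    ``R`` maps the radial direction to the first axis; the two tangential
    rows are arbitrary (any orthonormal completion gives the same tensor).
    Used as an independent cross-check of :func:`diffusion_tensor`.
    """
    N = radial_direction(np.asarray(X, dtype=float))
    if tangent_basis is None:
        helper = np.array([1.0, 0.0, 0.0])
        if abs(N @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        t1 = np.cross(helper, N)
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(N, t1)
    else:
        t1, t2 = tangent_basis
    R = np.stack([N, t1, t2], axis=0)
    return R.T @ np.diag([params.D_normal, params.D_tangential, params.D_tangential]) @ R


def reaction_rate(I3_F, C, params, mechanical_cue=None):
    """Net morphogen rate R(I3(F), C); vectorised over matching shapes.

    ``mechanical_cue`` optionally overrides the production argument
    s = max(I3(F) - 1, 0) with a precomputed scalar cue, providing the hook
    for alternative feedbacks on other tensor invariants.
    """
    if mechanical_cue is None:
        s = np.maximum(np.asarray(I3_F, dtype=float) - 1.0, 0.0)
    else:
        s = np.maximum(np.asarray(mechanical_cue, dtype=float), 0.0)
    production = params.k2_max_production * s / (params.km_michaelis + s)
    return production - params.k1_degradation * np.asarray(C, dtype=float)


def pullback_diffusion(F, J, D):
    """Lagrangian mobility J F^{-1} D F^{-T} (symmetric PSD when D is)."""
    F = np.asarray(F, dtype=float)
    if abs(np.linalg.det(F)) < 1e-300:
        raise ValidationError("deformation gradient is singular")
    Finv = np.linalg.inv(F)
    return J * Finv @ np.asarray(D, dtype=float) @ Finv.T
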