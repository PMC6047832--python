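"""Manufactured solution for the steady anisotropic-diffusion verification.

C* = g(r) (1 + x/r) with g(r) = cos(pi (r - r_in)/(r_out - r_in)), so
g'(r_in) = g'(r_out) = 0 and the anisotropic flux D grad(C*) . N vanishes
on both shell walls (compatible with the natural Neumann boundary).
x/r is an l = 1 spherical harmonic (surface-Laplacian eigenvalue -2).
"""

import numpy as np


def manufactured_problem(space, diff, k1):
    r_in, r_out = space.mesh.r_inner, space.mesh.r_outer
    L = r_out - r_in
    DN, DT = diff.D_normal, diff.D_tangential

    def g(r):
        return np.cos(np.pi * (r - r_in) / L)

    def gp(r):
        return -np.pi / L * np.sin(np.pi * (r - r_in) / L)

    def gpp(r):
        return -((np.pi / L) ** 2) * np.cos(np.pi * (r - r_in) / L)

    def exact(X):
        r = np.linalg.norm(X, axis=-1)
        return g(r) * (1.0 + X[..., 0] / r)

    def source(X):
        r = np.linalg.norm(X, axis=-1)
        xhat = X[..., 0] / r
        lap_rad = gpp(r) + 2.0 * gp(r) / r
        div_D_grad = DN * lap_rad * (1.0 + xhat) - DT * 2.0 * g(r) * xhat / r**2
        return k1 * exact(X) - div_D_grad

    return exact, source
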