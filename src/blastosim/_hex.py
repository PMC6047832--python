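"""Reference hexahedron: Lagrange shape functions and Gauss quadrature.

Shared by the mesh module (element volumes / centroids) and the FEM module
(assembly).  Q1 uses the standard 8-node VTK corner ordering; Q2 uses a
lexicographic (i fastest, then j, then k) 27-node ordering that is internal
to this package (Q2 spaces are for verification only and are not exported).
"""

from __future__ import annotations

import numpy as np

# VTK_HEXAHEDRON corner ordering: bottom quad counter-clockwise (seen from
# the top node layer), then top quad.
HEX_CORNERS = np.array(
    [
        [-1.0, -1.0, -1.0],
        [1.0, -1.0, -1.0],
        [1.0, 1.0, -1.0],
        [-1.0, 1.0, -1.0],
        [-1.0, -1.0, 1.0],
        [1.0, -1.0, 1.0],
        [1.0, 1.0, 1.0],
        [-1.0, 1.0, 1.0],
    ]
)


def _lagrange_1d(order):
    """Return (nodes, eval) for 1D Lagrange basis of given order on [-1, 1]."""
    if order == 1:
        nodes = np.array([-1.0, 1.0])

        def ev(x):
            v = np.array([0.5 * (1.0 - x), 0.5 * (1.0 + x)])
            d = np.array([-0.5, 0.5])
            return v, d

    elif order == 2:
        nodes = np.array([-1.0, 0.0, 1.0])

        def ev(x):
            v = np.array([0.5 * x * (x - 1.0), 1.0 - x * x, 0.5 * x * (x + 1.0)])
            d = np.array([x - 0.5, -2.0 * x, x + 0.5])
            return v, d

    else:
        raise ValueError(f"unsupported element order {order}")
    return nodes, ev


def reference_nodes(order):
    """Reference-element node coordinates, shape (n_nodes, 3)."""
    if order == 1:
        return HEX_CORNERS.copy()
    nodes1d, _ = _lagrange_1d(order)
    pts = []
    for c in nodes1d:  # k (zeta) slowest
        for b in nodes1d:
            for a in nodes1d:
                pts.append((a, b, c))
    return np.array(pts)


def shape_functions(order, xi):
    """Evaluate basis at a single reference point xi.

    Returns (N, dN) with N shape (n_nodes,), dN shape (n_nodes, 3).
    """
    xi = np.asarray(xi, dtype=float)
    nodes1d, ev = _lagrange_1d(order)
    n1 = len(nodes1d)
    va, da = ev(xi[0])
    vb, db = ev(xi[1])
    vc, dc = ev(xi[2])
    if order == 1:
        # map lexicographic (i,j,k) -> VTK corner ordering
        lex_to_vtk = _q1_lex_to_vtk()
    n_nodes = n1**3
    N = np.empty(n_nodes)
    dN = np.empty((n_nodes, 3))
    idx = 0
    for k in range(n1):
        for j in range(n1):
            for i in range(n1):
                N[idx] = va[i] * vb[j] * vc[k]
                dN[idx, 0] = da[i] * vb[j] * vc[k]
                dN[idx, 1] = va[i] * db[j] * vc[k]
                dN[idx, 2] = va[i] * vb[j] * dc[k]
                idx += 1
    if order == 1:
        perm = lex_to_vtk
        N = N[perm]
        dN = dN[perm]
    return N, dN


def _q1_lex_to_vtk():
    """Permutation p with lex_nodes[p] == HEX_CORNERS."""
    lex = np.array(
        [(a, b, c) for c in (-1.0, 1.0) for b in (-1.0, 1.0) for a in (-1.0, 1.0)]
    )
    perm = []
    for corner in HEX_CORNERS:
        matches = np.where((lex == corner).all(axis=1))[0]
        perm.append(int(matches[0]))
    return np.array(perm)


def gauss_rule_1d(n):
    """n-point Gauss-Legendre rule on [-1, 1]."""
    return np.polynomial.legendre.leggauss(n)


def hex_quadrature(n):
    """Tensor-product Gauss rule: (points (n^3, 3), weights (n^3,))."""
    x, w = gauss_rule_1d(n)
    pts = []
    wts = []
    for c, wc in zip(x, w):
        for b, wb in zip(x, w):
            for a, wa in zip(x, w):
                pts.append((a, b, c))
                wts.append(wa * wb * wc)
    return np.array(pts), np.array(wts)


def tabulate(order, n_gauss):
    """Tabulated basis at quadrature points.

    Returns (qpoints (q, 3), qweights (q,), N (q, a), dN (q, a, 3)).
    """
    qp, qw = hex_quadrature(n_gauss)
    Ns = []
    dNs = []
    for xi in qp:
        N, dN = shape_functions(order, xi)
        Ns.append(N)
        dNs.append(dN)
    return qp, qw, np.array(Ns), np.array(dNs)


def element_geometry(node_coords, connectivity, dN, qw):
    """Geometric quadrature data for a batch of (tri)linear elements.

    Parameters
    ----------
    node_coords : (n_nodes, 3)
    connectivity : (n_el, a) vertex indices (a matching dN's basis size)
    dN : (q, a, 3) reference-space basis gradients
    qw : (q,) quadrature weights

    Returns
    -------
    B : (n_el, q, a, 3) physical basis gradients
    wdet : (n_el, q) quadrature weight times |det dX/dxi|
    detJ : (n_el, q) signed Jacobian determinants
    """
    X = node_coords[connectivity]  # (e, a, 3)
    Jgeo = np.einsum("eai,qaj->eqij", X, dN)  # dX_i/dxi_j
    detJ = np.linalg.det(Jgeo)
    invJ = np.linalg.inv(Jgeo)
    B = np.einsum("qaj,eqji->eqai", dN, invJ)
    wdet = qw[None, :] * detJ
    return B, wdet, detJ
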