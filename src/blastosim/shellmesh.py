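"""Hollow-sphere hexahedral mesh partitioned into biological cells.

The blastula wall is meshed as a cubed sphere: the six faces of a cube are
subdivided into ``n_face`` x ``n_face`` biological cells, each cell into
``refine``^3 hexahedral finite elements (so the wall is one biological cell
thick, with ``refine`` element layers radially).  Cube surface points are
pushed onto the sphere by radial normalisation and replicated on
``refine + 1`` uniformly spaced radial layers between the inner and outer
radius.

Nodes shared between elements, between cubed-sphere patches, and along patch
edges/corners are merged exactly: the generator keys every surface node by
its integer cube-lattice coordinates, so no floating-point merge tolerance
is involved and the construction is bit-deterministic.

Each biological cell carries a local orthonormal frame (rotation ``Q`` and
centroid ``m``): local coordinates are ``X_hat = Q (X - m)`` with the third
local axis pointing radially outward.  Active constriction tensors are
expressed in these frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _hex
from .errors import MeshError, ValidationError

# (normal axis, sign, u axis, v axis) per cubed-sphere patch, chosen so that
# u x v points along the outward normal: element bottom quads (inner layer)
# are then counter-clockwise seen from outside and all hexahedra have
# positive Jacobians.
_FACES = (
    (0, +1, 1, 2),
    (0, -1, 2, 1),
    (1, +1, 2, 0),
    (1, -1, 0, 2),
    (2, +1, 0, 1),
    (2, -1, 1, 0),
)


@dataclass
class ShellMesh:
    """Hexahedral cubed-sphere shell with biological-cell bookkeeping.

    Attributes
    ----------
    node_coords : (n_nodes, 3) float array, micrometres.
    hex_connectivity : (n_elements, 8) int array, VTK hexahedron ordering.
    bio_cell_id : (n_elements,) int array; elements of one biological cell
        form a contiguous ``refine**3`` block.
    patch_id : (n_elements,) int array in 0..5 (cubed-sphere face).
    outer_surface_faces, inner_surface_faces : (n, 4) int arrays of quads.
    """

    node_coords: np.ndarray
    hex_connectivity: np.ndarray
    bio_cell_id: np.ndarray
    patch_id: np.ndarray
    outer_surface_faces: np.ndarray
    inner_surface_faces: np.ndarray
    r_outer: float
    r_inner: float
    n_face: int
    refine: int
    metadata: dict = field(default_factory=dict)

    @property
    def n_nodes(self):
        return self.node_coords.shape[0]

    @property
    def n_elements(self):
        return self.hex_connectivity.shape[0]

    @property
    def n_bio_cells(self):
        return 6 * self.n_face**2

    def save_vtu(self, path):
        """Write the reference mesh to an ASCII VTU file."""
        from . import vtuio

        vtuio.write_vtu(
            path,
            self.node_coords,
            self.hex_connectivity,
            cell_data={
                "bio_cell_id": self.bio_cell_id.astype(float),
                "patch_id": self.patch_id.astype(float),
            },
        )


@dataclass
class CellFrame:
    """Local orthonormal frame of one biological cell.

    ``Q`` is a rotation whose third row is the unit radial direction at the
    cell centroid ``m``; local coordinates of a point are ``Q X - Q m``.
    """

    cell_id: int
    m: np.ndarray
    Q: np.ndarray


def radial_direction(X):
    """Unit radial (Lagrangian normal) direction N = X / |X|."""
    X = np.asarray(X, dtype=float)
    r = np.linalg.norm(X, axis=-1, keepdims=True)
    if np.any(r == 0.0):
        raise ValidationError("radial direction undefined at the origin")
    return X / r


def _surface_lattice(m):
    """Integer cube-lattice keys for all 6 faces.

    Returns (keys (6*(m+1)^2, 3) int array, per-face index grid of shape
    (6, m+1, m+1) into the stacked key array).
    """
    keys = []
    grids = np.empty((6, m + 1, m + 1), dtype=np.int64)
    count = 0
    for f, (ax, sgn, ua, va) in enumerate(_FACES):
        ii, jj = np.meshgrid(np.arange(m + 1), np.arange(m + 1), indexing="ij")
        k = np.empty((m + 1, m + 1, 3), dtype=np.int64)
        k[..., ax] = sgn * m
        k[..., ua] = 2 * ii - m
        k[..., va] = 2 * jj - m
        keys.append(k.reshape(-1, 3))
        grids[f] = np.arange(count, count + (m + 1) ** 2).reshape(m + 1, m + 1)
        count += (m + 1) ** 2
    return np.concatenate(keys, axis=0), grids


def build_shell_mesh(n_face=16, refine=4, r_outer=150.0, r_inner=135.0):
    """Generate the cubed-sphere shell mesh.

    Parameters
    ----------
    n_face : biological cells per cube-face edge (6 * n_face**2 cells total).
    refine : elements per biological-cell edge (refine**3 elements per cell).
    r_outer, r_inner : outer/inner radius in micrometres.

    The standard blastula discretisation (``n_face=16, refine=4``,
    radii 150/135 um) has 1536 biological cells, 98304 elements and
    122890 nodes.
    """
    if n_face < 1 or refine < 1:
        raise MeshError("n_face and refine must be >= 1")
    if not (0.0 < r_inner < r_outer):
        raise MeshError("radii must satisfy 0 < r_inner < r_outer")

    m = n_face * refine
    keys, grids = _surface_lattice(m)
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    n_surf = uniq.shape[0]
    assert n_surf == 6 * m * m + 2
    surf_id = inverse[grids]  # (6, m+1, m+1) -> unique surface node id

    dirs = uniq.astype(float) / m
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    radii = np.linspace(r_inner, r_outer, refine + 1)
    node_coords = (radii[:, None, None] * dirs[None, :, :]).reshape(-1, 3)

    # Elements, grouped per (face, cell) so each biological cell is a
    # contiguous refine^3 run; within a cell ordering is (radial, v, u).
    conn = []
    cell_ids = []
    patch_ids = []
    outer_faces = []
    inner_faces = []
    for f in range(6):
        sid = surf_id[f]
        # surface quads for all element columns on this face
        q00 = sid[:-1, :-1]
        q10 = sid[1:, :-1]
        q11 = sid[1:, 1:]
        q01 = sid[:-1, 1:]
        quad = np.stack([q00, q10, q11, q01], axis=-1)  # (m, m, 4)
        outer_faces.append((quad + refine * n_surf).reshape(-1, 4))
        inner_faces.append(quad.reshape(-1, 4))
        for ci in range(n_face):
            for cj in range(n_face):
                sub = quad[
                    ci * refine : (ci + 1) * refine,
                    cj * refine : (cj + 1) * refine,
                ]  # (refine, refine, 4)
                for kr in range(refine):
                    lo = sub + kr * n_surf
                    hi = sub + (kr + 1) * n_surf
                    hexes = np.concatenate([lo, hi], axis=-1).reshape(-1, 8)
                    conn.append(hexes)
                cell = f * n_face**2 + ci * n_face + cj
                cell_ids.append(np.full(refine**3, cell, dtype=np.int64))
                patch_ids.append(np.full(refine**3, f, dtype=np.int64))

    mesh = ShellMesh(
        node_coords=node_coords,
        hex_connectivity=np.concatenate(conn, axis=0).astype(np.int64),
        bio_cell_id=np.concatenate(cell_ids),
        patch_id=np.concatenate(patch_ids),
        outer_surface_faces=np.concatenate(outer_faces, axis=0),
        inner_surface_faces=np.concatenate(inner_faces, axis=0),
        r_outer=float(r_outer),
        r_inner=float(r_inner),
        n_face=int(n_face),
        refine=int(refine),
        metadata={"projection": "radial normalisation of an equispaced cube grid"},
    )
    return mesh


def element_volumes_and_centroids(mesh, n_gauss=2):
    """Quadrature element volumes (um^3) and volume centroids (um)."""
    _, qw, N, dN = _hex.tabulate(1, n_gauss)
    B, wdet, detJ = _hex.element_geometry(
        mesh.node_coords, mesh.hex_connectivity, dN, qw
    )
    if np.any(detJ <= 0.0):
        raise MeshError("mesh contains elements with non-positive Jacobian")
    vol = wdet.sum(axis=1)
    Xq = np.einsum("qa,eai->eqi", N, mesh.node_coords[mesh.hex_connectivity])
    cent = np.einsum("eq,eqi->ei", wdet, Xq) / vol[:, None]
    return vol, cent


def compute_cell_frames(mesh):
    """One :class:`CellFrame` per biological cell.

    The centroid ``m`` is the volume-weighted centroid of the cell's element
    block; ``Q`` maps the unit radial direction at ``m`` to the third local
    axis (rows of ``Q`` are the two tangential directions and the radial
    direction).
    """
    vol, cent = element_volumes_and_centroids(mesh)
    n_cells = mesh.n_bio_cells
    cell_vol = np.bincount(mesh.bio_cell_id, weights=vol, minlength=n_cells)
    if np.any(cell_vol <= 0.0):
        raise MeshError("degenerate biological cell with non-positive volume")
    ms = np.empty((n_cells, 3))
    for i in range(3):
        ms[:, i] = (
            np.bincount(mesh.bio_cell_id, weights=vol * cent[:, i], minlength=n_cells)
            / cell_vol
        )
    frames = []
    for cid in range(n_cells):
        frames.append(CellFrame(cell_id=cid, m=ms[cid], Q=frame_rotation(ms[cid])))
    return frames


def frame_rotation(m):
    """Rotation whose third row is the unit radial direction at ``m``.

    The two tangential rows are constructed deterministically: the first is
    the normalised cross product of a fixed helper axis with the radial
    direction (helper = x unless the radial direction is nearly parallel to
    x, in which case y).
    """
    n = radial_direction(np.asarray(m, dtype=float))
    helper = np.array([1.0, 0.0, 0.0])
    if abs(n @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    t1 = np.cross(helper, n)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(n, t1)
    return np.stack([t1, t2, n], axis=0)


def shell_volume(r_outer, r_inner):
    """Analytic volume of the spherical shell."""
    return 4.0 / 3.0 * np.pi * (r_outer**3 - r_inner**3)


def expected_node_count(n_face, refine):
    """Closed-form node count of the one-cell-thick cubed-sphere shell."""
    m = n_face * refine
    return (6 * m * m + 2) * (refine + 1)
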