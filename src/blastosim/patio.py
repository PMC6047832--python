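"""Output and pattern quantification.

The simulations are judged on what the tissue *looks* like: where morphogen
accumulates on the deformed outer surface, how the surface bends, and how
the two co-localise.  This module extracts the deformed outer surface,
computes discrete mean curvature (cotangent Laplacian on the triangulated
quads), detects connected morphogen patches above a threshold and measures
their areas/spacing, and writes VTU snapshots of the full volume state.

All quantification rules here (threshold choice, edge adjacency, barycentric
vertex areas, fixed quad-splitting diagonal) are artifact conventions of
this package; the underlying model only produces fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from . import vtuio
from .errors import UndefinedCorrelationError, ValidationError

write_vtu = vtuio.write_vtu
read_vtu = vtuio.read_vtu


@dataclass
class SurfaceField:
    """Closed quad surface in deformed coordinates with per-vertex fields."""

    vertices: np.ndarray          # (n, 3) deformed coordinates, um
    quads: np.ndarray             # (m, 4) vertex indices, outward oriented
    concentration: np.ndarray = None
    curvature: np.ndarray = None  # per-vertex mean curvature, 1/um

    @property
    def triangles(self):
        """Quads split along the fixed (v0, v2) diagonal."""
        q = self.quads
        return np.concatenate([q[:, [0, 1, 2]], q[:, [0, 2, 3]]], axis=0)

    def euler_characteristic(self):
        edges = set()
        for quad in self.quads:
            for a, b in zip(quad, np.roll(quad, -1)):
                edges.add((min(a, b), max(a, b)))
        return self.vertices.shape[0] - len(edges) + self.quads.shape[0]


@dataclass
class PatchReport:
    """Connected above-threshold morphogen patches on the surface."""

    n_patches: int
    areas: np.ndarray            # um^2 per patch
    mean_spacing: float          # mean nearest-neighbour centroid distance, um
    threshold: float
    labels: np.ndarray = field(default=None, repr=False)


def extract_surface(mesh, u=None, C=None, which="outer"):
    """Deformed outer (or inner) surface of the shell as a SurfaceField."""
    faces = (
        mesh.outer_surface_faces if which == "outer" else mesh.inner_surface_faces
    )
    vid = np.unique(faces)
    remap = -np.ones(mesh.n_nodes, dtype=np.int64)
    remap[vid] = np.arange(vid.size)
    coords = mesh.node_coords[vid].copy()
    if u is not None:
        coords = coords + np.asarray(u, dtype=float).reshape(-1, 3)[vid]
    conc = None if C is None else np.asarray(C, dtype=float)[vid]
    return SurfaceField(vertices=coords, quads=remap[faces], concentration=conc)


def vertex_areas(surface):
    """Barycentric vertex areas (one third of each incident triangle)."""
    tris = surface.triangles
    v = surface.vertices
    cross = np.cross(v[tris[:, 1]] - v[tris[:, 0]], v[tris[:, 2]] - v[tris[:, 0]])
    ta = 0.5 * np.linalg.norm(cross, axis=1)
    areas = np.zeros(v.shape[0])
    for c in range(3):
        np.add.at(areas, tris[:, c], ta / 3.0)
    return areas


def vertex_normals(surface):
    """Area-weighted outward vertex normals (quads are outward oriented)."""
    tris = surface.triangles
    v = surface.vertices
    cross = np.cross(v[tris[:, 1]] - v[tris[:, 0]], v[tris[:, 2]] - v[tris[:, 0]])
    normals = np.zeros_like(v)
    for c in range(3):
        np.add.at(normals, tris[:, c], cross)
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    return normals / np.maximum(norms, 1e-300)


def mean_curvature(surface):
    """Discrete mean curvature via the cotangent-Laplacian normal.

    Sign convention: positive where the surface bulges outward (H = 1/R on
    the reference sphere of radius R).  Degenerate (zero-area) triangles
    raise an error listing the offending faces.
    """
    tris = surface.triangles
    v = surface.vertices
    n = v.shape[0]
    cross = np.cross(v[tris[:, 1]] - v[tris[:, 0]], v[tris[:, 2]] - v[tris[:, 0]])
    ta2 = np.linalg.norm(cross, axis=1)  # twice the triangle area
    bad = np.where(ta2 <= 1e-300)[0]
    if bad.size:
        raise ValidationError(f"degenerate surface triangles: {bad[:10]}")

    rows, cols, vals = [], [], []
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        # cotangent at vertex i weights edge (j, k)
        e1 = v[tris[:, j]] - v[tris[:, i]]
        e2 = v[tris[:, k]] - v[tris[:, i]]
        cot = np.einsum("ij,ij->i", e1, e2) / ta2
        rows.append(tris[:, j]); cols.append(tris[:, k]); vals.append(0.5 * cot)
        rows.append(tris[:, k]); cols.append(tris[:, j]); vals.append(0.5 * cot)
    W = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    L = W - sp.diags(np.asarray(W.sum(axis=1)).ravel())
    lap = L @ v  # (n, 3) cotangent Laplacian of position
    areas = vertex_areas(surface)
    normals = vertex_normals(surface)
    H = -np.einsum("ij,ij->i", lap, normals) / (2.0 * areas)
    return H


def _surface_adjacency(surface):
    q = surface.quads
    n = surface.vertices.shape[0]
    a = np.concatenate([q[:, [0, 1]], q[:, [1, 2]], q[:, [2, 3]], q[:, [3, 0]]])
    data = np.ones(a.shape[0])
    A = sp.coo_matrix((data, (a[:, 0], a[:, 1])), shape=(n, n))
    return (A + A.T).tocsr()


def detect_patches(surface, threshold=None, values=None):
    """Connected components of vertices with field value >= threshold.

    ``values`` defaults to the surface concentration.  ``threshold=None``
    uses the midpoint of the field's min/max, which makes detection
    invariant to adding a constant to the field.
    """
    vals = surface.concentration if values is None else np.asarray(values)
    if vals is None:
        raise ValidationError("no field to threshold")
    if threshold is None:
        threshold = 0.5 * (float(vals.min()) + float(vals.max()))
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    above = vals >= threshold
    labels = -np.ones(vals.shape[0], dtype=np.int64)
    if not np.any(above) or vals.max() == vals.min():
        return PatchReport(0, np.array([]), np.nan, threshold, labels)
    idx = np.where(above)[0]
    A = _surface_adjacency(surface)[np.ix_(idx, idx)]
    n_comp, comp = connected_components(A, directed=False)
    labels[idx] = comp
    areas_v = vertex_areas(surface)
    areas = np.bincount(comp, weights=areas_v[idx], minlength=n_comp)
    centroids = np.stack(
        [
            np.bincount(comp, weights=areas_v[idx] * surface.vertices[idx, c],
                        minlength=n_comp)
            / areas
            for c in range(3)
        ],
        axis=1,
    )
    if n_comp > 1:
        d = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        spacing = float(d.min(axis=1).mean())
    else:
        spacing = np.nan
    return PatchReport(int(n_comp), areas, spacing, float(threshold), labels)


def colocalization(a, b, weights=None):
    """Area-weighted Pearson correlation of two per-vertex fields."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("fields must have equal length")
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    am = a - w @ a
    bm = b - w @ b
    va = w @ am**2
    vb = w @ bm**2
    # relative floor: constant fields leave only accumulation roundoff
    if va <= 1e-28 * max(1.0, w @ a**2) or vb <= 1e-28 * max(1.0, w @ b**2):
        raise UndefinedCorrelationError("zero-variance field in correlation")
    return float((w @ (am * bm)) / np.sqrt(va * vb))


def lumen_volume(mesh, u=None):
    """Volume enclosed by the (deformed) inner surface, via the divergence
    theorem over the closed inner quad mesh."""
    surf = extract_surface(mesh, u=u, which="inner")
    tris = surf.triangles
    v = surf.vertices
    # inner faces are oriented with u x v pointing radially outward, i.e.
    # out of the enclosed lumen as seen from the lumen
    return float(
        np.abs(
            np.einsum(
                "ij,ij->i",
                v[tris[:, 0]],
                np.cross(v[tris[:, 1]] - v[tris[:, 0]], v[tris[:, 2]] - v[tris[:, 0]]),
            ).sum()
        )
        / 6.0
    )


@dataclass
class InnerVolumeConstraint:
    """Penalty on changes of the enclosed lumen volume (disabled stub).

    Deep invaginations compress the lumen; penalising lumen-volume change
    may stabilise them past the point where the unconstrained model breaks
    down.  Only the diagnostic (:func:`lumen_volume`) is implemented; the
    penalty assembly is not wired into the solver.
    """

    penalty: float = 0.0
    enabled: bool = False

    def __post_init__(self):
        if self.enabled:
            raise NotImplementedError(
                "the inner-volume penalty is a disabled stub; only the "
                "lumen_volume diagnostic is available"
            )


def write_snapshot(mesh, space, state, assembler=None, path=None, extra_cell_data=None):
    """Write a VTU snapshot of the full volumetric state.

    Point data: displacement (3-vector), concentration; cell data:
    bio_cell_id, element-averaged volume change I3(F), patch id.
    """
    u3 = state.u.reshape(-1, 3)
    cell_data = {
        "bio_cell_id": mesh.bio_cell_id.astype(float),
        "patch_id": mesh.patch_id.astype(float),
    }
    if assembler is not None:
        kin = assembler.kinematics(state.u, state.C)
        cell_data["I3_F"] = (
            np.einsum("eq,eq->e", space.wdet, kin["J"]) / space.wdet.sum(axis=1)
        )
    if extra_cell_data:
        cell_data.update(extra_cell_data)
    vtuio.write_vtu(
        path,
        mesh.node_coords,
        mesh.hex_connectivity,
        point_data={"displacement": u3, "concentration": state.C},
        cell_data=cell_data,
    )
    return path
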