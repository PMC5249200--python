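"""Closest-point-on-mesh queries used by registration and wear mapping.

Implements point-to-triangle projection with a cKDTree over triangle
centroids as the candidate filter: for each query point the k nearest
centroids are tested exactly.  On the dense, nearly uniform meshes
produced by marching cubes the true nearest triangle is in the candidate
set for all practical purposes (k is configurable).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def _closest_point_on_triangles(p: np.ndarray, a, b, c):
    """Closest point on each triangle (a, b, c) to each point p.

    All arrays broadcast over leading dimensions; standard region-based
    projection (Ericson, Real-Time Collision Detection ch. 5).
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.sum(ab * ap, axis=-1)
    d2 = np.sum(ac * ap, axis=-1)
    bp = p - b
    d3 = np.sum(ab * bp, axis=-1)
    d4 = np.sum(ac * bp, axis=-1)
    cp = p - c
    d5 = np.sum(ab * cp, axis=-1)
    d6 = np.sum(ac * cp, axis=-1)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    denom = vb + vc + va
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
    face = a + v[..., None] * ab + w[..., None] * ac

    # edge/vertex regions
    out = face
    # region vertex A
    cond_a = (d1 <= 0) & (d2 <= 0)
    # region vertex B
    cond_b = (d3 >= 0) & (d4 <= d3)
    # region vertex C
    cond_c = (d6 >= 0) & (d5 <= d6)
    # edge AB
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ab = np.where((d1 - d3) != 0, d1 / (d1 - d3), 0.0)
    cond_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    # edge AC
    with np.errstate(divide="ignore", invalid="ignore"):
        t_ac = np.where((d2 - d6) != 0, d2 / (d2 - d6), 0.0)
    cond_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    # edge BC
    num = d4 - d3
    den = (d4 - d3) + (d5 - d6)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_bc = np.where(den != 0, num / den, 0.0)
    cond_bc = (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)

    out = np.where(cond_bc[..., None], b + np.clip(t_bc, 0, 1)[..., None] * (c - b), out)
    out = np.where(cond_ac[..., None], a + np.clip(t_ac, 0, 1)[..., None] * ac, out)
    out = np.where(cond_ab[..., None], a + np.clip(t_ab, 0, 1)[..., None] * ab, out)
    out = np.where(cond_c[..., None], c, out)
    out = np.where(cond_b[..., None], b, out)
    out = np.where(cond_a[..., None], a, out)
    return out


class MeshProximity:
    """Reusable closest-point / signed-distance queries against one mesh."""

    def __init__(self, vertices: np.ndarray, triangles: np.ndarray, face_normals=None):
        self.vertices = np.asarray(vertices, dtype=float)
        self.triangles = np.asarray(triangles, dtype=np.int64)
        tri = self.vertices[self.triangles]
        self._a, self._b, self._c = tri[:, 0], tri[:, 1], tri[:, 2]
        self._centroids = tri.mean(axis=1)
        self._tree = cKDTree(self._centroids)
        if face_normals is None:
            n = np.cross(self._b - self._a, self._c - self._a)
            norm = np.linalg.norm(n, axis=1, keepdims=True)
            norm[norm == 0] = 1.0
            face_normals = n / norm
        self.face_normals = np.asarray(face_normals, dtype=float)

    def closest(self, points: np.ndarray, k: int = 6):
        """Closest surface points; returns (distances, points, face_index)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        k = min(k, len(self._centroids))
        _, idx = self._tree.query(points, k=k)
        idx = np.atleast_2d(idx)
        cand = _closest_point_on_triangles(
            points[:, None, :], self._a[idx], self._b[idx], self._c[idx]
        )
        d2 = np.sum((cand - points[:, None, :]) ** 2, axis=-1)
        best = np.argmin(d2, axis=1)
        rows = np.arange(len(points))
        return (
            np.sqrt(d2[rows, best]),
            cand[rows, best],
            idx[rows, best],
        )

    def signed_distance(self, points: np.ndarray, k: int = 6) -> np.ndarray:
        """Signed distance: positive on the outward-normal side of the mesh.

        Sign from the dot product with the closest face's normal; reliable
        away from sharp creases, which is the regime of the smooth cup
        surfaces this package measures.
        """
        d, q, fi = self.closest(points, k=k)
        side = np.sum((np.atleast_2d(points) - q) * self.face_normals[fi], axis=-1)
        return np.where(side >= 0, d, -d)
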