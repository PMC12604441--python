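"""Low-level surface queries: closest point on a triangle mesh and point-in-mesh tests.

These primitives back correspondence search, ICP and voxelization. They are
pure numpy/scipy (KD-tree candidate search + exact point-triangle projection,
and a z-column crossing-parity test for containment) and require no spatial
index beyond :class:`scipy.spatial.cKDTree`.
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy.spatial import cKDTree


class SurfaceQuery:
    """Closest-point-on-surface queries against a fixed triangle mesh.

    Candidate triangles are found with a KD-tree over triangle centroids and
    the exact foot point is computed per candidate; the true nearest triangle
    is among the candidates for meshes whose triangle size is small relative
    to query distances, which holds for the remeshed bone surfaces used here.

    Parameters
    ----------
    mesh : trimesh.Trimesh or (V, 3) array + faces
    n_candidates : int
        Number of candidate triangles examined per query point.
    """

    def __init__(self, mesh: trimesh.Trimesh, n_candidates: int = 12):
        self.triangles = np.asarray(mesh.triangles, dtype=float)
        if len(self.triangles) == 0:
            raise ValueError("empty mesh has no surface to query")
        self.n_candidates = int(min(n_candidates, len(self.triangles)))
        self._tree = cKDTree(self.triangles.mean(axis=1))

    def closest(self, points: np.ndarray):
        """Return (closest points on surface, distances, triangle indices)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        _, cand = self._tree.query(points, k=self.n_candidates)
        cand = np.atleast_2d(cand)
        n, k = cand.shape
        tri = self.triangles[cand.ravel()]            # (n*k, 3, 3)
        rep = np.repeat(points, k, axis=0)            # (n*k, 3)
        foot = trimesh.triangles.closest_point(tri, rep)
        d2 = ((foot - rep) ** 2).sum(axis=1).reshape(n, k)
        best = d2.argmin(axis=1)
        idx = np.arange(n)
        closest = foot.reshape(n, k, 3)[idx, best]
        return closest, np.sqrt(d2[idx, best]), cand[idx, best]


def points_inside(mesh: trimesh.Trimesh, points: np.ndarray) -> np.ndarray:
    """Test containment of points by crossing parity along the +z direction.

    A point is inside a watertight surface iff a ray cast from it crosses the
    surface an odd number of times. Query xy coordinates are nudged by a tiny
    deterministic offset so rays do not pass exactly through shared triangle
    edges or vertices.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tris = np.asarray(mesh.triangles, dtype=float)
    if len(tris) == 0:
        return np.zeros(len(points), dtype=bool)

    scale = float(np.ptp(mesh.bounds, axis=0).max())
    px = points[:, 0] + 1.2345e-7 * scale
    py = points[:, 1] + 2.3456e-7 * scale
    pz = points[:, 2]
    crossings = np.zeros(len(points), dtype=np.int64)

    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
    for i in range(len(tris)):
        ax, ay, az = a[i]
        bx, by, bz = b[i]
        cx, cy, cz = c[i]
        xmin, xmax = min(ax, bx, cx), max(ax, bx, cx)
        ymin, ymax = min(ay, by, cy), max(ay, by, cy)
        m = (px >= xmin) & (px <= xmax) & (py >= ymin) & (py <= ymax)
        if not m.any():
            continue
        # 2D barycentric coordinates in the xy projection
        d = (by - cy) * (ax - cx) + (cx - bx) * (ay - cy)
        if abs(d) < 1e-14:      # triangle vertical to z: ray parallel, skip
            continue
        x, y = px[m], py[m]
        w1 = ((by - cy) * (x - cx) + (cx - bx) * (y - cy)) / d
        w2 = ((cy - ay) * (x - cx) + (ax - cx) * (y - cy)) / d
        w3 = 1.0 - w1 - w2
        hit = (w1 >= 0) & (w2 >= 0) & (w3 >= 0)
        if not hit.any():
            continue
        zint = w1 * az + w2 * bz + w3 * cz
        above = np.zeros(hit.shape, dtype=bool)
        above[hit] = zint[hit] > pz[m][hit]
        idx = np.flatnonzero(m)
        crossings[idx[above]] += 1
    return (crossings % 2) == 1
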