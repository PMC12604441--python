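"""Surface extraction and mesh standardization.

Turns label volumes into clean, single-component, left-standardized triangle
meshes: marching cubes on the (anti-aliased) class indicator, mirroring of
right-side meshes across the sagittal plane, loose-body filtering, Laplacian
smoothing with isotropic-style remeshing, rigid ICP alignment to a reference
and the 7 cm femoral shaft cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure

from .surface import SurfaceQuery
from .volumes import LabelVolume

log = logging.getLogger(__name__)


@dataclass
class RigidTransform:
    """Rotation (proper orthonormal) + translation, in mm. No scaling."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("reflections are not rigid transforms here")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        matrix = np.asarray(matrix, dtype=float)
        return cls(matrix[:3, :3], matrix[:3, 3])

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


def _as_mesh(vertices, faces) -> trimesh.Trimesh:
    return trimesh.Trimesh(vertices=vertices, faces=faces, process=False)


def marching_cubes(volume: LabelVolume, class_id: int, level: float = 0.5,
                   smooth_sigma: float = 1.0) -> trimesh.Trimesh:
    """Extract the surface of one label class in mm coordinates.

    The binary class indicator is Gaussian-smoothed (``smooth_sigma`` in
    voxels) before isosurfacing to suppress the staircase bias of marching
    cubes on binary data; if smoothing erases the object (peak below the iso
    level, e.g. for objects a few voxels wide) the raw indicator is used.
    The volume is zero-padded so surfaces touching the grid border close.
    """
    if volume.is_probability:
        raise ValueError("marching_cubes expects a label-mode volume")
    indicator = (volume.data == class_id)
    if not indicator.any():
        raise ValueError(f"class {class_id} is absent from the volume")
    field = np.pad(indicator.astype(np.float32), 1)
    if smooth_sigma > 0:
        smoothed = ndimage.gaussian_filter(field, smooth_sigma)
        if smoothed.max() > level:
            field = smoothed
    verts, faces, _, _ = measure.marching_cubes(field, level=level,
                                                spacing=volume.spacing)
    verts = verts - np.asarray(volume.spacing) + np.asarray(volume.origin)
    mesh = _as_mesh(verts, faces)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def mirror_to_left(mesh: trimesh.Trimesh, side: str,
                   plane_x: float | None = None) -> trimesh.Trimesh:
    """Standardize right knees to left by reflecting across a sagittal plane.

    Left meshes are returned unchanged (as a copy). Right meshes are
    reflected across the plane ``x = plane_x`` (default: the bounding-box
    center, which makes the operation an involution) and the face winding is
    flipped so outward normals are preserved.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    if side == "left":
        return mesh.copy()
    c = float(plane_x) if plane_x is not None else float(mesh.bounds[:, 0].mean())
    verts = mesh.vertices.copy()
    verts[:, 0] = 2.0 * c - verts[:, 0]
    return _as_mesh(verts, mesh.faces[:, ::-1])


def keep_largest_component(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Drop loose bodies, retaining the component with the most faces
    (ties: larger enclosed volume)."""
    if len(mesh.faces) == 0:
        raise ValueError("empty mesh")
    parts = mesh.split(only_watertight=False)
    if len(parts) <= 1:
        return mesh
    key = [(len(p.faces), abs(p.volume) if p.is_watertight else 0.0) for p in parts]
    return parts[max(range(len(parts)), key=lambda i: key[i])]


def component_flags(mesh: trimesh.Trimesh, bipartite_fraction: float = 0.10) -> dict:
    """Exclusion bookkeeping: meshes whose second-largest component carries
    more than ``bipartite_fraction`` of the faces are flagged (analogous to
    excluding bipartite patellae rather than silently filtering them)."""
    parts = mesh.split(only_watertight=False)
    counts = sorted((len(p.faces) for p in parts), reverse=True)
    second = counts[1] if len(counts) > 1 else 0
    return {
        "n_components": len(counts),
        "second_component_fraction": second / max(sum(counts), 1),
        "flag_bipartite": second > bipartite_fraction * sum(counts),
    }


def smooth_and_remesh(mesh: trimesh.Trimesh, rounds: int = 2,
                      smooth_iters: int = 5,
                      target_edge: float | None = None) -> trimesh.Trimesh:
    """Isotropic-style remeshing followed by Laplacian smoothing, repeated.

    Each round splits edges longer than the target edge length (default: the
    input's median edge length), merges the resulting duplicate vertices and
    applies volume-preserving Laplacian smoothing with ``smooth_iters``
    iterations. ``rounds=0`` returns the input unchanged.
    """
    if rounds == 0:
        return mesh.copy()
    if not mesh.is_watertight:
        raise ValueError("smooth_and_remesh expects a watertight mesh")
    out = mesh.copy()
    if target_edge is None:
        target_edge = float(np.median(out.edges_unique_length))
    for _ in range(int(rounds)):
        # split only clearly over-long edges (4/3 criterion); the Laplacian
        # relaxation below equalizes the remaining length spread
        v, f, _ = trimesh.remesh.subdivide_to_size(
            out.vertices, out.faces, max_edge=4.0 * target_edge / 3.0,
            return_index=True)
        out = trimesh.Trimesh(vertices=v, faces=f, process=True)
        out.update_faces(out.nondegenerate_faces())
        out.remove_unreferenced_vertices()
        trimesh.smoothing.filter_laplacian(out, iterations=int(smooth_iters),
                                           volume_constraint=True)
    if not out.is_watertight:
        raise ValueError("remeshing destroyed watertightness; "
                         "reduce rounds or target edge length")
    return out


def _principal_frame(points: np.ndarray):
    c = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - c, full_matrices=False)
    axes = vt.T
    if np.linalg.det(axes) < 0:
        axes[:, 2] *= -1
    return c, axes


def _rigid_fit(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid (Kabsch) fit mapping source points onto target."""
    sc, tc = source.mean(axis=0), target.mean(axis=0)
    h = (source - sc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(r, tc - r @ sc)


def icp_align(moving, reference, max_iter: int = 50, tol: float = 1e-4,
              init: str = "principal", n_samples: int | None = None):
    """Rigid iterative-closest-point registration of ``moving`` onto
    ``reference`` (point-to-surface when the reference is a mesh).

    Initialization aligns centroids and principal axes, disambiguating axis
    signs by the best of the four proper flip candidates (``init='identity'``
    skips this). Returns ``(RigidTransform, aligned vertices, final mean
    closest-point distance)``; the objective is non-increasing and iteration
    stops when its decrease falls below ``tol`` (mm).
    """
    mv = np.asarray(moving.vertices if hasattr(moving, "vertices") else moving, float)
    if hasattr(reference, "faces") and len(getattr(reference, "faces", ())) > 0:
        query = SurfaceQuery(reference)
        ref_pts = np.asarray(reference.vertices, float)
    else:
        ref_pts = np.asarray(reference.vertices if hasattr(reference, "vertices")
                             else reference, float)
        query = None
        ref_tree = cKDTree(ref_pts)
    if len(mv) < 3 or len(ref_pts) < 3:
        raise ValueError("ICP needs at least 3 points per shape")
    if np.linalg.matrix_rank(mv - mv.mean(axis=0)) < 2:
        raise ValueError("degenerate (collinear) moving point set")

    sample = mv
    if n_samples is not None and n_samples < len(mv):
        sample = mv[np.linspace(0, len(mv) - 1, n_samples).astype(int)]

    def closest(points):
        if query is not None:
            pts, d, _ = query.closest(points)
            return pts, d
        d, idx = ref_tree.query(points)
        return ref_pts[idx], d

    # ---- initialization candidates
    candidates = [RigidTransform.identity()]
    if init == "principal":
        mc, maxes = _principal_frame(mv)
        rc, raxes = _principal_frame(ref_pts)
        candidates = []
        for fx, fy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
            flip = np.diag([fx, fy, fx * fy])
            r = raxes @ flip @ maxes.T
            candidates.append(RigidTransform(r, rc - r @ mc))
    best_t, best_obj = None, np.inf
    for cand in candidates:
        _, d = closest(cand.apply(sample))
        if d.mean() < best_obj:
            best_obj, best_t = float(d.mean()), cand

    transform, obj = best_t, best_obj
    for _ in range(int(max_iter)):
        cur = transform.apply(sample)
        targets, d = closest(cur)
        step = _rigid_fit(cur, targets)
        new_transform = step.compose(transform)
        _, d_new = closest(new_transform.apply(sample))
        if d_new.mean() > obj:       # overshoot: keep previous iterate
            break
        transform = new_transform
        if obj - d_new.mean() < tol:
            obj = float(d_new.mean())
            break
        obj = float(d_new.mean())
    aligned = transform.apply(mv)
    if hasattr(moving, "faces"):
        aligned = _as_mesh(aligned, moving.faces)
    return transform, aligned, obj


def cut_femoral_shaft(mesh: trimesh.Trimesh, keep_length: float = 70.0,
                      axis: int = 1) -> trimesh.Trimesh:
    """Cut the femoral shaft at ``keep_length`` mm from the bottom of the
    bounding box along the shaft axis, capping the cut so the result stays
    closed. Meshes shorter than ``keep_length`` are returned unchanged."""
    lo = float(mesh.bounds[0, axis])
    extent = float(mesh.bounds[1, axis] - lo)
    if extent <= keep_length:
        log.warning("mesh extent %.1f mm along axis %d is within the keep "
                    "length %.1f mm; returning unchanged", extent, axis, keep_length)
        return mesh.copy()
    normal = np.zeros(3)
    normal[axis] = -1.0
    origin = mesh.bounds.mean(axis=0).copy()
    origin[axis] = lo + keep_length
    cut = trimesh.intersections.slice_mesh_plane(mesh, plane_normal=normal,
                                                 plane_origin=origin, cap=False)
    cut = trimesh.Trimesh(cut.vertices, cut.faces, process=True)  # merge dups
    cut.remove_unreferenced_vertices()
    cut = _cap_boundary_loops(cut, cap_normal=-normal)
    if not cut.is_watertight:
        raise ValueError("shaft cut failed to produce a closed surface")
    return cut


def _cap_boundary_loops(mesh: trimesh.Trimesh, cap_normal) -> trimesh.Trimesh:
    """Close each open boundary loop with a planar fan from its centroid,
    wound so the cap normal points along ``cap_normal`` (outward)."""
    edges = mesh.edges_sorted
    unique, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = unique[counts == 1]
    if len(boundary) == 0:
        return mesh
    # walk boundary edges into loops
    adj: dict[int, list] = {}
    for a, b in boundary:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    seen = set()
    verts = mesh.vertices.copy()
    faces = mesh.faces.tolist()
    cap_normal = np.asarray(cap_normal, dtype=float)
    for start in sorted(adj):
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        cur = start
        while True:
            nxt = next((n for n in adj[cur] if n not in seen), None)
            if nxt is None:
                break
            loop.append(nxt)
            seen.add(nxt)
            cur = nxt
        if len(loop) < 3:
            continue
        center = verts[loop].mean(axis=0)
        ci = len(verts)
        verts = np.vstack([verts, center])
        ring = loop + [loop[0]]
        for a, b in zip(ring[:-1], ring[1:]):
            n = np.cross(verts[a] - center, verts[b] - center)
            faces.append([ci, a, b] if n @ cap_normal > 0 else [ci, b, a])
    return trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
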