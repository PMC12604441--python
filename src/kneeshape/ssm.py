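"""Statistical shape modeling: groupwise rigid alignment, point
correspondence and PCA modes of variation.

The model follows the classic point-distribution construction: after
groupwise rigid registration (no scaling — size differences are themselves
of interest in a growing population), every shape is re-expressed as an
ordered set of P corresponding surface points; PCA of the stacked 3P-vectors
yields the mean shape, orthonormal modes and eigenvalues. Mode scores are
reported in SD units (raw coefficient divided by sqrt(eigenvalue)), the
scale on which ±3 SD reconstructions and distance maps are defined.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import trimesh
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .meshing import RigidTransform, _rigid_fit
from .surface import SurfaceQuery

log = logging.getLogger(__name__)


def _as_points(shape) -> np.ndarray:
    pts = np.asarray(shape.vertices if hasattr(shape, "vertices") else shape, float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("shape must be a (P, 3) point set or a mesh")
    if len(pts) == 0:
        raise ValueError("empty shape")
    return pts


def groupwise_align(shapes, max_iter: int = 50, tol: float = 1e-6):
    """Unbiased groupwise rigid alignment of same-cardinality point sets.

    Iterates: rigidly fit every shape to the current mean, recompute the
    mean, until the mean moves by less than ``tol`` mm (max vertex change) or
    ``max_iter`` is reached. The initial mean is the average of the centered
    input shapes, so the result does not depend on input order. No scaling
    or reflection is ever applied.

    Returns ``(aligned point sets, transforms)``.
    """
    pts = [_as_points(s) for s in shapes]
    if len(pts) < 2:
        raise ValueError("groupwise alignment needs at least 2 shapes")
    p0 = len(pts[0])
    if any(len(p) != p0 for p in pts):
        raise ValueError("groupwise_align requires equal point counts; "
                         "run correspondence against a template first")
    transforms = []
    centered = [p - p.mean(axis=0) for p in pts]
    mean = np.mean(centered, axis=0)
    aligned = list(pts)
    for it in range(int(max_iter)):
        transforms = [_rigid_fit(p, mean) for p in pts]
        aligned = [t.apply(p) for t, p in zip(transforms, pts)]
        new_mean = np.mean(aligned, axis=0)
        shift = float(np.abs(new_mean - mean).max())
        mean = new_mean
        if shift < tol:
            break
    else:
        log.warning("groupwise alignment did not converge in %d iterations", max_iter)
    return aligned, transforms


def choose_template(aligned_shapes) -> int:
    """Index of the shape minimizing summed RMSD to all others (a
    deterministic, data-driven stand-in for a manually chosen reference)."""
    arr = np.stack([_as_points(s) for s in aligned_shapes])
    flat = arr.reshape(len(arr), -1)
    sq = (flat ** 2).sum(axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * flat @ flat.T, 0.0)
    return int(np.sqrt(d2).sum(axis=1).argmin())


def correspond(aligned_shapes, template=None, faces=None) -> np.ndarray:
    """Closest-point correspondence of every aligned shape to a template.

    Point j of the output for a given shape is the closest point on that
    shape's surface (when ``faces`` provide one) or its closest vertex to
    template point j, so all shapes share the template's cardinality P.

    Returns an (N, P, 3) array of corresponded point sets.
    """
    shapes = list(aligned_shapes)
    if template is None:
        template = shapes[choose_template(shapes)]
    tpts = _as_points(template)
    out = np.empty((len(shapes), len(tpts), 3))
    for i, s in enumerate(shapes):
        spts = _as_points(s)
        sfaces = faces
        if hasattr(s, "faces") and len(getattr(s, "faces", ())) > 0:
            sfaces = s.faces
        if sfaces is not None:
            mesh = trimesh.Trimesh(vertices=spts, faces=sfaces, process=False)
            out[i], _, _ = SurfaceQuery(mesh).closest(tpts)
        else:
            from scipy.spatial import cKDTree

            _, idx = cKDTree(spts).query(tpts)
            out[i] = spts[idx]
    return out


class StatisticalShapeModel(BaseEstimator, TransformerMixin):
    """PCA shape model over corresponded point sets.

    Parameters
    ----------
    n_modes : int or None
        Number of modes to retain; ``None`` keeps all nonzero modes
        (``min(N-1, 3P)``).

    Attributes (after :meth:`fit`)
    ------------------------------
    mean_ : (3P,) mean shape vector in mm.
    modes_ : (3P, M) orthonormal mode matrix (columns).
    eigenvalues_ : (M,) descending variances in mm².
    explained_fraction_ : (M,) eigenvalue fractions of the total variance.
    n_points_, n_samples_ : problem sizes.

    ``transform`` maps shapes to SD-unit scores; ``inverse_transform`` maps
    SD-unit scores back to point coordinates.
    """

    def __init__(self, n_modes: int | None = None):
        self.n_modes = n_modes

    # ------------------------------------------------------------- helpers
    @staticmethod
    def _to_matrix(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            X = X.reshape(X.shape[0], -1)
        if X.ndim != 2:
            raise ValueError("expected (N, 3P) or (N, P, 3) input")
        return X

    # ----------------------------------------------------------------- API
    def fit(self, X, y=None):
        X = self._to_matrix(X)
        n, d = X.shape
        if n < 3:
            raise ValueError("need at least 3 shapes to build a model")
        m_max = min(n - 1, d)
        m = m_max if self.n_modes is None else min(int(self.n_modes), m_max)
        pca = PCA(n_components=m_max, svd_solver="full")
        pca.fit(X)
        total = pca.explained_variance_.sum()
        modes = pca.components_[:m].T.copy()
        # deterministic sign: largest-magnitude loading of each mode positive
        peak = np.abs(modes).argmax(axis=0)
        sign = np.sign(modes[peak, np.arange(m)])
        sign[sign == 0] = 1.0
        modes *= sign
        self.mean_ = pca.mean_
        self.modes_ = modes
        self.eigenvalues_ = pca.explained_variance_[:m].copy()
        self.explained_fraction_ = self.eigenvalues_ / total
        self.n_samples_ = n
        self.n_points_ = d // 3
        return self

    def transform(self, X) -> np.ndarray:
        """Project shapes onto the modes; scores are in SD units."""
        check_is_fitted(self, "modes_")
        X = self._to_matrix(np.asarray(X))
        coeff = (X - self.mean_) @ self.modes_
        lam = self.eigenvalues_
        zero = lam <= 0
        if zero.any():
            warnings.warn("zero-variance modes projected to score 0")
        scale = np.where(zero, np.inf, np.sqrt(np.where(zero, 1.0, lam)))
        return coeff / scale

    def inverse_transform(self, scores_sd) -> np.ndarray:
        """Reconstruct shapes from SD-unit scores: mean + Σ s_k √λ_k φ_k."""
        check_is_fitted(self, "modes_")
        s = np.atleast_2d(np.asarray(scores_sd, dtype=float))
        if not np.isfinite(s).all():
            raise ValueError("scores must be finite")
        if s.shape[1] > self.modes_.shape[1]:
            raise ValueError("score vector longer than the number of modes")
        coeff = s * np.sqrt(self.eigenvalues_[: s.shape[1]])
        out = self.mean_ + coeff @ self.modes_[:, : s.shape[1]].T
        return out if np.asarray(scores_sd).ndim > 1 else out[0]

    # ------------------------------------------------------------- extras
    @property
    def mean_points_(self) -> np.ndarray:
        check_is_fitted(self, "mean_")
        return self.mean_.reshape(-1, 3)

    def select_modes(self, min_fraction: float = 0.01) -> np.ndarray:
        """Indices of modes explaining at least ``min_fraction`` of the
        total population variance, in descending-eigenvalue order."""
        check_is_fitted(self, "explained_fraction_")
        return np.flatnonzero(self.explained_fraction_ >= min_fraction)

    def distance_map(self, mode: int, sd: float = 3.0,
                     faces: np.ndarray | None = None) -> dict:
        """Per-vertex distance (mm) between the ±``sd`` reconstructions of
        one mode and the mean shape; signed along the outward mean-surface
        normal when ``faces`` are supplied."""
        check_is_fitted(self, "modes_")
        m = self.modes_.shape[1]
        if not 0 <= mode < m:
            raise ValueError(f"mode {mode} outside [0, {m})")
        e = np.zeros(m)
        out = {}
        mean_pts = self.mean_points_
        normals = None
        if faces is not None:
            mesh = trimesh.Trimesh(vertices=mean_pts, faces=faces, process=False)
            normals = np.asarray(mesh.vertex_normals)
        for label, s in (("plus", sd), ("minus", -sd)):
            e[mode] = s
            delta = self.inverse_transform(e).reshape(-1, 3) - mean_pts
            d = np.linalg.norm(delta, axis=1)
            if normals is not None:
                d = d * np.sign((delta * normals).sum(axis=1) + 1e-300)
            out[label] = d
        return out

    # ------------------------------------------------------------- storage
    def save(self, path, metadata: dict | None = None) -> None:
        check_is_fitted(self, "modes_")
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), mean=self.mean_,
                            modes=self.modes_, eigenvalues=self.eigenvalues_,
                            explained_fraction=self.explained_fraction_)
        meta = {"n_points": int(self.n_points_), "n_samples": int(self.n_samples_)}
        meta.update(metadata or {})
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "StatisticalShapeModel":
        path = Path(path)
        arr = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(n_modes=arr["modes"].shape[1])
        model.mean_ = arr["mean"]
        model.modes_ = arr["modes"]
        model.eigenvalues_ = arr["eigenvalues"]
        model.explained_fraction_ = arr["explained_fraction"]
        model.n_points_ = meta["n_points"]
        model.n_samples_ = meta["n_samples"]
        return model


# --------------------------------------------------------- thin functional API
def build_model(corresponded, n_modes: int | None = None) -> StatisticalShapeModel:
    return StatisticalShapeModel(n_modes=n_modes).fit(corresponded)


def project(shape, model: StatisticalShapeModel) -> np.ndarray:
    return model.transform(np.asarray(shape).reshape(1, -1))[0]


def reconstruct(model: StatisticalShapeModel, scores_sd) -> np.ndarray:
    return model.inverse_transform(scores_sd)


def select_modes(fractions, min_fraction: float = 0.01) -> np.ndarray:
    """Indices of explained-variance fractions at or above the cutoff
    (fractions and cutoff on the same scale, e.g. both in [0, 1])."""
    fractions = np.asarray(list(fractions), dtype=float)
    return np.flatnonzero(fractions >= min_fraction)
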