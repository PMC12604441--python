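"""Synthetic cohorts and bone-like shape populations with known ground truth.

The raw MRI cohort behind the original analysis is not redistributable, so
every downstream stage is exercised on simulated data: a covariate table
drawn to match the published participant characteristics (sex ratio, age
14.1 ± 0.67 y, BMI-SDS 0.43 ± 1.2, 70% sports participation, 5.3 ± 1.8
active days/week, 62% active transport), and populations of bone-like
meshes sampled from a known mean + orthonormal modes with chosen
eigenvalues. Mode scores can be linked to covariates and are correlated
between the two knees of a subject through a shared subject-level Gaussian
component (variance ``rho``) plus a knee-level component (variance
``1 - rho``), which yields exactly exchangeable within-subject correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .surface import points_inside
from .volumes import LabelVolume

COVARIATE_COLUMNS = ("subject_id", "side", "sex", "age", "bmi_sds", "sports13",
                     "sports9and13", "pa_days", "active_transport")

#: numeric coding used when effects reference a covariate
_NUMERIC = {
    "sex": {"girl": 0.0, "boy": 1.0},
    "sports13": {"no": 0.0, "yes": 1.0},
    "active_transport": {"no": 0.0, "yes": 1.0},
    "sports9and13": {"none": 0.0, "only13": 0.0, "both": 1.0},
}


@dataclass
class CohortConfig:
    """Distribution settings for the simulated cohort (defaults match the
    published participant characteristics table)."""

    p_girl: float = 0.52
    age_mean: float = 14.1
    age_sd: float = 0.67
    bmi_sds_mean: float = 0.43
    bmi_sds_sd: float = 1.2
    p_sports13: float = 0.70
    p_both_given_sports13: float = 0.655   # 877 of 1338 sport participants
    pa_days_mean: float = 5.3
    pa_days_sd: float = 1.8
    p_active_transport: float = 0.62
    missing_rates: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("p_girl", "p_sports13", "p_both_given_sports13",
                     "p_active_transport"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        for name, v in self.missing_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"missing rate for {name} outside [0, 1]: {v}")
            if name not in COVARIATE_COLUMNS:
                raise ValueError(f"unknown covariate in missing_rates: {name}")


def generate_cohort(n_subjects: int, config: CohortConfig | None = None,
                    seed: int = 0) -> pd.DataFrame:
    """Simulate a knee-level cohort table (two knee rows per subject).

    Returns a DataFrame with one row per knee and the covariate columns
    ``subject_id, side, sex, age, bmi_sds, sports13, sports9and13, pa_days,
    active_transport``. Deterministic given ``(n_subjects, config, seed)``.
    """
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)

    sex = np.where(rng.random(n_subjects) < cfg.p_girl, "girl", "boy")
    age = rng.normal(cfg.age_mean, cfg.age_sd, n_subjects)
    bmi = rng.normal(cfg.bmi_sds_mean, cfg.bmi_sds_sd, n_subjects)
    sports13 = np.where(rng.random(n_subjects) < cfg.p_sports13, "yes", "no")
    both = rng.random(n_subjects) < cfg.p_both_given_sports13
    sports9and13 = np.where(sports13 == "yes",
                            np.where(both, "both", "only13"), "none")
    pa = np.clip(np.round(rng.normal(cfg.pa_days_mean, cfg.pa_days_sd,
                                     n_subjects)), 0, 7).astype(int)
    transport = np.where(rng.random(n_subjects) < cfg.p_active_transport, "yes", "no")

    subj = pd.DataFrame({
        "subject_id": [f"S{i:05d}" for i in range(n_subjects)],
        "sex": sex, "age": age, "bmi_sds": bmi, "sports13": sports13,
        "sports9and13": sports9and13, "pa_days": pa,
        "active_transport": transport,
    })
    for name, rate in cfg.missing_rates.items():
        mask = rng.random(n_subjects) < rate
        subj.loc[mask, name] = np.nan

    knees = subj.loc[subj.index.repeat(2)].reset_index(drop=True)
    knees.insert(1, "side", np.tile(["left", "right"], n_subjects))
    return knees[list(COVARIATE_COLUMNS)]


# --------------------------------------------------------------- truth model
@dataclass
class GroundTruthShapeModel:
    """Known population model: mean points + orthonormal modes + eigenvalues."""

    mean_points: np.ndarray          # (P, 3) mm
    true_modes: np.ndarray           # (3P, K) orthonormal columns
    true_eigenvalues: np.ndarray     # (K,) mm², descending
    residual_sd: float = 0.0         # isotropic per-coordinate noise, mm
    faces: np.ndarray | None = None  # template topology, if any

    def __post_init__(self):
        self.mean_points = np.asarray(self.mean_points, float)
        self.true_modes = np.asarray(self.true_modes, float)
        self.true_eigenvalues = np.asarray(self.true_eigenvalues, float)
        p = len(self.mean_points)
        if p < 4:
            raise ValueError("need at least 4 mean points")
        k = self.true_modes.shape[1]
        if self.true_modes.shape != (3 * p, k):
            raise ValueError("mode matrix must be (3P, K)")
        gram = self.true_modes.T @ self.true_modes
        if not np.allclose(gram, np.eye(k), atol=1e-8):
            raise ValueError("modes are not orthonormal")
        if k and ((self.true_eigenvalues <= 0).any()
                  or (np.diff(self.true_eigenvalues) > 0).any()):
            raise ValueError("eigenvalues must be positive and descending")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")

    @property
    def n_points(self) -> int:
        return len(self.mean_points)


def _smooth_fields(points: np.ndarray, n: int, rng) -> np.ndarray:
    """Smooth candidate displacement fields (3P each): global scalings,
    axis stretches and seeded low-order polynomial modulations."""
    p = points - points.mean(axis=0)
    scale = np.abs(p).max() or 1.0
    q = p / scale
    fields = [p.ravel()]                               # isotropic size
    for ax in range(2):   # two axis stretches (third is dependent given size)
        f = np.zeros_like(p)
        f[:, ax] = p[:, ax]
        fields.append(f.ravel())
    while len(fields) < n:
        coef = rng.normal(size=(3, 10))
        x, y, z = q.T
        basis = np.stack([np.ones_like(x), x, y, z, x * y, y * z, x * z,
                          x ** 2, y ** 2, z ** 2])
        fields.append((coef @ basis).T.ravel())
    return np.column_stack(fields[:n])


def make_truth_model(template, k_modes: int, eigenvalues,
                     residual_sd: float = 0.0, seed: int = 0) -> GroundTruthShapeModel:
    """Build a ground-truth shape model on a template mesh.

    Modes are smooth displacement fields (size, stretches, random low-order
    polynomial deformations) orthonormalized by QR; the mean equals the
    template vertices.
    """
    points = np.asarray(template.vertices if hasattr(template, "vertices")
                        else template, float)
    eigenvalues = np.asarray(list(eigenvalues), float)
    if len(eigenvalues) != k_modes:
        raise ValueError("eigenvalues must have length k_modes")
    if k_modes > 3 * len(points):
        raise ValueError(f"k_modes={k_modes} exceeds 3P={3 * len(points)}")
    if k_modes and (eigenvalues <= 0).any():
        raise ValueError("eigenvalues must be strictly positive")
    order = np.argsort(eigenvalues)[::-1]
    eigenvalues = eigenvalues[order]
    rng = np.random.default_rng(seed)
    if k_modes:
        cand = _smooth_fields(points, k_modes, rng)
        q, r = np.linalg.qr(cand)
        q *= np.sign(np.diag(r))[None, :]
        modes = q[:, :k_modes]
    else:
        modes = np.zeros((3 * len(points), 0))
    faces = np.asarray(template.faces) if hasattr(template, "faces") else None
    return GroundTruthShapeModel(points, modes, eigenvalues,
                                 residual_sd=residual_sd, faces=faces)


# ---------------------------------------------------------------- sampling
@dataclass
class EffectSpec:
    """Covariate-linked mode scores: ``effects[(mode, covariate)]`` is the
    shift in SD units per covariate unit; ``within_subject_rho`` is the
    exchangeable correlation of the score noise between a subject's knees."""

    effects: dict = field(default_factory=dict)
    within_subject_rho: float = 0.8

    def __post_init__(self):
        if not 0.0 <= self.within_subject_rho < 1.0:
            raise ValueError("within_subject_rho must lie in [0, 1)")
        for (k, c), v in self.effects.items():
            if not np.isfinite(v):
                raise ValueError(f"effect for mode {k}, covariate {c} not finite")


def covariate_numeric(cohort: pd.DataFrame, name: str) -> np.ndarray:
    """Numeric coding of a covariate column (girl/no/none reference = 0)."""
    if name not in cohort.columns:
        raise KeyError(f"covariate '{name}' not present in the cohort table")
    col = cohort[name]
    if name in _NUMERIC:
        return col.map(_NUMERIC[name]).to_numpy(dtype=float)
    return col.to_numpy(dtype=float)


def sample_scores(truth_k: int, cohort: pd.DataFrame, effects: EffectSpec,
                  seed: int = 0) -> pd.DataFrame:
    """Draw per-knee true mode scores: covariate shift + shared subject
    deviation (variance rho) + knee deviation (variance 1 - rho)."""
    rng = np.random.default_rng(seed)
    subjects, subj_idx = np.unique(cohort["subject_id"], return_inverse=True)
    n_knees = len(cohort)
    rho = effects.within_subject_rho
    scores = np.empty((n_knees, truth_k))
    for k in range(truth_k):
        eta = np.zeros(n_knees)
        for (mode, cov), beta in effects.effects.items():
            if mode == k:
                eta += beta * covariate_numeric(cohort, cov)
        z_subj = rng.standard_normal(len(subjects))[subj_idx]
        z_knee = rng.standard_normal(n_knees)
        scores[:, k] = eta + np.sqrt(rho) * z_subj + np.sqrt(1.0 - rho) * z_knee
    out = cohort[["subject_id", "side"]].copy()
    for k in range(truth_k):
        out[f"mode_{k + 1}"] = scores[:, k]
    return out


def sample_shapes(truth: GroundTruthShapeModel, cohort: pd.DataFrame,
                  effects: EffectSpec | None = None, seed: int = 0):
    """Sample one point set per knee row of ``cohort``.

    shape = mean + Σ_k score_k √λ_k mode_k + N(0, residual_sd²) per
    coordinate, with scores from :func:`sample_scores` (unit marginal noise
    variance before covariate shifts).

    Returns ``(shapes (n_knees, P, 3), true score table)``.
    """
    effects = effects or EffectSpec()
    k = len(truth.true_eigenvalues)
    score_df = sample_scores(k, cohort, effects, seed=seed)
    scores = score_df.filter(like="mode_").to_numpy() if k else np.zeros((len(cohort), 0))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    coeff = scores * np.sqrt(truth.true_eigenvalues)
    flat = truth.mean_points.ravel() + coeff @ truth.true_modes.T
    if truth.residual_sd > 0:
        flat = flat + rng.normal(0.0, truth.residual_sd, size=flat.shape)
    return flat.reshape(len(cohort), truth.n_points, 3), score_df


# ---------------------------------------------------------------- templates
def patella_template(radii=(15.0, 17.5, 7.5), subdivisions: int = 3) -> trimesh.Trimesh:
    """Patella-like tri-axial ellipsoid (default ~30 × 35 × 15 mm)."""
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    mesh.vertices *= np.asarray(radii, dtype=float)
    return mesh


def femur_template(shaft_length: float = 110.0, shaft_radius: float = 12.0,
                   condyle_radius: float = 16.0, condyle_offset: float = 11.0,
                   grid_mm: float = 2.5) -> trimesh.Trimesh:
    """Distal-femur-like surface: a vertical shaft capsule topped by two
    condylar blobs, generated as the zero level set of a union of signed
    distance fields (watertight, single component). The shaft runs along +y.
    """
    import skimage.measure as _measure

    pad = condyle_radius + 3 * grid_mm
    xs = np.arange(-pad - condyle_offset, pad + condyle_offset, grid_mm)
    ys = np.arange(-pad, shaft_length + pad, grid_mm)
    zs = np.arange(-pad, pad, grid_mm)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")

    def capsule(px, py, pz, a_y, b_y, r):
        t = np.clip((py - a_y) / (b_y - a_y), 0, 1)
        return np.sqrt(px ** 2 + (py - (a_y + t * (b_y - a_y))) ** 2 + pz ** 2) - r

    def sphere(px, py, pz, cx, cy, cz, r):
        return np.sqrt((px - cx) ** 2 + (py - cy) ** 2 + (pz - cz) ** 2) - r

    sdf = np.minimum(
        capsule(X, Y, Z, condyle_radius, shaft_length - shaft_radius, shaft_radius),
        np.minimum(
            sphere(X, Y, Z, -condyle_offset, condyle_radius * 0.8, 2.0, condyle_radius),
            sphere(X, Y, Z, condyle_offset, condyle_radius * 0.8, 2.0, condyle_radius),
        ),
    )
    verts, faces, _, _ = _measure.marching_cubes(-sdf, level=0.0,
                                                 spacing=(grid_mm,) * 3)
    verts += np.array([xs[0], ys[0], zs[0]])
    mesh = trimesh.Trimesh(verts, faces, process=True)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


# ---------------------------------------------------------------- voxelize
def voxelize(mesh: trimesh.Trimesh, spacing: float = 0.7, label: int = 1,
             classes=("background", "patella", "femur", "tibia"),
             margin_voxels: int = 2) -> LabelVolume:
    """Rasterize a closed mesh: a voxel is labeled iff its center lies
    inside the surface."""
    if spacing <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    if not mesh.is_watertight:
        raise ValueError("voxelize requires a watertight (closed) mesh")
    lo = mesh.bounds[0] - margin_voxels * spacing
    hi = mesh.bounds[1] + margin_voxels * spacing
    counts = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    axes = [lo[d] + (np.arange(counts[d]) + 0.5) * spacing for d in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    centers = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    inside = points_inside(mesh, centers).reshape(counts)
    grid = np.where(inside, np.int16(label), np.int16(0))
    return LabelVolume(grid, classes, (spacing,) * 3, tuple(lo + 0.5 * spacing))
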