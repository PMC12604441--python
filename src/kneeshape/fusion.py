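"""Probabilistic combination of multi-atlas and appearance segmentations.

The spatial component is the arithmetic mean of deformed atlas labels; the
appearance component is a pluggable per-voxel classifier. The two are pooled
log-linearly, with the appearance probabilities raised to a power ``alpha``
in [0, 1] before multiplication and per-voxel renormalization, so that
``alpha = 0`` reproduces the atlas prior and ``alpha = 1`` the plain product
rule. ``alpha`` is tuned by leave-one-out cross-validation over the atlases
using the mean Dice similarity coefficient of the foreground classes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import LabelVolume

log = logging.getLogger(__name__)


@dataclass
class FusionConfig:
    """Settings for probability combination and alpha tuning."""

    alpha: float = 0.4
    alpha_grid: tuple = tuple(np.round(np.arange(0.0, 1.01, 0.1), 1))
    min_atlas_dice: float | None = None   # optional atlas-exclusion threshold

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")
        grid = tuple(sorted(set(float(a) for a in self.alpha_grid)))
        if any(a < 0 or a > 1 for a in grid):
            raise ValueError("alpha grid values must lie in [0, 1]")
        self.alpha_grid = grid


def fuse_atlas_labels(atlases, ids=None) -> LabelVolume:
    """Average deformed atlas labels into a per-voxel class probability map."""
    atlases = list(atlases)
    if not atlases:
        raise ValueError("need at least one atlas to fuse")
    ids = list(ids) if ids is not None else [f"atlas_{i}" for i in range(len(atlases))]
    ref = atlases[0]
    probs = []
    for vol, name in zip(atlases, ids):
        if not vol.same_grid(ref):
            raise ValueError(f"atlas '{name}' is not on the common grid")
        probs.append(vol.one_hot().data)
    mean = np.mean(probs, axis=0)
    return LabelVolume(mean, ref.classes, ref.spacing, ref.origin)


def combine_probabilities(spatial: LabelVolume, appearance: LabelVolume,
                          alpha: float) -> LabelVolume:
    """Log-linear pool: ``spatial * appearance**alpha``, renormalized per voxel."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    if not spatial.same_grid(appearance) or spatial.classes != appearance.classes:
        raise ValueError("spatial and appearance volumes must share grid and classes")
    sp = spatial.one_hot().data.astype(float)
    ap = appearance.one_hot().data.astype(float)
    if alpha == 0.0:
        out = sp.copy()
    else:
        out = sp * np.power(ap, alpha)
    total = out.sum(axis=-1)
    dead = total <= 0.0
    if dead.any():
        # no class supported at all: fall back to background
        out[dead] = 0.0
        out[dead, 0] = 1.0
        total = out.sum(axis=-1)
        log.debug("combine_probabilities: %d voxels with zero total probability "
                  "assigned to background", int(dead.sum()))
    return LabelVolume(out / total[..., None], spatial.classes,
                       spatial.spacing, spatial.origin)


def argmax_labels(prob: LabelVolume) -> LabelVolume:
    """Per-voxel maximum-probability class; ties go to the non-background
    class of lowest index (background wins only when it is strictly larger)."""
    if not prob.is_probability:
        raise ValueError("argmax_labels expects a probability-mode volume")
    p = prob.data
    # order classes (1, 2, ..., 0) so that on exact ties a bone class wins
    order = np.r_[np.arange(1, p.shape[-1]), 0]
    labels = order[np.argmax(p[..., order], axis=-1)]
    return LabelVolume(labels.astype(np.int16), prob.classes, prob.spacing, prob.origin)


def dice(a: LabelVolume, b: LabelVolume, class_id: int) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|) for one class.

    Both masks empty is defined as perfect agreement (1.0).
    """
    if a.is_probability or b.is_probability:
        raise ValueError("dice expects label-mode volumes")
    if not a.same_grid(b):
        raise ValueError("volumes are not on the same grid")
    ma = a.data == class_id
    mb = b.data == class_id
    denom = int(ma.sum()) + int(mb.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((ma & mb).sum()) / denom


def mean_foreground_dice(a: LabelVolume, b: LabelVolume) -> float:
    return float(np.mean([dice(a, b, c) for c in range(1, len(a.classes))]))


# ------------------------------------------------------------------ plugins
class IdentityRegistration:
    """Trivial registration: atlas labels are already on the target grid."""

    def __call__(self, moving: LabelVolume, fixed: LabelVolume) -> LabelVolume:
        return moving


class ShiftWarp:
    """Synthetic deformation: nearest-neighbour shift by a fixed voxel offset."""

    def __init__(self, shift_voxels=(0, 0, 0)):
        self.shift_voxels = tuple(shift_voxels)

    def __call__(self, moving: LabelVolume, fixed: LabelVolume) -> LabelVolume:
        out = ndimage.shift(moving.data, self.shift_voxels, order=0,
                            mode="constant", cval=0)
        return LabelVolume(out.astype(moving.data.dtype), moving.classes,
                           moving.spacing, moving.origin)


class OracleClassifier:
    """Appearance model that returns the target's one-hot reference labels.

    Useful as an upper bound in tests: combining with a perfect appearance
    component can only help.
    """

    def __call__(self, target: LabelVolume) -> LabelVolume:
        return target.one_hot()


class UniformClassifier:
    """Uninformative appearance model: equal probability for every class."""

    def __call__(self, target: LabelVolume) -> LabelVolume:
        k = len(target.classes)
        p = np.full(target.grid_shape + (k,), 1.0 / k)
        return LabelVolume(p, target.classes, target.spacing, target.origin)


class IntensityThresholdClassifier:
    """Toy probabilistic voxel classifier from a scalar intensity image.

    Each class is modelled with a Gaussian class-conditional density on the
    intensity; posterior probabilities assume equal priors. Stands in for a
    trained appearance model in tests and demos.
    """

    def __init__(self, intensity_image: np.ndarray, class_means, class_sd=1.0):
        self.image = np.asarray(intensity_image, dtype=float)
        self.class_means = np.asarray(class_means, dtype=float)
        self.class_sd = float(class_sd)

    def __call__(self, target: LabelVolume) -> LabelVolume:
        if self.image.shape != target.grid_shape:
            raise ValueError("intensity image does not match target grid")
        z = (self.image[..., None] - self.class_means) / self.class_sd
        loglik = -0.5 * z ** 2
        loglik -= loglik.max(axis=-1, keepdims=True)
        p = np.exp(loglik)
        p /= p.sum(axis=-1, keepdims=True)
        return LabelVolume(p, target.classes, target.spacing, target.origin)


# ------------------------------------------------------------------ tuning
def tune_alpha_loocv(atlases, classifier, grid=None, registration=None,
                     ids=None):
    """Tune the appearance exponent by leave-one-out cross-validation.

    For every held-out atlas the remaining atlases are registered to it and
    fused into the spatial prior; the classifier provides the appearance
    probabilities; the pooled segmentation at each candidate ``alpha`` is
    scored by mean foreground Dice against the held-out reference labels.

    Returns
    -------
    best_alpha : float
        Argmax of the mean Dice over the grid; ties resolved toward the
        smaller alpha.
    table : pandas.DataFrame with columns ``alpha`` and ``mean_dice``.
    """
    atlases = list(atlases)
    if len(atlases) < 2:
        raise ValueError("leave-one-out tuning needs at least 2 atlases")
    grid = FusionConfig(alpha_grid=grid).alpha_grid if grid is not None \
        else FusionConfig().alpha_grid
    registration = registration or IdentityRegistration()
    ids = list(ids) if ids is not None else [f"atlas_{i}" for i in range(len(atlases))]

    scores = np.zeros((len(grid), len(atlases)))
    for i, target in enumerate(atlases):
        others = [registration(a, target) for j, a in enumerate(atlases) if j != i]
        spatial = fuse_atlas_labels(others)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            appearance = classifier(target)
        for g, alpha in enumerate(grid):
            combined = combine_probabilities(spatial, appearance, alpha)
            scores[g, i] = mean_foreground_dice(argmax_labels(combined), target)

    mean_dice = scores.mean(axis=1)
    best = int(np.argmax(np.round(mean_dice, 12)))  # first argmax -> smallest alpha
    table = pd.DataFrame({"alpha": grid, "mean_dice": mean_dice})
    return float(grid[best]), table
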