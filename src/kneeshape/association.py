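"""Shape-mode / exposure association by generalized estimating equations.

One Gaussian identity-link GEE per (shape mode, exposure) pair, clustered on
subject so that the correlation between a subject's two knees is taken into
account, adjusted for sex and age, with robust (sandwich) standard errors.
95% CIs use the normal multiplier 1.96 and p-values the normal reference.
Multiple testing over the included modes is handled with a Bonferroni
threshold 0.05 / (number of included modes).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .synthetic import _NUMERIC

Z95 = 1.959963984540054


@dataclass(frozen=True)
class ExposureSpec:
    """One exposure per model fit.

    ``levels`` restricts a categorical exposure to a two-level comparison
    (rows at other levels are excluded from that fit); ``reference`` is the
    level coded 0.
    """

    name: str
    kind: str = "continuous"            # continuous | binary | categorical
    reference: str | None = None
    comparison: str | None = None       # level coded 1 (categorical/binary)

    def code(self, col: pd.Series) -> pd.Series:
        if self.kind == "continuous":
            return pd.to_numeric(col, errors="coerce")
        ref, cmp_ = self.reference, self.comparison
        out = pd.Series(np.nan, index=col.index, dtype=float)
        out[col == ref] = 0.0
        out[col == cmp_] = 1.0
        return out


#: the five loading exposures of the analysis, with their reference coding
STANDARD_EXPOSURES = (
    ExposureSpec("bmi_sds", "continuous"),
    ExposureSpec("sports13", "binary", reference="no", comparison="yes"),
    ExposureSpec("sports9and13", "categorical", reference="only13", comparison="both"),
    ExposureSpec("pa_days", "continuous"),
    ExposureSpec("active_transport", "binary", reference="no", comparison="yes"),
)


@dataclass
class AssociationResult:
    mode: int
    exposure: str
    beta: float
    ci_low: float
    ci_high: float
    p_value: float
    n_knees: int
    n_subjects: int
    sex_p: float
    age_p: float
    threshold: float | None = None
    significant: bool | None = None

    def with_threshold(self, threshold: float) -> "AssociationResult":
        return replace(self, threshold=threshold,
                       significant=bool(self.p_value < threshold))


def bonferroni_threshold(n_modes: int) -> float:
    """Familywise 0.05 split over the included modes: 0.05 / n_modes."""
    if n_modes < 1:
        raise ValueError(f"n_modes must be >= 1, got {n_modes}")
    return 0.05 / n_modes


def _working(structure: str):
    from statsmodels.genmod import cov_struct

    if structure == "exchangeable":
        return cov_struct.Exchangeable()
    if structure == "independence":
        return cov_struct.Independence()
    raise ValueError(f"unknown working correlation: {structure!r}")


def fit_gee(data: pd.DataFrame, outcome: str, exposure: ExposureSpec,
            covariates=("sex", "age"), cluster: str = "subject_id",
            working: str = "exchangeable", mode: int = 0) -> AssociationResult:
    """Fit one GEE and return the exposure coefficient with robust CI/p.

    ``data`` holds one row per knee. Complete-case (listwise) deletion is
    applied over the fitted variables only. Sex is coded girl = 0 / boy = 1.
    """
    df = pd.DataFrame({
        "y": pd.to_numeric(data[outcome], errors="coerce"),
        "x": exposure.code(data[exposure.name]),
        "cluster": data[cluster],
    })
    for cov in covariates:
        if cov == "sex":
            df["sex"] = data["sex"].map(_NUMERIC["sex"])
        else:
            df[cov] = pd.to_numeric(data[cov], errors="coerce")
    df = df.dropna()
    if df["cluster"].nunique() < 2:
        raise ValueError("need at least 2 clusters (subjects) to fit a GEE")
    if df["x"].nunique() < 2:
        raise ValueError(f"exposure '{exposure.name}' is constant after "
                         "complete-case filtering")
    design = sm.add_constant(df[["x", *covariates]].to_numpy(dtype=float))
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(f"singular design for exposure '{exposure.name}' with "
                         f"covariates {tuple(covariates)}")
    model = sm.GEE(df["y"].to_numpy(), design, groups=df["cluster"].to_numpy(),
                   family=sm.families.Gaussian(), cov_struct=_working(working))
    res = model.fit()
    beta, se = float(res.params[1]), float(res.bse[1])
    p = 2.0 * stats.norm.sf(abs(beta / se)) if se > 0 else np.nan
    names = ["const", "x", *covariates]
    def _p(i):
        return 2.0 * stats.norm.sf(abs(res.params[i] / res.bse[i]))
    sex_p = _p(names.index("sex")) if "sex" in names else np.nan
    age_p = _p(names.index("age")) if "age" in names else np.nan
    return AssociationResult(
        mode=mode, exposure=exposure.name, beta=beta,
        ci_low=beta - Z95 * se, ci_high=beta + Z95 * se, p_value=float(p),
        n_knees=len(df), n_subjects=int(df["cluster"].nunique()),
        sex_p=float(sex_p), age_p=float(age_p),
    )


def association_table(scores: pd.DataFrame, cohort: pd.DataFrame,
                      exposures=STANDARD_EXPOSURES, modes=None,
                      working: str = "exchangeable",
                      covariates=("sex", "age")) -> pd.DataFrame:
    """Fit one GEE per (mode, exposure) pair and assemble the results table.

    ``scores`` holds per-knee SD-unit mode scores (columns ``mode_1..``)
    keyed by (subject_id, side); ``cohort`` the covariates. ``modes`` are
    1-based mode numbers; default: every mode column in ``scores``.
    """
    merged = scores.merge(cohort, on=["subject_id", "side"], how="inner")
    if len(merged) == 0:
        raise ValueError("join of scores and cohort produced zero rows")
    mode_cols = [c for c in scores.columns if c.startswith("mode_")]
    if modes is None:
        modes = [int(c.split("_")[1]) for c in mode_cols]
    modes = list(modes)
    if len(modes) == 0:
        raise ValueError("no modes selected for association analysis")
    threshold = bonferroni_threshold(len(modes))
    rows = []
    for m in modes:
        for exp in exposures:
            r = fit_gee(merged, f"mode_{m}", exp, covariates=covariates,
                        working=working, mode=m).with_threshold(threshold)
            rows.append(r.__dict__)
    table = pd.DataFrame(rows)
    table["sex_flag"] = table["sex_p"] < 0.05
    table["age_flag"] = table["age_p"] < 0.05
    return table


def format_association_table(table: pd.DataFrame) -> pd.DataFrame:
    """Publication-style rounding: betas/CIs to 3 decimals, threshold to 4."""
    out = table.copy()
    for c in ("beta", "ci_low", "ci_high"):
        out[c] = out[c].round(3)
    out["threshold"] = out["threshold"].round(4)
    return out


class ModeAssociationGEE(BaseEstimator):
    """Estimator wrapper around :func:`association_table`.

    Parameters
    ----------
    exposures : sequence of ExposureSpec
    working : working correlation structure ('exchangeable'|'independence')
    min_fraction : unused here (mode selection happens upstream); kept for
        pipeline configuration symmetry.
    """

    def __init__(self, exposures=STANDARD_EXPOSURES, working="exchangeable"):
        self.exposures = exposures
        self.working = working

    def fit(self, scores: pd.DataFrame, cohort: pd.DataFrame, modes=None):
        self.results_ = association_table(scores, cohort, self.exposures,
                                          modes=modes, working=self.working)
        self.threshold_ = float(self.results_["threshold"].iloc[0])
        return self

    def significant_modes(self, exposure: str) -> list:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "results_")
        t = self.results_
        hit = t[(t["exposure"] == exposure) & t["significant"]]
        return sorted(hit["mode"].tolist())
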