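"""Region-wise case--control contrasts of the principal gradient.

Each region's gradient score is modelled with an ordinary least squares
GLM on [intercept, group, age, sex, education, age x sex]; the group
coefficient's t-statistic forms the case--control t-map (group coded
control=0, case=1, so positive t means cases > controls).  Age and
education are mean-centered before forming the interaction.  Regional
p-values are corrected with Benjamini-Hochberg FDR; label-level analyses
average the gradient within each network/class first and correct across
the seven labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mindgrad.exceptions import DesignError, InsufficientSampleError
from mindgrad.spatial_nulls import SpinEnsemble, spin_correlation_test

COVARIATES = ("group", "age", "sex", "education", "age_x_sex")


@dataclass
class ContrastResult:
    """Per-region group-contrast statistics (t, p, BH-FDR q, flags)."""

    region_ids: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    significant: np.ndarray
    covariate_set: tuple = COVARIATES

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": self.region_ids,
                "t": self.t_values,
                "p": self.p_values,
                "q": self.q_values,
                "significant": self.significant.astype(int),
            }
        )


def _design_matrix(covariates: pd.DataFrame, extra: pd.DataFrame = None) -> np.ndarray:
    group = covariates["group"].to_numpy(dtype=float)
    if np.all(group == group[0]):
        raise DesignError("group is constant: no case-control contrast exists")
    age = covariates["age"].to_numpy(dtype=float)
    sex = covariates["sex"].to_numpy(dtype=float)
    edu = covariates["education"].to_numpy(dtype=float)
    age_c = age - age.mean()
    edu_c = edu - edu.mean()
    cols = [np.ones_like(group), group, age_c, sex, edu_c, age_c * sex]
    names = ["intercept", "group", "age", "sex", "education", "age_x_sex"]
    if extra is not None:
        for name in extra.columns:
            cols.append(extra[name].to_numpy(dtype=float))
            names.append(name)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        _, r = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-10]
        raise DesignError(f"design matrix rank deficient; collinear columns: {bad}")
    return X


def fit_region_glm(
    gradient1: pd.DataFrame,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    extra_covariates: pd.DataFrame = None,
) -> ContrastResult:
    """OLS group contrast of gradient scores at every region.

    ``gradient1``: subjects x R (a region_id-labelled DataFrame; a
    ``subject_id`` column is ignored if present).  ``covariates`` must
    provide group (0/1), age, sex (0/1), education.  The t-statistic and
    two-sided p for the group coefficient are computed per region and
    BH-FDR corrected across regions.
    """
    g = gradient1.drop(columns=["subject_id"], errors="ignore")
    Y = g.to_numpy(dtype=float)
    X = _design_matrix(covariates, extra_covariates)
    n, p = X.shape
    if n != Y.shape[0]:
        raise DesignError("covariates and gradient table have different subject counts")
    if n <= p:
        raise InsufficientSampleError(f"need more than {p} subjects, got {n}")

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = n - p
    sigma2 = np.sum(resid**2, axis=0) / dof
    se_group = np.sqrt(sigma2 * xtx_inv[1, 1])
    t = beta[1] / se_group
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    q = bh_fdr(pvals)
    return ContrastResult(
        region_ids=np.asarray(g.columns),
        t_values=t,
        p_values=pvals,
        q_values=q,
        significant=q < alpha,
    )


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the original order."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def aggregate_by_label(
    gradient1: pd.DataFrame,
    covariates: pd.DataFrame,
    labels: np.ndarray,
    alpha: float = 0.05,
) -> ContrastResult:
    """Label-level contrast: average gradient within each network/class,
    refit the identical GLM, and BH-FDR across the labels."""
    g = gradient1.drop(columns=["subject_id"], errors="ignore")
    labels = np.asarray(labels)
    if labels.shape[0] != g.shape[1]:
        raise ValueError("labels must have one entry per region")
    uniq = np.unique(labels)
    means = {}
    for lab in uniq:
        cols = np.flatnonzero(labels == lab)
        if cols.size == 0:
            raise ValueError(f"label {lab} has no regions")
        means[lab] = g.iloc[:, cols].mean(axis=1)
    return fit_region_glm(pd.DataFrame(means), covariates, alpha=alpha)


def distribution_test(mean_g1_cases, mean_g1_controls) -> tuple:
    """Two-sample Kolmogorov-Smirnov test on subject-level mean gradient
    scores (asymptotic p)."""
    a = np.asarray(mean_g1_cases, dtype=float)
    b = np.asarray(mean_g1_controls, dtype=float)
    if len(a) < 5 or len(b) < 5:
        raise InsufficientSampleError("need at least 5 subjects per group for KS")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def tmap_vs_reference(
    t_map: np.ndarray, control_mean_map: np.ndarray, ensemble: SpinEnsemble
) -> tuple:
    """Spatial correlation of the case--control t-map with the control-group
    mean gradient map, spin-test significance."""
    return spin_correlation_test(t_map, control_mean_map, ensemble)
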