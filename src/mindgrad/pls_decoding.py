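"""PLS decoding of a contrast map against term or gene predictor matrices.

Partial least squares regression relates a regions x predictors matrix X
(cognitive term loadings or gene expression, z-scored per column) to a
univariate regional response y (the case--control t-map).  The first
component (PLS1) — the linear combination of predictors maximising
covariance with y — is the object of interest:

* its explained response variance is tested against a spin null obtained
  by spherically rotating y;
* predictor contributions are ranked by bootstrap weight Z-scores
  (resampling regions, sign-aligning each replicate's first component to
  the original) and retained after BH-FDR, split into positive- and
  negative-weight sets.

PLS1 is oriented so its region scores correlate positively with y.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from mindgrad.exceptions import DegenerateInputError, InsufficientSampleError
from mindgrad.group_contrast import bh_fdr
from mindgrad.spatial_nulls import SpinEnsemble, spin_correlation_test

_SD_FLOOR = 1e-12


@dataclass
class PLSResult:
    """Fitted PLS decomposition plus (optionally) its significance fields."""

    n_components: int
    predictor_ids: np.ndarray
    weights: np.ndarray  # P x k, original predictor basis
    region_scores: np.ndarray  # R x k
    variance_explained_y: np.ndarray  # k fractions of Var(y)
    p_spin_component1: Optional[float] = None
    bootstrap_z: Optional[np.ndarray] = None
    q_values: Optional[np.ndarray] = None
    positive_set: List = field(default_factory=list)
    negative_set: List = field(default_factory=list)


def _as_matrix(X) -> tuple:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), np.asarray(X.columns)
    X = np.asarray(X, dtype=float)
    return X, np.arange(X.shape[1])


def _zscore_columns(M: np.ndarray) -> np.ndarray:
    sd = M.std(axis=0)
    return (M - M.mean(axis=0)) / np.maximum(sd, _SD_FLOOR)


def fit_pls(X, y: np.ndarray, n_components: int = 20) -> PLSResult:
    """Fit PLS regression of a centered regional response on z-scored
    predictor columns.

    ``variance_explained_y[i]`` is the increment in the R-squared of y
    regressed on components 1..i+1 over components 1..i, so it partitions
    the response variance captured by the retained components.
    """
    Xm, ids = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if y.std() == 0:
        raise DegenerateInputError("response is constant")
    R = Xm.shape[0]
    if R != y.shape[0]:
        raise ValueError("X and y have different region counts")
    n_components = min(n_components, Xm.shape[1], R - 1)
    if R <= n_components:
        raise InsufficientSampleError("need more regions than components")
    Xz = _zscore_columns(Xm)
    yc = y - y.mean()

    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xz, yc)
    weights = pls.x_weights_.copy()  # P x k
    scores = pls.x_scores_.copy()  # R x k

    # incremental response variance per component
    ve = np.empty(n_components)
    prev_r2 = 0.0
    for i in range(n_components):
        T = scores[:, : i + 1]
        coef, *_ = np.linalg.lstsq(T, yc, rcond=None)
        resid = yc - T @ coef
        r2 = 1.0 - resid @ resid / (yc @ yc)
        ve[i] = r2 - prev_r2
        prev_r2 = r2

    # orient PLS1 so region scores correlate positively with the response
    if np.corrcoef(scores[:, 0], yc)[0, 1] < 0:
        weights[:, 0] *= -1.0
        scores[:, 0] *= -1.0
    return PLSResult(
        n_components=n_components,
        predictor_ids=ids,
        weights=weights,
        region_scores=scores,
        variance_explained_y=ve,
    )


def _pls1_scores_null(Xz: np.ndarray, Y_perm: np.ndarray) -> np.ndarray:
    """Component-1 explained variance for many permuted responses at once.

    For a univariate response the first PLS weight vector is proportional
    to X'y, so the component-1 explained variance is the squared
    correlation of X X'y with y — computed here for every permuted y.
    """
    Yc = Y_perm - Y_perm.mean(axis=1, keepdims=True)  # n_perm x R
    W = Xz.T @ Yc.T  # P x n_perm
    T = Xz @ W  # R x n_perm
    Tc = T - T.mean(axis=0)
    cov = np.sum(Tc * Yc.T, axis=0)
    denom = np.linalg.norm(Tc, axis=0) * np.linalg.norm(Yc, axis=1)
    corr = np.where(denom > 0, cov / np.maximum(denom, _SD_FLOOR), 0.0)
    return corr**2


def spin_significance_of_component(
    X, y: np.ndarray, ensemble: SpinEnsemble, n_components: int = 20
) -> float:
    """One-sided spin p-value for the variance explained by PLS1.

    The response is spin-permuted; the null statistic is the component-1
    explained variance refitted on each permuted response.
    """
    Xm, _ = _as_matrix(X)
    result = fit_pls(Xm, y, n_components=n_components)
    observed = result.variance_explained_y[0]
    Xz = _zscore_columns(Xm)
    null = _pls1_scores_null(Xz, ensemble.apply(np.asarray(y, dtype=float)))
    return float((1.0 + np.sum(null >= observed)) / (1.0 + ensemble.n_spins))


@dataclass
class BootstrapWeights:
    """Bootstrap Z-scores for PLS1 weights with FDR-retained sign sets."""

    bootstrap_z: np.ndarray
    q_values: np.ndarray
    positive_set: List
    negative_set: List


def bootstrap_weight_z(
    X, y: np.ndarray, n_boot: int = 10_000, seed: int = 0, alpha: float = 0.05
) -> BootstrapWeights:
    """Normalised PLS1 weights by region-resampling bootstrap.

    Regions are resampled with replacement; the first component is
    refitted on each replicate (re-standardising predictors within the
    replicate), sign-aligned to the original weights, and the Z-score of
    each predictor is its original weight over its bootstrap SD.
    Predictors surviving BH-FDR at ``alpha`` are split by weight sign.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    Xm, ids = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    R = Xm.shape[0]
    result = fit_pls(Xm, y, n_components=1)
    w_orig = result.weights[:, 0]

    rng = np.random.default_rng(seed)
    w_boot = np.empty((n_boot, Xm.shape[1]))
    for b in range(n_boot):
        for _attempt in range(100):
            idx = rng.integers(0, R, size=R)
            if np.unique(idx).size >= 2:
                break
        else:
            raise RuntimeError("bootstrap resample degenerate after retries")
        Xb = _zscore_columns(Xm[idx])
        yb = y[idx] - y[idx].mean()
        w = Xb.T @ yb
        norm = np.linalg.norm(w)
        w = w / max(norm, _SD_FLOOR)
        if w @ w_orig < 0:
            w = -w
        w_boot[b] = w

    sd = w_boot.std(axis=0)
    z = w_orig / np.maximum(sd, _SD_FLOOR)
    p = 2.0 * stats.norm.sf(np.abs(z))
    q = bh_fdr(p)
    sig = q < alpha
    positive = [ids[j] for j in np.flatnonzero(sig & (w_orig > 0))]
    negative = [ids[j] for j in np.flatnonzero(sig & (w_orig < 0))]
    return BootstrapWeights(
        bootstrap_z=z, q_values=q, positive_set=positive, negative_set=negative
    )


def score_target_correlation(
    result: PLSResult, y: np.ndarray, ensemble: SpinEnsemble
) -> tuple:
    """Spin-tested correlation of the PLS1 region-score map with the
    response map."""
    return spin_correlation_test(result.region_scores[:, 0], np.asarray(y, float), ensemble)


def pls_decode(
    X,
    y: np.ndarray,
    ensemble: SpinEnsemble,
    n_components: int = 20,
    n_boot: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> PLSResult:
    """Full decoding: fit, spin-test PLS1 variance, bootstrap weight Z."""
    result = fit_pls(X, y, n_components=n_components)
    result.p_spin_component1 = spin_significance_of_component(
        X, y, ensemble, n_components=result.n_components
    )
    boot = bootstrap_weight_z(X, y, n_boot=n_boot, seed=seed, alpha=alpha)
    result.bootstrap_z = boot.bootstrap_z
    result.q_values = boot.q_values
    result.positive_set = boot.positive_set
    result.negative_set = boot.negative_set
    return result
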