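"""LMG relative-importance decomposition of a regional regression.

The contrast t-map is regressed on a small set of molecular/genetic
predictor maps.  Each predictor's importance is its LMG share: the
average, over all orderings of the predictors, of the R-squared increment
when the predictor enters the model.  Shares are exact (subset
enumeration), always nonnegative, and sum to the model R-squared.  Fit
significance uses a spin null on the response; share uncertainty uses a
region-resampling bootstrap with percentile intervals on the percentage
shares.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import factorial
from typing import Optional

import numpy as np
import pandas as pd

from mindgrad.exceptions import DesignError
from mindgrad.spatial_nulls import SpinEnsemble


@dataclass
class ImportanceResult:
    predictor_names: np.ndarray
    coefficients: np.ndarray
    r2: float
    adjusted_r2: float
    lmg_shares: np.ndarray  # raw shares, sum to r2
    percentage_shares: np.ndarray  # normalised to sum to 100
    share_ci: Optional[np.ndarray] = None  # p x 2 percentile bounds on %
    p_spin_fit: Optional[float] = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "predictor": self.predictor_names,
                "coefficient": self.coefficients,
                "lmg_share": self.lmg_shares,
                "percent_share": self.percentage_shares,
            }
        )
        if self.share_ci is not None:
            out["percent_lo"] = self.share_ci[:, 0]
            out["percent_hi"] = self.share_ci[:, 1]
        return out


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    """R-squared of y on [1, X] (0 for an empty predictor set)."""
    if X.shape[1] == 0:
        return 0.0
    X1 = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ beta
    tss = np.sum((y - y.mean()) ** 2)
    return float(1.0 - resid @ resid / tss)


def lmg_shares(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Exact LMG decomposition by enumeration of all 2^p subsets.

    share_j = sum over subsets S not containing j of
              |S|! (p-|S|-1)! / p! * (R2(S u {j}) - R2(S)).
    """
    p = X.shape[1]
    r2_cache = {(): 0.0}
    cols = tuple(range(p))
    for size in range(1, p + 1):
        for S in combinations(cols, size):
            r2_cache[S] = _r2(y, X[:, list(S)])
    shares = np.zeros(p)
    fact = [factorial(i) for i in range(p + 1)]
    for j in range(p):
        others = tuple(c for c in cols if c != j)
        for size in range(0, p):
            w = fact[size] * fact[p - size - 1] / fact[p]
            for S in combinations(others, size):
                Sj = tuple(sorted(S + (j,)))
                shares[j] += w * (r2_cache[Sj] - r2_cache[S])
    return shares


def fit_importance(
    y: np.ndarray,
    predictors: pd.DataFrame,
    ensemble: Optional[SpinEnsemble] = None,
    n_boot: int = 1_000,
    seed: int = 0,
) -> ImportanceResult:
    """OLS fit of the t-map on predictor maps with exact LMG shares.

    The spin p-value for the model fit compares the observed (unadjusted)
    R-squared against R-squared values recomputed with the response
    spin-permuted.  Bootstrap CIs resample regions and report percentile
    bounds on the percentage shares.
    """
    y = np.asarray(y, dtype=float)
    names = np.asarray(predictors.columns)
    X = predictors.to_numpy(dtype=float)
    R, p = X.shape
    if p > 10:
        raise ValueError(
            f"{p} predictors: exact LMG enumerates 2^p subsets; restrict to <= 10"
        )
    if np.linalg.matrix_rank(np.column_stack([np.ones(R), X])) < p + 1:
        raise DesignError("predictors collinear to machine precision")

    X1 = np.column_stack([np.ones(R), X])
    beta, *_ = np.linalg.lstsq(X1, y, rcond=None)
    r2 = _r2(y, X)
    adj = 1.0 - (1.0 - r2) * (R - 1) / (R - p - 1)
    shares = lmg_shares(y, X)
    pct = 100.0 * shares / shares.sum()

    p_spin = None
    if ensemble is not None:
        null = np.array([_r2(yp, X) for yp in ensemble.apply(y)])
        p_spin = float((1.0 + np.sum(null >= r2)) / (1.0 + ensemble.n_spins))

    ci = None
    if n_boot:
        rng = np.random.default_rng(seed)
        boot_pct = np.empty((n_boot, p))
        for b in range(n_boot):
            idx = rng.integers(0, R, size=R)
            sh = lmg_shares(y[idx], X[idx])
            boot_pct[b] = 100.0 * sh / sh.sum()
        ci = np.column_stack(
            [np.quantile(boot_pct, 0.025, axis=0), np.quantile(boot_pct, 0.975, axis=0)]
        )
    return ImportanceResult(
        predictor_names=names,
        coefficients=beta[1:],
        r2=r2,
        adjusted_r2=adj,
        lmg_shares=shares,
        percentage_shares=pct,
        share_ci=ci,
        p_spin_fit=p_spin,
    )
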