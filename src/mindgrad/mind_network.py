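"""Morphometric Inverse Divergence (MIND) similarity networks.

A MIND network treats each cortical region as a cloud of vertices in
feature space (here five morphometric features per vertex) and scores the
similarity of two regions as an inverse transform of the symmetrised
Kullback--Leibler divergence between their multivariate feature
distributions:

    MIND(A, B) = 1 / (1 + D(A||B) + D(B||A))          in (0, 1].

The divergence is estimated nonparametrically with the k-nearest-neighbour
estimator of Wang, Kulkarni & Verdu:

    D_hat(A||B) = (d / n_a) * sum_i log(nu_k(i) / rho_k(i))
                  + log(n_b / (n_a - 1))

where rho_k(i) is the distance from point i of A to its k-th neighbour
within A (self excluded) and nu_k(i) the distance to its k-th neighbour in
B.  Negative estimates are clipped at zero so the similarity stays <= 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from mindgrad.exceptions import (
    DegenerateInputError,
    IncompleteParcellationError,
    InsufficientSampleError,
)
from mindgrad.synthetic_data import FEATURES, Parcellation

#: floor applied to zero nearest-neighbour distances (duplicate points) so
#: the log stays finite; deterministic and invariant to vertex order.
_DIST_FLOOR = 1e-10


def standardize_features(table: pd.DataFrame, features=FEATURES) -> pd.DataFrame:
    """Z-score each morphometric feature across ALL vertices of a subject.

    Normalisation is subject-wide, not per region: regional contrasts in
    the features are exactly what the divergence should see.  Uses the
    population SD (ddof=0).  Raises on a zero-variance feature.
    """
    out = table.copy()
    for feat in features:
        col = table[feat].to_numpy(dtype=float)
        sd = col.std()
        if sd == 0.0 or not np.isfinite(sd):
            raise DegenerateInputError(f"feature {feat!r} has zero variance")
        out[feat] = (col - col.mean()) / sd
    return out


def _knn_distance(tree: cKDTree, points: np.ndarray, k: int, exclude_self: bool) -> np.ndarray:
    """Distance to the k-th neighbour, optionally skipping the point itself."""
    kk = k + 1 if exclude_self else k
    dist, _ = tree.query(points, k=kk)
    if kk == 1:
        dist = dist[:, None]
    return np.maximum(dist[:, kk - 1], _DIST_FLOOR)


def kl_divergence_knn(sample_a: np.ndarray, sample_b: np.ndarray, k: int = 1) -> float:
    """k-NN estimate of D(A||B), clipped at zero.

    Both samples are point clouds of equal dimension.  Requires more than
    k points in each sample (A needs k+1 so self-exclusion leaves k
    neighbours).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if a.shape[1] != b.shape[1]:
        raise ValueError(f"dimension mismatch: {a.shape[1]} vs {b.shape[1]}")
    n_a, d = a.shape
    n_b = b.shape[0]
    if n_a <= k or n_b <= k:
        raise InsufficientSampleError(
            f"need more than k={k} points per sample (got {n_a}, {n_b})"
        )
    rho = _knn_distance(cKDTree(a), a, k, exclude_self=True)
    nu = _knn_distance(cKDTree(b), a, k, exclude_self=False)
    est = (d / n_a) * np.sum(np.log(nu / rho)) + np.log(n_b / (n_a - 1))
    return float(max(est, 0.0))


def mind_similarity(sample_a: np.ndarray, sample_b: np.ndarray, k: int = 1) -> float:
    """MIND similarity = 1 / (1 + D(A||B) + D(B||A)); symmetric, in (0, 1]."""
    d_sym = kl_divergence_knn(sample_a, sample_b, k) + kl_divergence_knn(
        sample_b, sample_a, k
    )
    return 1.0 / (1.0 + d_sym)


@dataclass
class MINDMatrix:
    """Per-subject region-by-region MIND similarity.

    ``values`` is symmetric with zero diagonal and off-diagonal entries in
    (0, 1]; ``degree`` is the mean off-diagonal similarity per region (the
    weighted node degree, no threshold applied).
    """

    values: np.ndarray
    region_ids: np.ndarray
    subject_id: str = ""

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def degree(self) -> np.ndarray:
        r = self.n_regions
        return self.values.sum(axis=1) / (r - 1)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.region_ids, columns=self.region_ids)
        df.index.name = "region_id"
        df.to_csv(path, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, subject_id: str = "") -> "MINDMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(
            values=df.to_numpy(dtype=float),
            region_ids=df.index.to_numpy(),
            subject_id=subject_id,
        )


def build_mind_matrix(
    table: pd.DataFrame,
    parcellation: Parcellation,
    k: int = 1,
    standardize: bool = True,
) -> MINDMatrix:
    """Compute the full R x R MIND matrix for one subject.

    The vertex table must cover every parcellation region.  All R(R-1)/2
    region pairs are estimated once and mirrored; the diagonal is zero by
    policy (self-similarity excluded from the network and from degree).
    """
    if standardize:
        table = standardize_features(table)
    region_ids = parcellation.region_ids
    groups = {rid: g[list(FEATURES)].to_numpy(dtype=float)
              for rid, g in table.groupby("region_id")}
    missing = [int(r) for r in region_ids if r not in groups]
    if missing:
        raise IncompleteParcellationError(f"vertex table missing regions: {missing}")

    R = len(region_ids)
    pts = [groups[r] for r in region_ids]
    trees = [cKDTree(p) for p in pts]
    rho = [  # within-region k-th NN distance, reused across all pairs
        _knn_distance(trees[i], pts[i], k, exclude_self=True) for i in range(R)
    ]
    d = pts[0].shape[1]

    def directed(i: int, j: int) -> float:
        n_a = pts[i].shape[0]
        n_b = pts[j].shape[0]
        if n_a <= k or n_b <= k:
            raise InsufficientSampleError(
                f"regions {region_ids[i]}, {region_ids[j]}: need > k={k} vertices"
            )
        nu = _knn_distance(trees[j], pts[i], k, exclude_self=False)
        est = (d / n_a) * np.sum(np.log(nu / rho[i])) + np.log(n_b / (n_a - 1))
        return max(est, 0.0)

    values = np.zeros((R, R))
    for i in range(R):
        for j in range(i + 1, R):
            sim = 1.0 / (1.0 + directed(i, j) + directed(j, i))
            values[i, j] = values[j, i] = sim
    subject = str(table["subject_id"].iloc[0]) if "subject_id" in table else ""
    return MINDMatrix(values=values, region_ids=region_ids, subject_id=subject)
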