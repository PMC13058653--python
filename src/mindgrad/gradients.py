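"""Diffusion-map gradients of MIND networks.

The pipeline is the standard connectivity-gradient recipe: sparsify each
similarity matrix row-wise (top 10% of entries per row by default), build
a normalized-angle affinity between the sparsified connectivity profiles,
and embed with diffusion maps (density-normalisation exponent alpha = 0.5,
diffusion time 0).  Individual embeddings are aligned to a group template
by orthogonal Procrustes rotation, and the first component — the principal
gradient — is carried downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import eigh, orthogonal_procrustes
from scipy.sparse.csgraph import connected_components

from mindgrad.exceptions import ConnectivityError, DegenerateInputError, DimensionError
from mindgrad.mind_network import MINDMatrix


@dataclass
class GradientSet:
    """Embedding components with eigenvalue bookkeeping.

    ``components`` is R x k with component i scaled by its eigenvalue
    (diffusion time 0); ``variance_explained`` is lambda_i over the sum of
    the retained nontrivial eigenvalues, so it sums to 1 across the k
    retained components.
    """

    components: np.ndarray
    lambdas: np.ndarray
    variance_explained: np.ndarray
    alpha: float
    threshold_fraction: Optional[float] = None
    aligned_to: Optional[str] = None
    region_ids: Optional[np.ndarray] = None

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    def to_csv(self, path) -> None:
        cols = {"region_id": self.region_ids
                if self.region_ids is not None
                else np.arange(1, len(self.components) + 1)}
        for j in range(self.n_components):
            cols[f"g{j + 1}"] = self.components[:, j]
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def threshold_rows(matrix, fraction: float = 0.1) -> np.ndarray:
    """Keep the ceil(fraction*(R-1)) largest off-diagonal entries per row.

    Everything else is zeroed; the result is generally asymmetric.  Ties
    at the cutoff are broken in favour of the lower region index, which
    makes the operation deterministic.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    values = matrix.values if isinstance(matrix, MINDMatrix) else np.asarray(matrix, float)
    R = values.shape[0]
    m = int(np.ceil(fraction * (R - 1)))
    out = np.zeros_like(values)
    idx = np.arange(R)
    for i in range(R):
        off = idx[idx != i]
        # stable sort on (-value, index): larger values first, lower index wins ties
        order = off[np.lexsort((off, -values[i, off]))]
        keep = order[:m]
        out[i, keep] = values[i, keep]
    return out


def normalized_angle_affinity(thresholded: np.ndarray) -> np.ndarray:
    """Affinity a_ij = 1 - arccos(cosine(row_i, row_j)) / pi.

    Computed between the rows of the sparsified matrix (the regions'
    connectivity profiles, diagonal zeros included as-is).  For
    nonnegative rows the cosine is nonnegative, so affinities lie in
    [0.5, 1] with an exact unit diagonal.
    """
    T = np.asarray(thresholded, dtype=float)
    norms = np.linalg.norm(T, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise DegenerateInputError(f"all-zero connectivity rows at indices {zero.tolist()}")
    cos = (T @ T.T) / np.outer(norms, norms)
    cos = np.clip(cos, -1.0, 1.0)
    aff = 1.0 - np.arccos(cos) / np.pi
    np.fill_diagonal(aff, 1.0)
    return 0.5 * (aff + aff.T)


def diffusion_embed(
    affinity: np.ndarray, alpha: float = 0.5, n_components: int = 10
) -> GradientSet:
    """Diffusion-map embedding of a symmetric nonnegative affinity matrix.

    Density-normalise W_alpha = D^-alpha W D^-alpha, form the Markov
    operator P = D_alpha^-1 W_alpha, and eigendecompose.  The trivial
    constant eigenvector (eigenvalue 1) is dropped; component i is
    lambda_i * psi_i with psi scaled so the trivial eigenvector is the
    ones vector.  variance_explained is lambda over the sum of the
    retained nontrivial lambdas.
    """
    W = np.asarray(affinity, dtype=float)
    if W.shape[0] != W.shape[1] or not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("affinity must be square and symmetric")
    if np.any(W < 0):
        raise ValueError("affinity must be nonnegative")
    n_comp_graph, _ = connected_components((W > 0).astype(int), directed=False)
    if n_comp_graph > 1:
        raise ConnectivityError(f"affinity graph has {n_comp_graph} components")

    R = W.shape[0]
    n_components = min(n_components, R - 1)
    d = W.sum(axis=1)
    d_alpha_scale = d**-alpha
    W_alpha = W * np.outer(d_alpha_scale, d_alpha_scale)
    d_alpha = W_alpha.sum(axis=1)

    # symmetric conjugate of the Markov operator; same eigenvalues
    inv_sqrt = 1.0 / np.sqrt(d_alpha)
    M = W_alpha * np.outer(inv_sqrt, inv_sqrt)
    M = 0.5 * (M + M.T)
    evals, evecs = eigh(M)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    # psi_0 is constant once divided through by the trivial eigenvector
    psi = evecs / evecs[:, [0]]
    lambdas = evals[1 : n_components + 1]
    components = psi[:, 1 : n_components + 1] * lambdas[None, :]
    total = lambdas.sum()
    variance = lambdas / total if total > 0 else np.full_like(lambdas, np.nan)
    return GradientSet(
        components=components,
        lambdas=lambdas,
        variance_explained=variance,
        alpha=alpha,
    )


def _orient(gset: GradientSet, anchor_idx: np.ndarray) -> GradientSet:
    """Flip component signs so each component's mean over the anchor set
    (highest-degree decile of regions) is nonnegative."""
    comps = gset.components.copy()
    means = comps[anchor_idx].mean(axis=0)
    comps *= np.where(means < 0, -1.0, 1.0)[None, :]
    return replace(gset, components=comps)


def build_group_template(
    matrices: Sequence[MINDMatrix],
    fraction: float = 0.1,
    alpha: float = 0.5,
    n_components: int = 10,
) -> GradientSet:
    """Embed the element-wise mean MIND matrix across all subjects.

    The template's sign convention: each component is oriented so its mean
    over the highest-degree decile of regions (degree of the mean matrix)
    is positive.  Individuals inherit the orientation via alignment.
    """
    if len(matrices) < 2:
        raise ValueError("need at least two subjects for a group template")
    R = matrices[0].n_regions
    for m in matrices[1:]:
        if m.n_regions != R:
            raise DimensionError("MIND matrices have mismatched sizes")
    mean_values = np.mean([m.values for m in matrices], axis=0)
    mean_mind = MINDMatrix(values=mean_values, region_ids=matrices[0].region_ids)
    gset = diffusion_embed(
        normalized_angle_affinity(threshold_rows(mean_values, fraction)),
        alpha=alpha,
        n_components=n_components,
    )
    degree = mean_mind.degree
    n_anchor = max(1, R // 10)
    anchor = np.argsort(degree)[::-1][:n_anchor]
    gset = _orient(gset, anchor)
    return replace(
        gset,
        threshold_fraction=fraction,
        aligned_to="template",
        region_ids=matrices[0].region_ids,
    )


def embed_subject(
    matrix: MINDMatrix,
    template: GradientSet,
    fraction: float = 0.1,
    alpha: float = 0.5,
) -> GradientSet:
    """Embed one subject's MIND matrix and align it to the group template."""
    gset = diffusion_embed(
        normalized_angle_affinity(threshold_rows(matrix.values, fraction)),
        alpha=alpha,
        n_components=template.n_components,
    )
    gset = replace(gset, threshold_fraction=fraction, region_ids=matrix.region_ids)
    return procrustes_align(gset, template)


def procrustes_align(individual: GradientSet, template: GradientSet) -> GradientSet:
    """Align an individual embedding to the template by orthogonal rotation.

    Columns of both embeddings are centered, the Frobenius-optimal
    orthogonal rotation is applied (no scaling), and the template's column
    means are restored.  ``variance_explained`` is carried over unchanged
    from the unaligned solution.  A rank-deficient individual triggers a
    warning and an identity rotation.
    """
    A, B = individual.components, template.components
    if A.shape != B.shape:
        raise DimensionError(f"shape mismatch {A.shape} vs {B.shape}")
    A_c = A - A.mean(axis=0)
    B_c = B - B.mean(axis=0)
    if np.linalg.matrix_rank(A_c) < A.shape[1]:
        warnings.warn("rank-deficient embedding; identity rotation applied")
        rotation = np.eye(A.shape[1])
    else:
        rotation, _ = orthogonal_procrustes(A_c, B_c)
    aligned = A_c @ rotation + B.mean(axis=0)
    return replace(individual, components=aligned, aligned_to="template")
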