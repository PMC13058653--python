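"""Spin-permutation null models for parcellated spherical maps.

Correlations between two cortical maps are inflated by spatial
autocorrelation, so significance is assessed against a null that rotates
one map over the sphere: draw a uniform random 3-D rotation, apply it to
the left-hemisphere centroids and its x-mirrored counterpart to the right,
and reassign every region the value of the nearest rotated centroid
(duplicates permitted, as in the original Alexander-Bloch construction).
The rotation preserves the map's autocorrelation while destroying its
alignment with the other map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import pearsonr

from mindgrad.exceptions import DegenerateInputError
from mindgrad.synthetic_data import Parcellation

_MIRROR = np.diag([-1.0, 1.0, 1.0])


@dataclass
class SpinEnsemble:
    """Pre-computed spin permutations for one parcellation.

    ``permutations[s, i]`` gives the source region (positional index) whose
    value region i receives under spin s.  Permutations never cross the
    midline: left regions draw from left regions and right from right.
    """

    permutations: np.ndarray  # n_spins x R int array
    seed: int
    n_spins: int

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Return the n_spins x R array of spun copies of ``values``."""
        return np.asarray(values, dtype=float)[self.permutations]

    def save(self, path) -> None:
        header = f"seed={self.seed} n_spins={self.n_spins}"
        np.savetxt(path, self.permutations, fmt="%d", header=header)

    @classmethod
    def load(cls, path) -> "SpinEnsemble":
        with open(path) as fh:
            head = fh.readline().lstrip("# ").split()
        meta = dict(kv.split("=") for kv in head)
        perms = np.loadtxt(path, dtype=int, ndmin=2)
        return cls(permutations=perms, seed=int(meta["seed"]), n_spins=int(meta["n_spins"]))


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform (Haar) random rotation in SO(3) via sign-corrected QR."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def build_spin_ensemble(
    parcellation: Parcellation, n_spins: int, seed: int
) -> SpinEnsemble:
    """Draw ``n_spins`` mirrored-pair spherical rotations.

    Each spin rotates the left centroids by a Haar-random rotation Q and
    the right centroids by the x-mirrored rotation F Q F; each region is
    then reassigned to its nearest rotated centroid within hemisphere.
    """
    if n_spins < 1:
        raise ValueError("n_spins must be >= 1")
    centroids = parcellation.centroids
    if not np.allclose(np.linalg.norm(centroids, axis=1), 1.0, atol=1e-9):
        raise ValueError("parcellation centroids must be unit vectors")
    rng = np.random.default_rng(seed)
    idx_l = parcellation.hemisphere_index("L")
    idx_r = parcellation.hemisphere_index("R")

    perms = np.empty((n_spins, parcellation.n_regions), dtype=int)
    for s in range(n_spins):
        q_left = _random_rotation(rng)
        q_right = _MIRROR @ q_left @ _MIRROR
        for idx, q in ((idx_l, q_left), (idx_r, q_right)):
            if idx.size == 0:
                continue
            rotated = centroids[idx] @ q.T
            _, nearest = cKDTree(rotated).query(centroids[idx])
            perms[s, idx] = idx[nearest]
    return SpinEnsemble(permutations=perms, seed=seed, n_spins=n_spins)


def spin_correlation_test(
    map_x: np.ndarray, map_y: np.ndarray, ensemble: SpinEnsemble
) -> tuple:
    """Pearson r between two regional maps with a two-sided spin p-value.

    The first map is spun (the second held fixed);
    p = (1 + #{|r_null| >= |r_obs|}) / (1 + n_spins), never zero.
    """
    x = np.asarray(map_x, dtype=float)
    y = np.asarray(map_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("maps must share a parcellation (length mismatch)")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("correlation undefined for a constant map")
    r_obs = pearsonr(x, y).statistic
    spun = ensemble.apply(x)
    spun_c = spun - spun.mean(axis=1, keepdims=True)
    y_c = y - y.mean()
    r_null = (spun_c @ y_c) / (
        np.linalg.norm(spun_c, axis=1) * np.linalg.norm(y_c)
    )
    p = (1.0 + np.sum(np.abs(r_null) >= abs(r_obs))) / (1.0 + ensemble.n_spins)
    return float(r_obs), float(p)


def adjust_bonferroni(p_values, m: int) -> np.ndarray:
    """Bonferroni adjustment p_adj = min(1, m * p) over a family of m tests."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m < len(p):
        raise ValueError(f"m={m} smaller than the number of tests ({len(p)})")
    return np.minimum(1.0, m * p)
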