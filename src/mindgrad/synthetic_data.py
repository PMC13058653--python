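"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be simulated here: a spherical
parcellation with bilateral mirror symmetry and spatially contiguous
network/class labels, vertex-level morphometric cohorts with a planted
case--control shift, spatially autocorrelated annotation maps (Gaussian
process on sphere centroids), and a regional gene-expression matrix whose
loaded genes track a chosen target map.

The defaults emulate the study conditions of a typical cortical
morphometry case--control design: 154 regions per hemisphere (308 total),
five morphometric features per vertex (CT, GM, SA, MC, SD), several
hundred vertices per region, ages 21--50, and seven network / seven
cytoarchitectonic label schemes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mindgrad.exceptions import DimensionError

FEATURES = ("CT", "GM", "SA", "MC", "SD")

# Raw feature scales (location, spread) before z-scoring, loosely matching
# FreeSurfer units: thickness in mm, volume in mm^3, area in mm^2,
# curvature in 1/mm, depth in arbitrary units.
_FEATURE_LOC = np.array([2.5, 520.0, 0.55, 0.12, 1.8])
_FEATURE_SCALE = np.array([0.35, 90.0, 0.12, 0.05, 0.6])

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


# ---------------------------------------------------------------------------
# Parcellation
# ---------------------------------------------------------------------------

@dataclass
class Parcellation:
    """A spherical cortical parcellation.

    ``table`` has one row per region with columns ``region_id`` (1..R),
    ``hemisphere`` ('L'/'R'), unit-sphere centroid ``x, y, z``,
    ``network_label`` and ``class_label`` (1..7 each), and ``n_vertices``.
    Right-hemisphere centroids are the left centroids with the x coordinate
    negated, so spin rotations can be applied in mirrored pairs.
    """

    table: pd.DataFrame
    seed: int = 0

    def __post_init__(self) -> None:
        c = self.centroids
        norms = np.linalg.norm(c, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("parcellation centroids must have unit norm")
        if self.table["region_id"].duplicated().any():
            raise ValueError("region_ids must be unique")

    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def region_ids(self) -> np.ndarray:
        return self.table["region_id"].to_numpy()

    @property
    def centroids(self) -> np.ndarray:
        return self.table[["x", "y", "z"]].to_numpy(dtype=float)

    @property
    def hemispheres(self) -> np.ndarray:
        return self.table["hemisphere"].to_numpy()

    def hemisphere_index(self, hemi: str) -> np.ndarray:
        """Positional indices of the regions in hemisphere 'L' or 'R'."""
        return np.flatnonzero(self.hemispheres == hemi)

    def left_only(self) -> "Parcellation":
        sub = self.table[self.table["hemisphere"] == "L"].reset_index(drop=True)
        return Parcellation(sub, seed=self.seed)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, seed: int = 0) -> "Parcellation":
        return cls(pd.read_csv(path), seed=seed)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n near-uniform points on the unit sphere (Fibonacci lattice)."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = i * _GOLDEN_ANGLE
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def generate_parcellation(R_per_hemisphere: int, seed: int) -> Parcellation:
    """Build a bilateral spherical parcellation.

    Left-hemisphere centroids come from a Fibonacci lattice over the unit
    sphere; the right hemisphere mirrors them in the x coordinate.  Network
    and class labels are assigned by contiguous angular sectors (azimuthal
    for networks, polar for classes), so both label schemes are spatially
    autocorrelated, and the right hemisphere inherits its mirror twin's
    labels.  Vertex counts are drawn uniformly in [200, 500].
    """
    if R_per_hemisphere < 4:
        raise ValueError("R_per_hemisphere must be >= 4")
    rng = np.random.default_rng(seed)
    left = _fibonacci_sphere(R_per_hemisphere)

    azimuth = np.mod(np.arctan2(left[:, 1], left[:, 0]), 2 * np.pi)
    network = np.minimum((azimuth / (2 * np.pi) * 7).astype(int), 6) + 1
    polar = np.arccos(np.clip(left[:, 2], -1, 1))
    klass = np.minimum((polar / np.pi * 7).astype(int), 6) + 1
    n_vertices = rng.integers(200, 501, size=2 * R_per_hemisphere)

    rows = []
    for hemi_idx, hemi in enumerate(("L", "R")):
        pts = left if hemi == "L" else left * np.array([-1.0, 1.0, 1.0])
        for j in range(R_per_hemisphere):
            rows.append(
                {
                    "region_id": hemi_idx * R_per_hemisphere + j + 1,
                    "hemisphere": hemi,
                    "x": pts[j, 0],
                    "y": pts[j, 1],
                    "z": pts[j, 2],
                    "network_label": int(network[j]),
                    "class_label": int(klass[j]),
                    "n_vertices": int(n_vertices[hemi_idx * R_per_hemisphere + j]),
                }
            )
    return Parcellation(pd.DataFrame(rows), seed=seed)


# ---------------------------------------------------------------------------
# Gaussian process maps
# ---------------------------------------------------------------------------

def _sq_exp_kernel(centroids: np.ndarray, length_scale: float) -> np.ndarray:
    """Squared-exponential kernel on chordal (straight-line) distance."""
    d2 = np.sum((centroids[:, None, :] - centroids[None, :, :]) ** 2, axis=-1)
    return np.exp(-d2 / (2.0 * length_scale**2))


def _gp_samples(
    centroids: np.ndarray, length_scale: float, n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """n_samples x R draws from a zero-mean GP with SE kernel."""
    k = _sq_exp_kernel(centroids, length_scale)
    k[np.diag_indices_from(k)] += 1e-9
    chol = np.linalg.cholesky(k)
    return rng.standard_normal((n_samples, len(centroids))) @ chol.T


def _bilateral_gp_samples(
    parcellation: Parcellation,
    length_scale: float,
    n_samples: int,
    rng: np.random.Generator,
    symmetry: float = 0.7,
) -> np.ndarray:
    """GP draws whose law is invariant under mirrored-pair sphere rotations.

    Each map is sqrt(symmetry) * a mirror-symmetric component (one GP on
    the left centroids, copied to the mirror twins) plus sqrt(1-symmetry)
    * hemisphere-specific components (independent GPs per hemisphere).
    Both parts are isotropic within hemisphere and carry no cross-
    hemisphere covariance beyond exact mirror symmetry, so applying a
    random rotation to the left sphere and its x-mirrored rotation to the
    right leaves the process law unchanged — the property spin-permutation
    nulls rely on.  ``symmetry`` sets the homotopic (left/right twin)
    correlation.
    """
    idx_l = parcellation.hemisphere_index("L")
    idx_r = parcellation.hemisphere_index("R")
    R = parcellation.n_regions
    out = np.zeros((n_samples, R))
    if idx_l.size and idx_r.size:
        if idx_l.size != idx_r.size:
            raise ValueError("mirrored hemispheres must have equal region counts")
        left_centroids = parcellation.centroids[idx_l]
        sym = _gp_samples(left_centroids, length_scale, n_samples, rng)
        own_l = _gp_samples(left_centroids, length_scale, n_samples, rng)
        own_r = _gp_samples(left_centroids, length_scale, n_samples, rng)
        out[:, idx_l] = np.sqrt(symmetry) * sym + np.sqrt(1 - symmetry) * own_l
        out[:, idx_r] = np.sqrt(symmetry) * sym + np.sqrt(1 - symmetry) * own_r
    else:
        idx = idx_l if idx_l.size else idx_r
        out[:, idx] = _gp_samples(parcellation.centroids[idx], length_scale, n_samples, rng)
    return out


def generate_annotation_map(
    parcellation: Parcellation, smoothness: float, seed: int, symmetry: float = 0.7
) -> np.ndarray:
    """A spatially autocorrelated regional map, z-scored across regions.

    A draw from a Gaussian process over the parcellation centroids with a
    squared-exponential kernel of length-scale ``smoothness`` (chordal
    distance on the unit sphere), built from a mirror-symmetric plus
    hemisphere-specific decomposition (see :func:`_bilateral_gp_samples`)
    so that spin-permutation nulls are exactly exchangeable.  Stands in
    for molecular annotation maps such as receptor or transporter
    densities.
    """
    if smoothness <= 0:
        raise ValueError("smoothness must be > 0")
    rng = np.random.default_rng(seed)
    vals = _bilateral_gp_samples(parcellation, smoothness, 1, rng, symmetry)[0]
    return (vals - vals.mean()) / vals.std()


# ---------------------------------------------------------------------------
# Vertex-level cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Design of a synthetic case--control cohort.

    ``effect_size`` is expressed in pooled-SD units of the vertex features:
    case subjects have all five feature means shifted by
    ``effect_size * SD`` inside ``effect_regions``.
    """

    n_cases: int
    n_controls: int
    effect_regions: frozenset = field(default_factory=frozenset)
    effect_size: float = 0.0
    seed: int = 0
    subject_sd: float = 0.15  # subject-level mean offsets, in feature-SD units

    def __post_init__(self) -> None:
        self.effect_regions = frozenset(self.effect_regions)
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")


def _region_distributions(parcellation: Parcellation):
    """Per-region 5-D Gaussian parameters, fixed by the parcellation seed.

    Feature means vary smoothly over the sphere (GP per feature); each
    region gets its own covariance built from a shared feature correlation
    structure plus regional SD modulation.
    """
    rng = np.random.default_rng(np.uint32(parcellation.seed) + 982_451_653)
    R = parcellation.n_regions
    gp = _bilateral_gp_samples(parcellation, 0.8, len(FEATURES), rng)  # 5 x R
    means = _FEATURE_LOC[:, None] + _FEATURE_SCALE[:, None] * gp  # 5 x R

    a = rng.standard_normal((len(FEATURES), len(FEATURES)))
    corr = a @ a.T
    dinv = 1.0 / np.sqrt(np.diag(corr))
    corr = 0.5 * np.eye(len(FEATURES)) + 0.5 * (corr * np.outer(dinv, dinv))

    sd_mod = np.exp(0.15 * _bilateral_gp_samples(parcellation, 0.8, len(FEATURES), rng))
    covs = np.empty((R, len(FEATURES), len(FEATURES)))
    for r in range(R):
        sd = _FEATURE_SCALE * sd_mod[:, r]
        covs[r] = corr * np.outer(sd, sd)
    return means.T, covs  # R x 5, R x 5 x 5


def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    age = rng.uniform(21.0, 50.0, size=n)
    sex = rng.integers(0, 2, size=n)
    edu = rng.normal(14.0, 2.0, size=n)
    while np.any(edu < 8.0):  # truncate at 8 years
        bad = edu < 8.0
        edu[bad] = rng.normal(14.0, 2.0, size=bad.sum())
    return pd.DataFrame({"age": age, "sex": sex, "education": edu})


def generate_cohort(parcellation: Parcellation, spec: CohortSpec):
    """Simulate vertex tables for a case--control cohort.

    Returns ``(tables, covariates)`` where ``tables`` is a list of
    per-subject DataFrames with columns ``subject_id, vertex_id, region_id,
    CT, GM, SA, MC, SD`` and ``covariates`` has one row per subject with
    ``subject_id, group, age, sex, education`` (group: 0 control, 1 case).

    Each region's vertices are drawn from a region-specific 5-D Gaussian
    whose parameters are fixed once per parcellation; subjects add small
    random mean offsets; cases additionally shift the feature means in
    ``effect_regions`` by ``effect_size`` pooled SDs.
    """
    unknown = spec.effect_regions - set(parcellation.region_ids.tolist())
    if unknown:
        raise ValueError(f"effect_regions not in parcellation: {sorted(unknown)}")
    rng = np.random.default_rng(spec.seed)
    means, covs = _region_distributions(parcellation)
    chols = np.linalg.cholesky(covs)
    sds = np.sqrt(np.einsum("rii->ri", covs))

    n_total = spec.n_cases + spec.n_controls
    groups = np.concatenate(
        [np.ones(spec.n_cases, dtype=int), np.zeros(spec.n_controls, dtype=int)]
    )
    cov_df = _draw_covariates(n_total, rng)
    cov_df.insert(0, "group", groups)
    cov_df.insert(0, "subject_id", [f"sub-{i:03d}" for i in range(n_total)])

    effect_mask = np.isin(parcellation.region_ids, sorted(spec.effect_regions))
    nv = parcellation.table["n_vertices"].to_numpy()
    tables = []
    for s in range(n_total):
        offsets = rng.normal(0.0, spec.subject_sd, size=sds.shape) * sds
        sub_means = means + offsets
        if groups[s] == 1 and spec.effect_size > 0:
            sub_means = sub_means + effect_mask[:, None] * spec.effect_size * sds
        blocks = []
        for r in range(parcellation.n_regions):
            z = rng.standard_normal((nv[r], len(FEATURES)))
            blocks.append(z @ chols[r].T + sub_means[r])
        feats = np.vstack(blocks)
        region_col = np.repeat(parcellation.region_ids, nv)
        df = pd.DataFrame(feats, columns=list(FEATURES))
        df.insert(0, "region_id", region_col)
        df.insert(0, "vertex_id", np.arange(len(df)))
        df.insert(0, "subject_id", cov_df["subject_id"].iloc[s])
        tables.append(df)
    return tables, cov_df


def generate_gradient_cohort(
    parcellation: Parcellation,
    n_cases: int,
    n_controls: int,
    effect_regions=(),
    effect_size: float = 0.0,
    subject_sd: float = 1.0,
    smoothness: float = 0.5,
    seed: int = 0,
):
    """Simulate per-subject principal-gradient maps directly.

    A smooth group-level base map (GP on the sphere) plus i.i.d. subject
    noise of SD ``subject_sd`` per region; cases are shifted by
    ``effect_size * subject_sd`` in ``effect_regions``.  This is the
    region-level abstraction of the full vertex->MIND->gradient chain and
    is what power studies over many seeds use.

    Returns ``(g1, covariates)``: g1 is a subjects x R DataFrame with
    region_id columns.
    """
    unknown = set(effect_regions) - set(parcellation.region_ids.tolist())
    if unknown:
        raise ValueError(f"effect_regions not in parcellation: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    base = _bilateral_gp_samples(parcellation, smoothness, 1, rng)[0]
    n_total = n_cases + n_controls
    groups = np.concatenate([np.ones(n_cases, dtype=int), np.zeros(n_controls, dtype=int)])
    cov_df = _draw_covariates(n_total, rng)
    cov_df.insert(0, "group", groups)
    cov_df.insert(0, "subject_id", [f"sub-{i:03d}" for i in range(n_total)])

    g1 = base[None, :] + rng.normal(0.0, subject_sd, size=(n_total, parcellation.n_regions))
    shift = np.isin(parcellation.region_ids, sorted(effect_regions)).astype(float)
    g1 = g1 + groups[:, None] * effect_size * subject_sd * shift[None, :]
    g1_df = pd.DataFrame(g1, columns=parcellation.region_ids)
    g1_df.insert(0, "subject_id", cov_df["subject_id"])
    return g1_df, cov_df


# ---------------------------------------------------------------------------
# Gene expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSet:
    """Regional expression matrix with class labels and planted truth.

    ``expression``: regions x genes DataFrame (index: left-hemisphere
    region_ids, columns: gene ids), z-scored per gene.
    ``gene_classes``: DataFrame (gene_id, class_id) with 7 classes.
    ``loaded_genes``: the ids whose expression tracks the target map.
    """

    expression: pd.DataFrame
    gene_classes: pd.DataFrame
    loaded_genes: list
    betas: pd.Series


def generate_expression(
    parcellation: Parcellation,
    n_genes: int,
    target_map: np.ndarray,
    loading_fraction: float,
    noise_sd: float = 0.5,
    seed: int = 0,
    n_classes: int = 7,
    enriched_classes=(1, 2),
    enrichment_prob: float = 0.8,
) -> ExpressionSet:
    """Simulate a left-hemisphere regional gene-expression matrix.

    A fraction ``loading_fraction`` of genes follows
    ``beta * target_map + noise`` with gene-specific signed loadings beta
    (|beta| uniform in [0.5, 1.5]); the remainder is spatially smooth
    noise.  Loaded genes fall into ``enriched_classes`` with probability
    ``enrichment_prob`` so downstream class enrichment has ground truth.
    Every gene is z-scored across regions.
    """
    if not 0.0 <= loading_fraction <= 1.0:
        raise ValueError("loading_fraction must be in [0, 1]")
    left = parcellation.left_only()
    target = np.asarray(target_map, dtype=float)
    if target.shape != (left.n_regions,):
        raise DimensionError(
            f"target_map length {target.shape} != left region count {left.n_regions}"
        )
    rng = np.random.default_rng(seed)
    n_loaded = int(round(loading_fraction * n_genes))
    gene_ids = [f"g{j:05d}" for j in range(n_genes)]
    loaded_ids = gene_ids[:n_loaded]

    betas = np.zeros(n_genes)
    betas[:n_loaded] = rng.uniform(0.5, 1.5, size=n_loaded) * rng.choice(
        [-1.0, 1.0], size=n_loaded
    )
    smooth = _gp_samples(left.centroids, 0.5, n_genes, rng).T  # R x G
    expr = betas[None, :] * target[:, None] + noise_sd * rng.standard_normal(
        (left.n_regions, n_genes)
    )
    expr[:, n_loaded:] = smooth[:, n_loaded:] + noise_sd * rng.standard_normal(
        (left.n_regions, n_genes - n_loaded)
    )
    expr = (expr - expr.mean(axis=0)) / expr.std(axis=0)

    classes = rng.integers(1, n_classes + 1, size=n_genes)
    enriched = np.asarray(sorted(enriched_classes))
    in_enriched = rng.random(n_loaded) < enrichment_prob
    classes[:n_loaded] = np.where(
        in_enriched,
        enriched[rng.integers(0, len(enriched), size=n_loaded)],
        classes[:n_loaded],
    )

    expression = pd.DataFrame(expr, index=left.region_ids, columns=gene_ids)
    expression.index.name = "region_id"
    gene_classes = pd.DataFrame({"gene_id": gene_ids, "class_id": classes})
    return ExpressionSet(
        expression=expression,
        gene_classes=gene_classes,
        loaded_genes=list(loaded_ids),
        betas=pd.Series(betas, index=gene_ids, name="beta"),
    )
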