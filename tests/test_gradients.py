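"""Embedding oracles: thresholding, affinity closed forms, diffusion maps,
Procrustes alignment."""

import numpy as np
import pytest

from mindgrad import (
    CohortSpec,
    build_group_template,
    build_mind_matrix,
    diffusion_embed,
    generate_cohort,
    normalized_angle_affinity,
    procrustes_align,
    threshold_rows,
)
from mindgrad.exceptions import ConnectivityError, DegenerateInputError
from mindgrad.gradients import GradientSet, embed_subject
from mindgrad.mind_network import MINDMatrix


def _random_similarity(R, seed):
    rng = np.random.default_rng(seed)
    m = rng.uniform(0.05, 1.0, (R, R))
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0.0)
    return m


class TestThresholdRows:
    def test_one_entry_kept_at_ten_percent_of_ten(self):
        m = _random_similarity(11, 0)
        t = threshold_rows(m, 0.1)  # ceil(0.1 * 10) = 1 per row
        assert np.all((t > 0).sum(axis=1) == 1)

    def test_fraction_one_is_identity_off_diagonal(self):
        m = _random_similarity(6, 1)
        np.testing.assert_array_equal(threshold_rows(m, 1.0), m)

    def test_ties_broken_by_lower_index(self):
        m = np.zeros((4, 4))
        m[0, 1:] = [0.5, 0.5, 0.5]  # three-way tie, keep ceil(.4*3)=2
        m += m.T
        t = threshold_rows(m, 0.4)
        assert t[0, 1] == 0.5 and t[0, 2] == 0.5 and t[0, 3] == 0.0

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            threshold_rows(_random_similarity(5, 2), 0.0)

    def test_kept_values_unchanged(self):
        m = _random_similarity(20, 3)
        t = threshold_rows(m, 0.3)
        kept = t > 0
        np.testing.assert_array_equal(t[kept], m[kept])


class TestNormalizedAngle:
    def test_identical_rows_affinity_one(self):
        T = np.tile([0.2, 0.0, 0.7, 0.1], (3, 1))
        a = normalized_angle_affinity(T)
        np.testing.assert_allclose(a, 1.0, atol=1e-12)

    def test_orthogonal_rows_half(self):
        T = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert normalized_angle_affinity(T)[0, 1] == pytest.approx(0.5)

    def test_45_degree_rows(self):
        # rows (1,0) and (1,1): cos = sqrt(2)/2, a = 1 - (pi/4)/pi = 0.75
        T = np.array([[1.0, 0.0], [1.0, 1.0]])
        assert normalized_angle_affinity(T)[0, 1] == pytest.approx(0.75)

    def test_zero_row_raises(self):
        T = np.array([[1.0, 0.0], [0.0, 0.0]])
        with pytest.raises(DegenerateInputError):
            normalized_angle_affinity(T)

    def test_bounds_on_nonnegative_input(self):
        rng = np.random.default_rng(4)
        T = threshold_rows(_random_similarity(30, 5), 0.2)
        a = normalized_angle_affinity(T)
        assert a.min() >= 0.5 - 1e-12 and a.max() <= 1.0 + 1e-12
        np.testing.assert_allclose(a, a.T, atol=1e-12)


def _ring_affinity(R, eps=1e-6):
    W = np.full((R, R), eps)
    np.fill_diagonal(W, 0.0)
    for i in range(R):
        W[i, (i + 1) % R] = W[(i + 1) % R, i] = 1.0
    return W


def _markov_oracle(W, alpha):
    """Independent dense-eigensolver reference for the diffusion operator."""
    d = W.sum(1)
    Wa = W / np.outer(d**alpha, d**alpha)
    P = Wa / Wa.sum(1, keepdims=True)
    evals, evecs = np.linalg.eig(P)
    order = np.argsort(evals.real)[::-1]
    return evals.real[order], evecs.real[:, order]


class TestDiffusionEmbed:
    def test_ring_first_gradient_is_sinusoid(self):
        R = 40
        gs = diffusion_embed(_ring_affinity(R), alpha=0.5, n_components=4)
        i = np.arange(R)
        basis = np.column_stack([np.cos(2 * np.pi * i / R), np.sin(2 * np.pi * i / R)])
        coef, *_ = np.linalg.lstsq(basis, gs.components[:, 0], rcond=None)
        fitted = basis @ coef
        assert abs(np.corrcoef(gs.components[:, 0], fitted)[0, 1]) > 0.99

    def test_variance_explained_matches_eigenvalue_ratios(self):
        W = normalized_angle_affinity(
            threshold_rows(_random_similarity(25, 6), 0.3)
        )
        gs = diffusion_embed(W, alpha=0.5, n_components=6)
        evals, _ = _markov_oracle(W, 0.5)
        lam = evals[1:7]
        np.testing.assert_allclose(gs.lambdas, lam, atol=1e-8)
        np.testing.assert_allclose(gs.variance_explained, lam / lam.sum(), atol=1e-8)

    def test_two_block_affinity_separates_blocks(self):
        W = np.full((12, 12), 0.05)
        W[:6, :6] = 1.0
        W[6:, 6:] = 1.0
        np.fill_diagonal(W, 0.0)
        g1 = diffusion_embed(W, 0.5, 2).components[:, 0]
        assert np.all(np.sign(g1[:6]) == np.sign(g1[0]))
        assert np.all(np.sign(g1[6:]) == -np.sign(g1[0]))

    def test_variance_explained_sums_to_one_and_descends(self):
        W = normalized_angle_affinity(
            threshold_rows(_random_similarity(20, 7), 0.3)
        )
        gs = diffusion_embed(W, 0.5, 5)
        assert gs.variance_explained.sum() == pytest.approx(1.0)
        assert np.all(np.diff(gs.variance_explained) <= 1e-12)

    def test_disconnected_graph_rejected(self):
        W = np.zeros((6, 6))
        W[:3, :3] = 1.0
        W[3:, 3:] = 1.0
        np.fill_diagonal(W, 0.0)
        with pytest.raises(ConnectivityError):
            diffusion_embed(W, 0.5, 2)

    def test_asymmetric_input_rejected(self):
        W = np.triu(np.ones((5, 5)))
        with pytest.raises(ValueError):
            diffusion_embed(W, 0.5, 2)


def _gset(components):
    k = components.shape[1]
    return GradientSet(
        components=components,
        lambdas=np.linspace(1, 0.5, k),
        variance_explained=np.full(k, 1 / k),
        alpha=0.5,
    )


class TestProcrustes:
    def test_identity_when_equal(self, rng):
        A = rng.normal(size=(30, 5))
        t = _gset(A)
        aligned = procrustes_align(_gset(A.copy()), t)
        np.testing.assert_allclose(aligned.components, A, atol=1e-10)

    def test_sign_flip_recovered(self, rng):
        A = rng.normal(size=(30, 4))
        flipped = A * np.array([-1, 1, 1, 1])
        aligned = procrustes_align(_gset(flipped), _gset(A))
        r = np.corrcoef(aligned.components[:, 0], A[:, 0])[0, 1]
        assert r > 0.999

    def test_random_rotation_recovered(self, rng):
        A = rng.normal(size=(40, 6))
        Q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        aligned = procrustes_align(_gset(A @ Q), _gset(A))
        assert np.linalg.norm(aligned.components - A) < 1e-6

    def test_variance_explained_preserved(self, rng):
        A = rng.normal(size=(20, 3))
        ind = _gset(A @ np.linalg.qr(rng.normal(size=(3, 3)))[0])
        ve = ind.variance_explained.copy()
        aligned = procrustes_align(ind, _gset(A))
        np.testing.assert_array_equal(aligned.variance_explained, ve)

    def test_rank_deficient_warns_identity(self, rng):
        A = rng.normal(size=(20, 3))
        degenerate = np.zeros((20, 3))
        with pytest.warns(UserWarning, match="rank-deficient"):
            aligned = procrustes_align(_gset(degenerate), _gset(A))
        np.testing.assert_allclose(
            aligned.components, A.mean(axis=0)[None, :].repeat(20, 0)
        )


class TestGroupTemplate:
    def test_identical_subjects_equal_template(self):
        m = _random_similarity(20, 8)
        mats = [MINDMatrix(values=m.copy(), region_ids=np.arange(1, 21))
                for _ in range(3)]
        template = build_group_template(mats, 0.2, 0.5, 4)
        single = diffusion_embed(
            normalized_angle_affinity(threshold_rows(m, 0.2)), 0.5, 4
        )
        # equal up to the template's per-component sign convention
        for j in range(4):
            r = np.corrcoef(template.components[:, j], single.components[:, j])[0, 1]
            assert abs(r) > 1 - 1e-9

    def test_template_deterministic(self):
        mats = [
            MINDMatrix(values=_random_similarity(15, s), region_ids=np.arange(15))
            for s in (1, 2, 3)
        ]
        t1 = build_group_template(mats)
        t2 = build_group_template(mats)
        np.testing.assert_array_equal(t1.components, t2.components)

    def test_anchor_orientation_positive(self):
        mats = [
            MINDMatrix(values=_random_similarity(30, s), region_ids=np.arange(30))
            for s in (4, 5)
        ]
        t = build_group_template(mats, 0.2, 0.5, 3)
        degree = np.mean([m.values for m in mats], axis=0).sum(1) / 29
        anchor = np.argsort(degree)[::-1][:3]
        assert np.all(t.components[anchor].mean(axis=0) >= 0)


class TestThresholdRobustness:
    def test_tmaps_consistent_across_thresholds(self, parc16):
        """Case-control t-maps at 10% vs 20% row threshold agree in
        direction (positive correlation) on a planted cohort."""
        from mindgrad import fit_region_glm
        import pandas as pd

        effect = [int(r) for r in parc16.region_ids[:2]]
        spec = CohortSpec(6, 6, effect_regions=frozenset(effect),
                          effect_size=1.5, seed=21)
        tables, cov = generate_cohort(parc16, spec)
        mats = [build_mind_matrix(t, parc16) for t in tables]
        t_maps = {}
        for fraction in (0.1, 0.2):
            template = build_group_template(mats, fraction=fraction)
            g1 = pd.DataFrame(
                [embed_subject(m, template, fraction=fraction).components[:, 0]
                 for m in mats],
                columns=parc16.region_ids,
            )
            t_maps[fraction] = fit_region_glm(g1, cov).t_values
        r = np.corrcoef(t_maps[0.1], t_maps[0.2])[0, 1]
        assert r > 0
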