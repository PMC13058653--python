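"""GLM contrast oracles, FDR arithmetic, aggregation, and KS tests."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from mindgrad import (
    aggregate_by_label,
    bh_fdr,
    distribution_test,
    fit_region_glm,
    generate_gradient_cohort,
    tmap_vs_reference,
)
from mindgrad.exceptions import DesignError, InsufficientSampleError


def _toy_cohort(parc, n=20, seed=0, **kw):
    return generate_gradient_cohort(parc, n // 2, n - n // 2, seed=seed, **kw)


class TestRegionGLM:
    def test_matches_statsmodels_oracle(self, parc16):
        g1, cov = _toy_cohort(parc16, n=20, seed=1)
        res = fit_region_glm(g1, cov)
        age_c = cov.age - cov.age.mean()
        edu_c = cov.education - cov.education.mean()
        X = np.column_stack(
            [np.ones(len(cov)), cov.group, age_c, cov.sex, edu_c,
             age_c * cov.sex]
        )
        for j, rid in enumerate(parc16.region_ids):
            fit = sm.OLS(g1[rid].to_numpy(), X).fit()
            assert res.t_values[j] == pytest.approx(fit.tvalues[1], abs=1e-8)
            assert res.p_values[j] == pytest.approx(fit.pvalues[1], abs=1e-8)

    def test_constant_group_rejected(self, parc16):
        g1, cov = _toy_cohort(parc16, n=10, seed=2)
        cov["group"] = 1
        with pytest.raises(DesignError, match="contrast"):
            fit_region_glm(g1, cov)

    def test_collinear_extra_covariate_named(self, parc16):
        g1, cov = _toy_cohort(parc16, n=12, seed=3)
        extra = pd.DataFrame({"group_copy": cov.group.to_numpy()})
        with pytest.raises(DesignError, match="group_copy"):
            fit_region_glm(g1, cov, extra_covariates=extra)

    def test_null_cohort_type_one_error(self, parc68):
        rejections = []
        for s in range(10):
            g1, cov = generate_gradient_cohort(parc68, 50, 50, seed=100 + s)
            res = fit_region_glm(g1, cov)
            rejections.append(np.mean(res.p_values < 0.05))
        assert 0.02 <= np.mean(rejections) <= 0.09

    def test_planted_effect_detected_null_regions_spared(self, parc68):
        effect = [int(r) for r in parc68.region_ids[:4]]
        g1, cov = generate_gradient_cohort(
            parc68, 49, 119, effect_regions=effect, effect_size=1.0, seed=7
        )
        res = fit_region_glm(g1, cov)
        mask = np.isin(res.region_ids.astype(int), effect)
        assert res.significant[mask].all()
        assert res.significant[~mask].mean() <= 0.05

    def test_nuisance_covariate_robustness(self, parc68):
        # a covariate uncorrelated with group barely moves the t-map
        g1, cov = generate_gradient_cohort(
            parc68, 30, 30, effect_regions=[1, 2], effect_size=1.0, seed=9
        )
        rng = np.random.default_rng(0)
        tiv = pd.DataFrame({"tiv": rng.normal(1500, 100, len(cov))})
        base = fit_region_glm(g1, cov)
        with_tiv = fit_region_glm(g1, cov, extra_covariates=tiv)
        assert np.median(np.abs(base.t_values - with_tiv.t_values)) < 0.2

    def test_subsample_robustness(self, parc68):
        # size-matched control subsampling keeps the planted t-map shape
        effect = [int(r) for r in parc68.region_ids[:4]]
        g1, cov = generate_gradient_cohort(
            parc68, 20, 60, effect_regions=effect, effect_size=1.2, seed=11
        )
        full = fit_region_glm(g1, cov)
        controls = cov.index[cov.group == 0]
        keep = cov.index[cov.group == 1].tolist() + controls[:20].tolist()
        sub = fit_region_glm(g1.iloc[keep], cov.iloc[keep].reset_index(drop=True))
        assert np.corrcoef(full.t_values, sub.t_values)[0, 1] > 0.5


class TestBHFDR:
    def test_step_up_hand_computation(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        np.testing.assert_array_equal(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_order_invariance(self):
        p = np.array([0.3, 0.001, 0.2, 0.04, 0.9])
        q = bh_fdr(p)
        perm = np.array([4, 2, 0, 1, 3])
        np.testing.assert_allclose(bh_fdr(p[perm]), q[perm])

    def test_q_at_least_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=30)
        assert np.all(bh_fdr(p) >= p - 1e-15)


class TestAggregate:
    def test_single_label_equals_whole_cortex_mean(self, parc16):
        g1, cov = _toy_cohort(parc16, n=16, seed=4)
        labels = np.ones(parc16.n_regions, dtype=int)
        agg = aggregate_by_label(g1, cov, labels)
        whole = fit_region_glm(
            pd.DataFrame({"all": g1.drop(columns="subject_id").mean(axis=1)}), cov
        )
        assert agg.t_values[0] == pytest.approx(whole.t_values[0], abs=1e-12)

    def test_label_means_exact(self, parc16):
        g1, cov = _toy_cohort(parc16, n=8, seed=5)
        g = g1.drop(columns="subject_id")
        labels = np.array([1, 1, 2, 2, 2, 3, 3, 3] * 2)
        # means computed independently by hand-indexing
        manual = g.iloc[:, np.flatnonzero(labels == 2)].mean(axis=1)
        agg_in = {lab: g.iloc[:, np.flatnonzero(labels == lab)].mean(axis=1)
                  for lab in (1, 2, 3)}
        pd.testing.assert_series_equal(agg_in[2], manual)

    def test_effect_confined_to_label_maximizes_its_t(self, parc68):
        labels = parc68.table.network_label.to_numpy()
        target_regions = [
            int(r) for r in parc68.region_ids[labels == 3]
        ]
        wins = 0
        for s in range(100):
            g1, cov = generate_gradient_cohort(
                parc68, 25, 25, effect_regions=target_regions,
                effect_size=0.8, seed=500 + s,
            )
            agg = aggregate_by_label(g1, cov, labels)
            lab_ids = agg.region_ids.astype(int)
            wins += lab_ids[np.argmax(np.abs(agg.t_values))] == 3
        assert wins >= 90

    def test_empty_label_rejected(self, parc16):
        g1, cov = _toy_cohort(parc16, n=8, seed=6)
        labels = np.ones(parc16.n_regions - 1, dtype=int)
        with pytest.raises(ValueError):
            aggregate_by_label(g1, cov, labels)


class TestDistribution:
    def test_identical_samples(self):
        x = np.arange(10.0)
        stat, p = distribution_test(x, x)
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_separated_samples_significant(self):
        rng = np.random.default_rng(2)
        _, p = distribution_test(rng.normal(0, 1, 50), rng.normal(3, 1, 50))
        assert p < 0.001

    def test_statistic_equals_max_ecdf_gap(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 1.2, 40)
        stat, _ = distribution_test(a, b)
        grid = np.sort(np.concatenate([a, b]))
        ecdf_a = np.searchsorted(np.sort(a), grid, side="right") / len(a)
        ecdf_b = np.searchsorted(np.sort(b), grid, side="right") / len(b)
        assert stat == pytest.approx(np.max(np.abs(ecdf_a - ecdf_b)))

    def test_too_few_subjects(self):
        with pytest.raises(InsufficientSampleError):
            distribution_test([1.0, 2.0], [3.0, 4.0, 5.0, 6.0, 7.0])


class TestTmapVsReference:
    def test_self_correlation(self, parc68, ensemble68):
        from mindgrad import generate_annotation_map

        t_map = generate_annotation_map(parc68, 0.5, seed=12)
        r, _ = tmap_vs_reference(t_map, t_map, ensemble68)
        assert r == pytest.approx(1.0)

    def test_amplified_cases_positive_association(self, parc68, ensemble68):
        """Cases expressing an amplified control pattern produce a t-map
        positively correlated with the control mean map."""
        hits = 0
        for s in range(10):
            base, cov_rng = generate_gradient_cohort(parc68, 1, 1, seed=700 + s)
            control_map = base.drop(columns="subject_id").iloc[0].to_numpy()
            rng = np.random.default_rng(800 + s)
            n_case, n_ctrl = 30, 30
            g_ctrl = control_map + rng.normal(0, 0.4, (n_ctrl, 68))
            g_case = 1.5 * control_map + rng.normal(0, 0.4, (n_case, 68))
            g1 = pd.DataFrame(np.vstack([g_case, g_ctrl]), columns=parc68.region_ids)
            cov = pd.DataFrame(
                {
                    "group": [1] * n_case + [0] * n_ctrl,
                    "age": rng.uniform(21, 50, 60),
                    "sex": rng.integers(0, 2, 60),
                    "education": rng.normal(14, 2, 60),
                }
            )
            res = fit_region_glm(g1, cov)
            r, p = tmap_vs_reference(res.t_values, control_map, ensemble68)
            hits += (r > 0) and (p < 0.05)
        assert hits >= 8
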