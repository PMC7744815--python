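"""Covariate adjustment, the selection chain, tallies and overlap rules."""

import numpy as np
import pytest

from mpradiomics.core import FeatureKey, SubjectRecord
from mpradiomics.selection import (
    BRANCHES,
    SelectionConfig,
    SelectionTally,
    adjust_covariates,
    decorrelate,
    fisher_rank,
    fisher_scores,
    high_frequency,
    lasso_select,
    mrmr_select,
    stability_run,
    stable_overlap,
    ttest_filter,
)
from mpradiomics.simulate import EffectSpec, synth_feature_cohort
from oracles import fisher_score_direct, ols_residuals_normal_equations


def records_for(fm, ages=None, sexes=None, edus=None):
    n = len(fm.subjects)
    rng = np.random.default_rng(0)
    ages = ages if ages is not None else rng.normal(66, 6, n)
    sexes = sexes if sexes is not None else rng.integers(0, 2, n)
    edus = edus if edus is not None else rng.normal(12, 3, n)
    return [
        SubjectRecord(id=s, group=0, age=float(a), sex=int(x), education=float(e))
        for s, a, x, e in zip(fm.subjects, ages, sexes, edus)
    ]


class TestAdjustCovariates:
    def test_feature_linear_in_age_residualizes_to_zero(self, feature_matrix_factory):
        ages = np.linspace(50, 80, 12)
        fm = feature_matrix_factory((2.0 * ages + 5.0)[:, None])
        recs = records_for(fm, ages=ages)
        adj = adjust_covariates(fm, recs)
        assert np.allclose(adj.values, 0.0, atol=1e-9)

    def test_orthogonal_covariates_leave_centered_feature(self, feature_matrix_factory, rng):
        n = 40
        x = rng.standard_normal(n)
        ages = rng.normal(66, 6, n)
        x = x - np.polyval(np.polyfit(ages, x, 1), ages)  # force orthogonality to age
        fm = feature_matrix_factory(x[:, None])
        recs = records_for(fm, ages=ages, sexes=np.zeros(n, int) , edus=np.full(n, 12.0))
        adj = adjust_covariates(fm, recs, covariates=("age",))
        assert np.allclose(adj.values[:, 0], x - x.mean(), atol=1e-9)

    def test_matches_normal_equations_oracle(self, feature_matrix_factory, rng):
        Y = rng.standard_normal((6, 3))
        ages = rng.normal(66, 5, 6)
        edus = rng.normal(12, 2, 6)
        fm = feature_matrix_factory(Y)
        recs = records_for(fm, ages=ages, edus=edus, sexes=np.zeros(6, int))
        adj = adjust_covariates(fm, recs, covariates=("age", "education"))
        expected = ols_residuals_normal_equations(Y, np.column_stack([ages, edus]))
        assert np.allclose(adj.values, expected, atol=1e-8)

    def test_constant_covariate_dropped_with_warning(self, feature_matrix_factory, rng, caplog):
        fm = feature_matrix_factory(rng.standard_normal((10, 2)))
        recs = records_for(fm, sexes=np.zeros(10, int))
        with caplog.at_level("WARNING"):
            adj = adjust_covariates(fm, recs)
        assert "constant" in caplog.text
        assert adj.shape == (10, 2)

    def test_missing_covariate_subjects_dropped(self, feature_matrix_factory, rng):
        fm = feature_matrix_factory(rng.standard_normal((10, 2)))
        recs = records_for(fm)
        recs[0] = SubjectRecord(id=recs[0].id, group=0, age=np.nan, sex=0, education=12.0)
        adj = adjust_covariates(fm, recs)
        assert len(adj.subjects) == 9


class TestTtestFilter:
    def test_constant_feature_removed(self, feature_matrix_factory):
        values = np.column_stack([np.ones(20), np.r_[np.zeros(10), np.ones(10)]])
        fm = feature_matrix_factory(values)
        labels = np.r_[np.zeros(10, int), np.ones(10, int)]
        kept = ttest_filter(fm, labels, alpha=0.05)
        assert [k.region for k in kept] == ["f_0001"]

    def test_huge_separation_retained(self, feature_matrix_factory, rng):
        x = rng.standard_normal(80)
        x[40:] += 10.0  # 10 pooled SDs
        fm = feature_matrix_factory(x[:, None])
        labels = np.r_[np.zeros(40, int), np.ones(40, int)]
        assert len(ttest_filter(fm, labels, alpha=0.05)) == 1

    def test_alpha_one_keeps_all_defined(self, feature_matrix_factory, rng):
        fm = feature_matrix_factory(rng.standard_normal((20, 5)))
        labels = np.r_[np.zeros(10, int), np.ones(10, int)]
        assert len(ttest_filter(fm, labels, alpha=1.0)) == 5

    def test_one_class_errors(self, feature_matrix_factory, rng):
        fm = feature_matrix_factory(rng.standard_normal((10, 2)))
        with pytest.raises(ValueError, match="both groups"):
            ttest_filter(fm, np.zeros(10, int), 0.05)


class TestDecorrelate:
    def test_duplicate_column_keeps_one(self, feature_matrix_factory, rng):
        x = rng.standard_normal(30)
        x[15:] += 2.0
        fm = feature_matrix_factory(np.column_stack([x, x]))
        labels = np.r_[np.zeros(15, int), np.ones(15, int)]
        kept = decorrelate(fm, list(fm.keys), labels, 0.8)
        assert len(kept) == 1

    def test_orthogonal_columns_all_kept(self, feature_matrix_factory):
        values = np.eye(6)[:, :4]
        labels = np.array([0, 0, 0, 1, 1, 1])
        fm = feature_matrix_factory(values + 0.01 * np.arange(6)[:, None])
        kept = decorrelate(fm, list(fm.keys), labels, 0.8)
        assert len(kept) == 4

    def test_chain_rule_keeps_A_and_C(self, feature_matrix_factory, rng):
        """r(A,B)=0.9, r(B,C)=0.9, r(A,C)=0.5, p-order A<B<C -> {A, C}."""
        n = 4000
        labels = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        # construct with explicit factor structure to hit the target r's
        za, zc = rng.standard_normal((2, n))
        zc = 0.5 * za + np.sqrt(1 - 0.25) * zc
        zb = (0.9 * za + 0.9 * zc - 0.9 * 0.5 * za) / np.sqrt(1 - 0.25)
        # normalize b to unit variance and verify correlations empirically
        b_raw = 0.643 * za + 0.643 * zc
        b = (b_raw - b_raw.mean()) / b_raw.std() + 0.001 * rng.standard_normal(n)
        A = za + 0.30 * labels
        B = b + 0.20 * labels
        C = zc + 0.10 * labels
        fm = feature_matrix_factory(np.column_stack([A, B, C]))
        r = np.corrcoef(fm.values, rowvar=False)
        assert abs(r[0, 1]) > 0.8 and abs(r[1, 2]) > 0.8 and abs(r[0, 2]) < 0.8
        kept = decorrelate(fm, list(fm.keys), labels, 0.8)
        assert [k.region for k in kept] == ["f_0000", "f_0002"]

    def test_posthoc_max_correlation_bound(self, feature_matrix_factory, rng):
        cohort = synth_feature_cohort(
            200, EffectSpec(n_cases=40, n_controls=40, feature_noise_corr=0.85, seed=3)
        )
        labels = cohort.labels
        kept = decorrelate(cohort.features, list(cohort.features.keys), labels, 0.8)
        sub = cohort.features.subset(kept)
        r = np.corrcoef(sub.values, rowvar=False)
        np.fill_diagonal(r, 0.0)
        assert np.abs(r).max() <= 0.8 + 1e-12


class TestFisherRank:
    def test_zero_within_class_variance_outranks(self, feature_matrix_factory, rng):
        labels = np.r_[np.zeros(5, int), np.ones(5, int)]
        perfect = labels.astype(float)
        noisy = labels + 0.3 * rng.standard_normal(10)
        fm = feature_matrix_factory(np.column_stack([noisy, perfect]))
        ranked = fisher_rank(fm, labels, k=2)
        assert ranked[0].region == "f_0001"

    def test_identical_distributions_score_zero(self):
        x = np.tile([1.0, 2.0, 3.0], 2)
        labels = np.r_[np.zeros(3, int), np.ones(3, int)]
        f = fisher_scores(x[:, None], labels)
        assert f[0] == pytest.approx(0.0)

    def test_matches_direct_formula(self, feature_matrix_factory, rng):
        values = rng.standard_normal((8, 4))
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        f = fisher_scores(values, labels)
        for j in range(4):
            assert f[j] == pytest.approx(fisher_score_direct(values[:, j], labels))

    def test_k_exceeding_pool_returns_all(self, feature_matrix_factory, rng):
        fm = feature_matrix_factory(rng.standard_normal((10, 3)))
        labels = np.r_[np.zeros(5, int), np.ones(5, int)]
        assert len(fisher_rank(fm, labels, k=10)) == 3


class TestLassoSelect:
    def test_tiny_penalty_gives_empty_selection(self, feature_matrix_factory, rng):
        fm = feature_matrix_factory(rng.standard_normal((40, 6)))
        labels = np.r_[np.zeros(20, int), np.ones(20, int)]
        assert lasso_select(fm, labels, C=1e-6) == []

    def test_informative_feature_selected(self, feature_matrix_factory, rng):
        labels = np.r_[np.zeros(30, int), np.ones(30, int)]
        signal = labels + 0.05 * rng.standard_normal(60)
        noise = rng.standard_normal((60, 9))
        fm = feature_matrix_factory(np.column_stack([signal, noise]))
        sel = lasso_select(fm, labels, C=0.1)
        assert FeatureKey("structural", "f_0000", "1", "global", "variance") in sel

    def test_duplicated_columns_share_one_weight(self, feature_matrix_factory, rng):
        """For identical columns the L1 objective depends only on the summed
        weight, so the duplicated fit carries the same total coefficient as a
        single-column fit (the split between the twins is arbitrary)."""
        from sklearn.linear_model import LogisticRegression

        labels = np.r_[np.zeros(30, int), np.ones(30, int)]
        signal = labels + 0.2 * rng.standard_normal(60)
        z = (signal - signal.mean()) / signal.std()
        single = LogisticRegression(l1_ratio=1.0, C=0.05, solver="liblinear",
                                    max_iter=2000).fit(z[:, None], labels)
        pair = LogisticRegression(l1_ratio=1.0, C=0.05, solver="liblinear",
                                  max_iter=2000).fit(np.column_stack([z, z]), labels)
        assert pair.coef_.sum() == pytest.approx(single.coef_.sum(), rel=1e-2)

    def test_inner_cv_path_runs(self, feature_matrix_factory, rng):
        labels = np.r_[np.zeros(25, int), np.ones(25, int)]
        signal = labels + 0.3 * rng.standard_normal(50)
        fm = feature_matrix_factory(np.column_stack([signal, rng.standard_normal((50, 4))]))
        sel = lasso_select(fm, labels, SelectionConfig(lasso_inner_folds=3))
        assert FeatureKey("structural", "f_0000", "1", "global", "variance") in sel


class TestMrmrSelect:
    def test_single_candidate_selected(self, feature_matrix_factory, rng):
        fm = feature_matrix_factory(rng.standard_normal((12, 1)))
        labels = np.r_[np.zeros(6, int), np.ones(6, int)]
        assert len(mrmr_select(fm, labels, k=5)) == 1

    def test_label_copy_selected_first(self, feature_matrix_factory, rng):
        labels = np.r_[np.zeros(15, int), np.ones(15, int)]
        fm = feature_matrix_factory(
            np.column_stack([rng.standard_normal(30), labels.astype(float),
                             rng.standard_normal(30)])
        )
        sel = mrmr_select(fm, labels, k=3)
        assert sel[0].region == "f_0001"

    def test_redundant_duplicate_deferred(self, feature_matrix_factory, rng):
        """A duplicate of the first pick ranks below an independent weaker
        feature under the relevance-minus-redundancy criterion."""
        labels = np.r_[np.zeros(40, int), np.ones(40, int)]
        strong = labels + 0.1 * rng.standard_normal(80)
        weak = labels + 1.2 * rng.standard_normal(80)
        fm = feature_matrix_factory(
            np.column_stack([strong, strong.copy(), weak, rng.standard_normal(80)])
        )
        sel = mrmr_select(fm, labels, k=3)
        regions = [k.region for k in sel]
        assert regions[0] == "f_0000"
        assert regions.index("f_0002") < regions.index("f_0001") if "f_0001" in regions else True
        assert regions[1] != "f_0001"


@pytest.fixture(scope="module")
def planted_cohort():
    spec = EffectSpec(n_cases=40, n_controls=40, n_planted=1, effect_size_d=20.0,
                      feature_noise_corr=0.3, seed=11)
    return synth_feature_cohort(120, spec)


class TestStabilityRun:

    def test_overwhelming_effect_saturates_fisher_tally(self, planted_cohort):
        cohort = planted_cohort
        cfg = SelectionConfig(seed=5, folds=5, repetitions=4)
        res = stability_run(cohort.features, cohort.labels, cfg)
        planted = cohort.planted_keys[0]
        assert res.tallies["fisher"].counts[planted] == cfg.max_possible
        for b in BRANCHES:
            assert max(res.tallies[b].counts.values()) <= cfg.max_possible

    def test_same_seed_identical_tallies(self, planted_cohort):
        cohort = planted_cohort
        cfg = SelectionConfig(seed=9, folds=3, repetitions=2)
        r1 = stability_run(cohort.features, cohort.labels, cfg)
        r2 = stability_run(cohort.features, cohort.labels, cfg)
        for b in BRANCHES:
            assert r1.tallies[b].counts == r2.tallies[b].counts
        assert np.array_equal(r1.fold_assignments, r2.fold_assignments)

    def test_tally_monotone_in_effect_size(self):
        """A planted feature's mean Fisher tally never drops as its effect
        size grows (checked over seeds at d in {0, 0.5, 2.0})."""
        mean_tallies = []
        for d in (0.0, 0.5, 2.0):
            tallies = []
            for seed in (0, 1, 2):
                cohort = synth_feature_cohort(
                    300,
                    EffectSpec(n_cases=40, n_controls=40, n_planted=1,
                               effect_size_d=d, seed=50 + seed),
                )
                cfg = SelectionConfig(seed=seed, folds=5, repetitions=3)
                res = stability_run(cohort.features, cohort.labels, cfg)
                tallies.append(res.tallies["fisher"].counts.get(cohort.planted_keys[0], 0))
            mean_tallies.append(np.mean(tallies))
        assert mean_tallies[0] <= mean_tallies[1] <= mean_tallies[2]

    def test_null_labels_no_saturation(self, rng):
        cohort = synth_feature_cohort(
            150, EffectSpec(n_cases=30, n_controls=30, n_planted=0, effect_size_d=0.0, seed=2)
        )
        cfg = SelectionConfig(seed=1, folds=5, repetitions=4)
        res = stability_run(cohort.features, cohort.labels, cfg)
        for b in BRANCHES:
            if res.tallies[b].counts:
                assert max(res.tallies[b].counts.values()) < cfg.max_possible


class TestHighFrequencyAndOverlap:
    def _tally(self, counts, max_possible=500, branch="fisher"):
        keys = {
            FeatureKey("structural", f"r_{i:03d}", "1", "GLSZM", "LZHGE"): c
            for i, c in enumerate(counts)
        }
        return SelectionTally(branch=branch, counts=keys, max_possible=max_possible)

    def test_top_ten_of_twelve(self):
        tally = self._tally(list(range(1, 13)))
        top = high_frequency(tally, 10)
        assert len(top) == 10
        assert [c for _, c in top] == list(range(12, 2, -1))

    def test_tie_at_rank_ten_resolved_canonically(self):
        counts = [100] * 5 + [50] * 7  # tie among the 50s at the boundary
        tally = self._tally(counts)
        top = high_frequency(tally, 10)
        tied = [k.region for k, c in top if c == 50]
        assert tied == sorted(tied)  # canonical order

    def test_fewer_than_ten_nonzero(self):
        tally = self._tally([5, 3, 0, 0, 0])
        assert len(high_frequency(tally, 10)) == 2

    def test_overlap_and_mean_counts(self):
        def key(i):
            return FeatureKey("structural", f"r_{i:03d}", "1", "GLSZM", "LZHGE")

        shared = {key(i): 400 + i for i in range(3)}
        tallies = {}
        for j, b in enumerate(BRANCHES):
            counts = dict(shared)
            for i in range(3, 11):
                counts[key(100 * (j + 1) + i)] = 350 - i
            tallies[b] = SelectionTally(branch=b, counts=counts, max_possible=500)
        report = stable_overlap(tallies)
        assert set(report.stable) == set(shared)
        assert set(report.stable_300) == set(shared)  # only shared exceed 300 in all
        assert report.mean_counts[key(0)] == pytest.approx(400.0)

    def test_branch_specific_counts_average(self):
        """Per-branch counts (500, 391, 486) average to 459."""
        k = FeatureKey("structural", "Cingulum_Post_R", "2/3", "GLSZM", "LZHGE")
        tallies = {
            b: SelectionTally(
                branch=b, counts={k: c}, max_possible=500
            )
            for b, c in zip(BRANCHES, (500, 391, 486))
        }
        report = stable_overlap(tallies)
        assert report.stable == [k]
        assert report.mean_counts[k] == pytest.approx(459.0)

    def test_disjoint_lists_empty_stable(self):
        tallies = {}
        for j, b in enumerate(BRANCHES):
            tallies[b] = self._tally([200] * 10, branch=b)
            tallies[b] = SelectionTally(
                branch=b,
                counts={
                    FeatureKey("structural", f"b{j}_{i:03d}", "1", "GLCM", "energy"): 200
                    for i in range(10)
                },
                max_possible=500,
            )
        report = stable_overlap(tallies)
        assert report.stable == []
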