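import numpy as np
import pytest
from scipy import stats

import snpmri as sm
from snpmri.errors import DataError, UsageError
from snpmri.explain import interaction_matrix


class TestShapleyExact:
    def test_additive_model_closed_form(self):
        fn = lambda X: 2 * X[:, 0] + 3 * X[:, 1]
        attr = sm.shapley_values(fn, [[1.0, 1.0]], [[0.0, 0.0]],
                                 estimator="exact")
        assert np.allclose(attr.values, [[2.0, 3.0]])

    def test_efficiency_axiom(self):
        rng = np.random.default_rng(0)
        fn = lambda X: np.sin(X[:, 0]) * X[:, 1] + (X[:, 2] > 0) * X[:, 3]
        X = rng.normal(size=(4, 4))
        bg = rng.normal(size=(12, 4))
        attr = sm.shapley_values(fn, X, bg, estimator="exact")
        assert np.allclose(attr.values.sum(axis=1),
                           fn(X) - attr.base_value, atol=1e-9)

    def test_symmetry_axiom(self):
        # two interchangeable features receive equal credit on symmetric input
        fn = lambda X: X[:, 0] + X[:, 1] + X[:, 0] * X[:, 1]
        attr = sm.shapley_values(fn, [[2.0, 2.0, 1.0]],
                                 [[0.0, 0.0, 0.0]], estimator="exact")
        assert attr.values[0, 0] == pytest.approx(attr.values[0, 1], abs=1e-12)

    def test_dummy_axiom(self):
        fn = lambda X: X[:, 0] ** 2  # feature 1 ignored
        rng = np.random.default_rng(1)
        attr = sm.shapley_values(fn, rng.normal(size=(3, 2)),
                                 rng.normal(size=(8, 2)), estimator="exact")
        assert np.allclose(attr.values[:, 1], 0.0, atol=1e-12)

    def test_exact_refused_above_limit(self):
        fn = lambda X: X.sum(axis=1)
        with pytest.raises(UsageError, match="sampling"):
            sm.shapley_values(fn, np.ones((1, 16)), np.zeros((1, 16)),
                              estimator="exact")

    def test_empty_background_fatal(self):
        with pytest.raises(DataError):
            sm.shapley_values(lambda X: X.sum(1), np.ones((1, 2)),
                              np.empty((0, 2)))


class TestShapleySampling:
    def test_matches_exact_within_monte_carlo_error(self):
        rng = np.random.default_rng(2)
        from sklearn.ensemble import RandomForestRegressor
        Xtr = rng.normal(size=(200, 5))
        ytr = Xtr[:, 0] * Xtr[:, 1] + Xtr[:, 2] + 0.1 * rng.normal(size=200)
        rf = RandomForestRegressor(n_estimators=50, random_state=0).fit(Xtr, ytr)
        fn = lambda X: rf.predict(X)
        X = rng.normal(size=(2, 5))
        bg = rng.normal(size=(15, 5))
        exact = sm.shapley_values(fn, X, bg, estimator="exact")
        sampled = sm.shapley_values(fn, X, bg, estimator="sampling",
                                    n_samples=2000, seed=3)
        gap = np.abs(exact.values - sampled.values)
        assert np.all(gap <= 3 * sampled.standard_errors + 1e-9)

    def test_spread_shrinks_with_more_samples(self):
        rng = np.random.default_rng(4)
        fn = lambda X: X[:, 0] * X[:, 1] + X[:, 2]
        x = rng.normal(size=(1, 3))
        bg = rng.normal(size=(10, 3))

        def spread(n_samples):
            vals = [sm.shapley_values(fn, x, bg, estimator="sampling",
                                      n_samples=n_samples, seed=s).values
                    for s in range(8)]
            return np.std(np.array(vals), axis=0).mean()

        assert spread(800) < spread(50)

    def test_seeded_determinism(self):
        fn = lambda X: X.sum(axis=1)
        x = np.ones((1, 4))
        bg = np.zeros((5, 4))
        a = sm.shapley_values(fn, x, bg, estimator="sampling", n_samples=50,
                              seed=9)
        b = sm.shapley_values(fn, x, bg, estimator="sampling", n_samples=50,
                              seed=9)
        assert np.array_equal(a.values, b.values)


class TestInteraction:
    def test_additive_model_has_zero_interactions(self):
        fn = lambda X: 2 * X[:, 0] + 3 * X[:, 1] - X[:, 2]
        rng = np.random.default_rng(5)
        X = rng.normal(size=(2, 3))
        bg = rng.normal(size=(6, 3))
        for pair in ((0, 1), (0, 2), (1, 2)):
            vals = sm.shapley_interaction(fn, X, pair, bg, estimator="exact")
            assert np.allclose(vals, 0.0, atol=1e-10)

    def test_product_game_four_coalition_value(self):
        # v({1,2}) - v({1}) - v({2}) + v(empty) = 1 for f(x)=x1*x2 at (1,1)
        fn = lambda X: X[:, 0] * X[:, 1]
        vals = sm.shapley_interaction(fn, [[1.0, 1.0]], (0, 1), [[0.0, 0.0]],
                                      estimator="exact")
        assert vals[0] == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_in_the_pair(self):
        rng = np.random.default_rng(6)
        fn = lambda X: X[:, 0] * X[:, 1] + X[:, 2] ** 2
        X = rng.normal(size=(2, 3))
        bg = rng.normal(size=(5, 3))
        a = sm.shapley_interaction(fn, X, (0, 1), bg, estimator="exact")
        b = sm.shapley_interaction(fn, X, (1, 0), bg, estimator="exact")
        assert np.allclose(a, b, atol=1e-12)

    def test_sampling_matches_exact(self):
        rng = np.random.default_rng(7)
        fn = lambda X: X[:, 0] * X[:, 1] + np.sin(X[:, 2]) * X[:, 3]
        X = rng.normal(size=(1, 4))
        bg = rng.normal(size=(8, 4))
        exact = sm.shapley_interaction(fn, X, (0, 1), bg, estimator="exact")
        sampled = sm.shapley_interaction(fn, X, (0, 1), bg,
                                         estimator="sampling",
                                         n_samples=6000, seed=8)
        assert sampled[0] == pytest.approx(exact[0], abs=0.1)

    def test_identical_indices_fatal(self):
        with pytest.raises(UsageError):
            sm.shapley_interaction(lambda X: X.sum(1), np.ones((1, 3)),
                                   (1, 1), np.zeros((2, 3)))

    def test_matrix_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(8)
        fn = lambda X: X[:, 0] * X[:, 1] + X[:, 2]
        M = interaction_matrix(fn, rng.normal(size=(2, 3)),
                               rng.normal(size=(4, 3)))
        assert np.allclose(M, M.T)
        assert np.all(np.diag(M) == 0)


def two_variable_pearson(x, y):
    """Closed-form r from covariance / variances — independent oracle."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    cx, cy = x - x.mean(), y - y.mean()
    return float((cx * cy).sum() / np.sqrt((cx ** 2).sum() * (cy ** 2).sum()))


class TestPearson:
    def test_self_correlation_is_one(self):
        x = np.array([[1.0], [2.0], [5.0], [3.0]])
        R, _ = sm.pearson_matrix(x, x)
        assert R[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_exact_inverse_linear(self):
        R, P = sm.pearson_matrix(np.array([[1.0], [2.0], [3.0]]),
                                 np.array([[6.0], [4.0], [2.0]]))
        assert R[0, 0] == pytest.approx(-1.0, abs=1e-12)

    def test_hand_value(self):
        R, _ = sm.pearson_matrix(np.array([[1.0], [2.0], [3.0]]),
                                 np.array([[1.0], [3.0], [2.0]]))
        assert R[0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_matches_two_variable_oracle_and_scipy(self):
        rng = np.random.default_rng(9)
        A = rng.normal(size=(40, 3))
        B = rng.normal(size=(40, 4))
        R, P = sm.pearson_matrix(A, B)
        for i in range(3):
            for j in range(4):
                assert R[i, j] == pytest.approx(
                    two_variable_pearson(A[:, i], B[:, j]), abs=1e-12)
                r_sp, p_sp = stats.pearsonr(A[:, i], B[:, j])
                assert P[i, j] == pytest.approx(p_sp, rel=1e-9)

    def test_constant_column_yields_nan(self):
        A = np.ones((10, 1))
        B = np.random.default_rng(10).normal(size=(10, 2))
        R, P = sm.pearson_matrix(A, B)
        assert np.isnan(R).all() and np.isnan(P).all()

    def test_too_few_subjects_fatal(self):
        with pytest.raises(DataError):
            sm.pearson_matrix(np.ones((2, 1)), np.ones((2, 1)))


def _stratified_cohort(n, beta, seed, maf=0.3):
    spec = sm.SyntheticSpec(n_subjects=n, n_snps=1, n_rois=1, mafs=maf,
                            causal_pairs=[(0, 0, beta)] if beta else [],
                            prevalences={"NC": 0.5, "AD": 0.5},
                            noise_sd=1.0, seed=seed)
    cohort, _ = sm.simulate_cohort(spec)
    return cohort


class TestStratifiedTest:
    def test_planted_effect_detected_with_monotone_medians(self):
        cohort = _stratified_cohort(300, beta=5.0, seed=0)
        res = sm.genotype_stratified_test(cohort, cohort.snp_ids[0],
                                          cohort.roi_ids[0])
        assert res.p_value < 0.05 and res.significant
        medians = [g["median"] for g in res.groups]
        assert medians == sorted(medians)

    def test_null_rejection_rate_near_alpha(self):
        # quick calibration check; the full 1000-replicate version lives in
        # the acceptance suite
        rej = 0
        for s in range(200):
            cohort = _stratified_cohort(120, beta=0.0, seed=1000 + s)
            res = sm.genotype_stratified_test(cohort, cohort.snp_ids[0],
                                              cohort.roi_ids[0])
            rej += res.p_value < 0.05
        assert 0.01 <= rej / 200 <= 0.10

    def test_two_group_case_is_mann_whitney_and_symmetric(self):
        rng = np.random.default_rng(3)
        g = np.array([0.0] * 10 + [1.0] * 10)
        y = rng.normal(size=20)
        cohort = sm.CohortTable(
            subject_ids=[f"s{i}" for i in range(20)],
            genotypes=g[:, None], snp_ids=["rs1"], imaging=y[:, None],
            roi_ids=["R1"],
            labels=np.array(["NC", "AD"] * 10, dtype=object))
        res = sm.genotype_stratified_test(cohort, "rs1", "R1")
        assert "mann-whitney" in res.test_name
        # swap the phenotype values between the two groups: same p
        y2 = np.concatenate([y[10:], y[:10]])
        cohort2 = sm.CohortTable(
            subject_ids=cohort.subject_ids, genotypes=g[:, None],
            snp_ids=["rs1"], imaging=y2[:, None], roi_ids=["R1"],
            labels=cohort.labels)
        res2 = sm.genotype_stratified_test(cohort2, "rs1", "R1")
        assert res.p_value == pytest.approx(res2.p_value, abs=1e-12)

    def test_allele_labels_rendered_when_metadata_present(self):
        cohort = _stratified_cohort(200, beta=1.0, seed=5)
        cohort.alleles["rs001"] = ("G", "A")
        res = sm.genotype_stratified_test(cohort, "rs001", cohort.roi_ids[0])
        assert {g["genotype"] for g in res.groups} <= {"GG", "AG", "AA"}

    def test_by_diagnosis_adds_crossed_summaries(self):
        cohort = _stratified_cohort(400, beta=2.0, seed=6)
        res = sm.genotype_stratified_test(cohort, cohort.snp_ids[0],
                                          cohort.roi_ids[0],
                                          by_diagnosis=True)
        assert all("diagnosis" in g for g in res.groups)
        assert res.per_diagnosis_p is not None

    def test_insufficient_groups_fatal(self):
        cohort = _stratified_cohort(50, beta=0.0, seed=7)
        cohort.genotypes[:] = 0.0
        with pytest.raises(DataError, match="group sizes"):
            sm.genotype_stratified_test(cohort, cohort.snp_ids[0],
                                        cohort.roi_ids[0])


class TestBenjaminiHochberg:
    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(12)
        p = rng.random(25)
        _, expected, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(sm.benjamini_hochberg(p), expected, atol=1e-12)

    def test_monotone_and_capped(self):
        adj = sm.benjamini_hochberg([0.001, 0.9, 0.04, 0.5])
        assert np.all(adj <= 1.0)
        assert adj[0] <= adj[2] <= adj[3] <= adj[1]


class TestImportanceRanking:
    def _attr(self, values, names):
        return sm.AttributionResult(values=np.asarray(values, float),
                                    feature_names=list(names),
                                    target_class="AD", estimator="exact",
                                    base_value=0.0)

    def test_dominant_feature_ranks_first(self):
        attr = self._attr([[0.1, 5.0, 0.2]], ["a", "b", "c"])
        assert sm.importance_ranking(attr)[0][0] == "b"

    def test_all_zero_gives_alphabetical(self):
        attr = self._attr([[0.0, 0.0, 0.0]], ["c", "a", "b"])
        assert [f for f, _ in sm.importance_ranking(attr)] == ["a", "b", "c"]

    def test_top_k_clipped_to_feature_count(self):
        attr = self._attr([[1.0, 2.0]], ["a", "b"])
        assert len(sm.importance_ranking(attr, top_k=10)) == 2
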