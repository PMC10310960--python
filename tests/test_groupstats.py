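"""Group-level regression models, orthogonalization and correlations."""
import numpy as np
import pandas as pd
import pytest

import cvrkit as ck


class TestStandardize:
    def test_three_point_example(self):
        np.testing.assert_allclose(ck.standardize([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])

    def test_zero_mean_unit_sd(self, rng):
        z = ck.standardize(rng.normal(10, 3, size=50))
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self, rng):
        x = rng.normal(size=30)
        np.testing.assert_allclose(ck.standardize(ck.standardize(x)),
                                   ck.standardize(x), atol=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            ck.standardize(np.full(10, 2.0))


class TestOrthogonalize:
    def test_self_orthogonalization_vanishes(self, rng):
        b = rng.normal(size=40)
        assert np.abs(ck.orthogonalize(b, b)).max() < 1e-10

    def test_result_uncorrelated_with_target(self, rng):
        a, b = rng.normal(size=(2, 60))
        out = ck.orthogonalize(a, b)
        assert abs(np.corrcoef(out, b)[0, 1]) < 1e-10

    def test_already_orthogonal_input_only_demeaned(self):
        b = np.array([-1.0, 1.0, -1.0, 1.0])
        a = np.array([1.0, 1.0, -1.0, -1.0]) + 5.0  # uncorrelated with b
        np.testing.assert_allclose(ck.orthogonalize(a, b), a - a.mean(), atol=1e-12)

    def test_constant_target_rejected(self, rng):
        with pytest.raises(ValueError):
            ck.orthogonalize(rng.normal(size=10), np.ones(10))


def _random_records(rng, n=40, planted_beta=0.0):
    tau = rng.normal(-0.02, 0.005, size=n)
    cvr1 = rng.normal(0.2, 0.05, size=n)
    cvr2 = 0.2 + planted_beta * (tau + 0.02) + rng.normal(0, 0.02, size=n)
    return pd.DataFrame({
        "id": [f"s{i}" for i in range(n)],
        "roi": "global",
        "age": rng.normal(65, 10, size=n),
        "sex": rng.choice(["M", "F"], size=n),
        "group": rng.choice(["cognitive", "sleep_apnea"], size=n),
        "design": rng.choice(["A", "B"], size=n),
        "cvr1": cvr1,
        "cvr2": cvr2,
        "transition_rate_1": tau,
    })


class TestFitModel1:
    def test_planted_negative_effect_recovered(self):
        rec = ck.cohort_records(ck.synthesize_cohort(n_subjects=54, beta=-80.0, seed=0))
        res = ck.fit_model1(rec)
        pe, p = res.term("transition_rate")
        assert pe < 0 and p <= 0.0125
        assert set(res.params) == {"transition_rate", "age", "sex", "group", "design"}

    def test_matches_normal_equations_oracle(self, rng):
        rec = _random_records(rng)
        res = ck.fit_model1(rec)
        df = rec.copy()
        df["sex"] = (df.sex == "M").astype(float)
        df["group"] = (df.group == "sleep_apnea").astype(float)
        df["design"] = (df.design == "B").astype(float)
        X = np.column_stack([
            np.ones(len(df)),
            ck.standardize(df.transition_rate_1),
            ck.standardize(df.age),
            df.sex, df.group, df.design,
        ])
        y = ck.standardize(df.cvr2)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.params["transition_rate"] == pytest.approx(beta[1], abs=1e-8)
        assert res.params["age"] == pytest.approx(beta[2], abs=1e-8)

    def test_duplicating_rows_keeps_pe_shrinks_p(self, rng):
        rec = _random_records(rng, planted_beta=-3.0)
        doubled = pd.concat([rec, rec], ignore_index=True)
        r1, r2 = ck.fit_model1(rec), ck.fit_model1(doubled)
        assert r2.params["transition_rate"] == pytest.approx(
            r1.params["transition_rate"], rel=1e-6
        )
        assert r2.pvalues["transition_rate"] < r1.pvalues["transition_rate"]

    def test_standardized_pes_invariant_to_affine_rescaling(self, rng):
        rec = _random_records(rng, planted_beta=-2.0)
        scaled = rec.copy()
        scaled["transition_rate_1"] = 1000.0 * scaled.transition_rate_1 + 7.0
        scaled["cvr2"] = 0.01 * scaled.cvr2 - 3.0
        r1, r2 = ck.fit_model1(rec), ck.fit_model1(scaled)
        for term in r1.params:
            sign = -1.0 if term == "cvr2" else 1.0  # outcome scale flip is positive here
            assert r2.params[term] == pytest.approx(sign * r1.params[term], abs=1e-8)

    def test_missing_rows_dropped_and_counted(self, rng):
        rec = _random_records(rng)
        rec.loc[0, "cvr2"] = np.nan
        res = ck.fit_model1(rec)
        assert res.n_dropped == 1 and res.n_used == len(rec) - 1

    def test_rank_deficiency_names_collinear_terms(self, rng):
        rec = _random_records(rng)
        # design indicator perfectly tracks the group indicator
        rec["design"] = np.where(rec.group == "sleep_apnea", "B", "A")
        with pytest.raises(ValueError, match="collinear"):
            ck.fit_model1(rec)

    def test_too_few_records_rejected(self, rng):
        with pytest.raises(ValueError, match="10"):
            ck.fit_model1(_random_records(rng, n=8))


class TestFitModel2:
    def test_both_planted_effects_significant_at_low_noise(self):
        rec = ck.cohort_records(
            ck.synthesize_cohort(n_subjects=54, beta=-80.0, seed=4, noise_sd=2.0)
        )
        res = ck.fit_model2(rec)
        pe_c, p_c = res.term("cvr1")
        pe_t, p_t = res.term("transition_rate_orth")
        assert pe_c > 0 and p_c <= 0.0125
        assert pe_t < 0 and p_t <= 0.0125

    def test_orthogonalized_term_uncorrelated_with_cvr1_by_construction(self, rng):
        rec = _random_records(rng)
        orth = ck.orthogonalize(rec.transition_rate_1, rec.cvr1)
        assert abs(np.corrcoef(orth, rec.cvr1)[0, 1]) < 1e-10

    def test_rate_determined_by_cvr1_leaves_no_unique_variance(self, rng):
        rec = _random_records(rng)
        rec["transition_rate_1"] = -0.1 * rec.cvr1 + 0.01
        with pytest.raises(ValueError):
            # orthogonalized term is (numerically) constant -> unfittable
            ck.fit_model2(rec)

    def test_outcome_orthogonalization_variant_runs(self, rng):
        rec = _random_records(rng, planted_beta=-2.0)
        res = ck.fit_model2(rec, orthogonalize_against="cvr2")
        assert res.model_id == "model2"


class TestBonferroni:
    def test_threshold_inclusive_at_0_0125(self):
        flags = ck.bonferroni_flag([0.0125, 0.013, 0.001])
        np.testing.assert_array_equal(flags, [True, False, True])

    def test_threshold_computed_from_m(self):
        assert ck.bonferroni_flag([0.011], m=5)[0] == False  # 0.05/5 = 0.01
        assert ck.bonferroni_flag([0.009], m=5)[0] == True

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            ck.bonferroni_flag([1.2])


class TestCorrelationMatrix:
    def test_perfect_linear_relation(self, rng):
        x = rng.normal(size=30)
        rec = pd.DataFrame({
            "transition_rate_1": x, "cvr1": 2 * x + 1,
            "cvr2": rng.normal(size=30), "cope_cvr": rng.normal(size=30),
        })
        corr = ck.correlation_matrix(rec)
        assert corr.loc["transition_rate_1", "cvr1"] == pytest.approx(1.0)

    def test_symmetric_with_unit_diagonal(self, rng):
        rec = ck.cohort_records(ck.synthesize_cohort(n_subjects=20, seed=9),
                                compute_cope=True)
        corr = ck.correlation_matrix(rec)
        np.testing.assert_allclose(corr.values, corr.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(corr.values), 1.0)

    def test_independent_columns_near_zero(self, rng):
        n = 4000
        rec = pd.DataFrame({
            "transition_rate_1": rng.normal(size=n), "cvr1": rng.normal(size=n),
            "cvr2": rng.normal(size=n), "cope_cvr": rng.normal(size=n),
        })
        off = ck.correlation_matrix(rec).values[np.triu_indices(4, k=1)]
        assert np.abs(off).max() < 0.06

    def test_missing_column_errors(self, rng):
        rec = pd.DataFrame({"cvr1": rng.normal(size=10)})
        with pytest.raises(ValueError, match="missing"):
            ck.correlation_matrix(rec)
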