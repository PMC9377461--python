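import numpy as np
import pandas as pd
import pytest

from fallstay import (
    CohortConfig,
    MatchedPairs,
    balance_report,
    estimate_atet,
    fit_propensity,
    generate_cohort,
    match_nn_replacement,
    pooled_matched_analysis,
    standardized_difference,
    standardized_difference_from_moments,
)


class TestFitPropensity:
    def test_null_model_auc_near_half(self, rng):
        x = pd.DataFrame(rng.normal(size=(8000, 5)), columns=list("abcde"))
        y = rng.integers(0, 2, size=8000)
        fit = fit_propensity(x, y)
        assert fit.in_sample_auc == pytest.approx(0.5, abs=0.03)

    def test_single_strong_covariate_separates(self, rng):
        x = rng.normal(size=(4000, 1))
        lp = 4.0 * x[:, 0]
        y = (rng.uniform(size=4000) < 1 / (1 + np.exp(-lp))).astype(int)
        fit = fit_propensity(x, y)
        assert fit.in_sample_auc > 0.9

    def test_coefficients_recovered_within_two_se(self, rng):
        """MLE consistency on a correctly specified logistic model."""
        n = 20_000
        x = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
        beta = np.array([0.8, -0.5, 0.3])
        lp = -2.0 + x.to_numpy() @ beta
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-lp))).astype(int)
        fit = fit_propensity(x, y)
        import statsmodels.api as sm

        res = sm.Logit(y, sm.add_constant(x.to_numpy())).fit(disp=0)
        se = res.bse
        est = fit.coefficients.to_numpy()
        truth = np.concatenate([[-2.0], beta])
        assert np.all(np.abs(est - truth) < 2.0 * se)

    def test_missing_cells_rejected(self):
        x = pd.DataFrame({"a": [1.0, np.nan, 2.0], "b": [0.0, 1.0, 0.0]})
        with pytest.raises(ValueError, match="missing"):
            fit_propensity(x, [0, 1, 1])

    def test_rank_deficiency_names_columns(self, rng):
        x = pd.DataFrame(rng.normal(size=(200, 2)), columns=["a", "b"])
        x["dup"] = x["a"]
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_propensity(x, rng.integers(0, 2, size=200))

    def test_single_class_rejected(self, rng):
        x = pd.DataFrame(rng.normal(size=(50, 2)))
        with pytest.raises(ValueError):
            fit_propensity(x, np.zeros(50))


def _oracle_match(scores, treatment):
    """Exhaustive nearest-neighbor search with the lowest-id tie rule."""
    pairs = []
    controls = [i for i, t in enumerate(treatment) if t == 0]
    for i, t in enumerate(treatment):
        if t != 1:
            continue
        best = min(controls, key=lambda j: (abs(scores[j] - scores[i]), j))
        pairs.append((i, best))
    return pairs


class TestMatching:
    def test_nearest_control_selected(self):
        scores = np.array([0.30, 0.10, 0.28, 0.90])
        pairs = match_nn_replacement(scores, [1, 0, 0, 0])
        assert list(zip(pairs.treated, pairs.control)) == [(0, 2)]

    def test_replacement_reuses_single_control(self):
        scores = np.array([0.5, 0.5, 0.31])
        pairs = match_nn_replacement(scores, [1, 1, 0])
        assert list(pairs.control) == [2, 2]

    def test_equidistant_tie_goes_to_lower_id(self):
        # exactly representable scores so the two distances are equal
        scores = np.array([0.5, 0.25, 0.75])
        pairs = match_nn_replacement(scores, [1, 0, 0])
        assert list(pairs.control) == [1]
        # after swapping the controls the lower id (now the 0.75 control) wins
        scores2 = np.array([0.5, 0.75, 0.25])
        pairs2 = match_nn_replacement(scores2, [1, 0, 0])
        assert list(pairs2.control) == [1]

    def test_agrees_with_exhaustive_oracle_on_small_inputs(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 13))
            treatment = rng.integers(0, 2, size=n)
            if treatment.min() == 1:
                treatment[0] = 0
            scores = np.round(rng.uniform(size=n), 2)  # rounding forces ties
            pairs = match_nn_replacement(scores, treatment)
            assert list(zip(pairs.treated, pairs.control)) == _oracle_match(
                scores, treatment
            )

    def test_idempotent(self, rng):
        scores = rng.uniform(size=500)
        treatment = rng.integers(0, 2, size=500)
        a = match_nn_replacement(scores, treatment)
        b = match_nn_replacement(scores, treatment)
        assert np.array_equal(a.treated, b.treated)
        assert np.array_equal(a.control, b.control)

    def test_caliper_drops_distant_treated(self):
        scores = np.array([0.9, 0.1, 0.11])
        pairs = match_nn_replacement(scores, [1, 0, 0], caliper=0.05)
        assert pairs.n_pairs == 0

    def test_no_controls_rejected(self):
        with pytest.raises(ValueError):
            match_nn_replacement(np.array([0.5]), [1])


class TestStandardizedDifference:
    def test_identical_samples_zero(self, rng):
        x = rng.normal(size=50)
        assert standardized_difference(x, x) == 0.0

    def test_published_age_moments(self):
        d = standardized_difference_from_moments(76.5, 6.8, 74.3, 6.4)
        assert round(d, 2) == 0.33

    def test_published_binary_rates(self):
        d = standardized_difference_from_moments(
            0.406, np.sqrt(0.406 * 0.594), 0.438, np.sqrt(0.438 * 0.562)
        )
        assert round(d, 2) == -0.06

    def test_degenerate_unequal_constants_rejected(self):
        with pytest.raises(ValueError):
            standardized_difference([1.0, 1.0], [2.0, 2.0])


class TestAtet:
    def test_point_is_mean_pair_difference(self, rng):
        outcomes = rng.uniform(1, 30, size=40)
        pairs = MatchedPairs(treated=np.arange(10), control=rng.integers(10, 40, 10))
        est = estimate_atet(pairs, outcomes, n_boot=50, seed=1)
        expected = outcomes[pairs.treated].mean() - outcomes[pairs.control].mean()
        assert est.point == pytest.approx(expected, abs=1e-12)

    def test_constant_differences_give_degenerate_ci(self):
        outcomes = np.array([13.0, 14.0, 15.0, 3.0, 4.0, 5.0])
        pairs = MatchedPairs(treated=[0, 1, 2], control=[3, 4, 5])
        est = estimate_atet(pairs, outcomes, n_boot=200, seed=2)
        assert est.point == 10.0
        assert est.ci_low == pytest.approx(10.0)
        assert est.ci_high == pytest.approx(10.0)

    def test_published_group_means_recover_point(self):
        # treated mean 30.3 vs matched-control mean 12.5 -> 17.8 days
        outcomes = np.array([30.3, 30.3, 12.5, 12.5])
        pairs = MatchedPairs(treated=[0, 1], control=[2, 3])
        est = estimate_atet(pairs, outcomes, n_boot=10, seed=3)
        assert est.point == pytest.approx(17.8)

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            estimate_atet(MatchedPairs(treated=[], control=[]), np.array([1.0]))


class TestBalance:
    def test_random_assignment_balanced_before_matching(self, rng):
        x = pd.DataFrame(rng.normal(size=(20_000, 4)), columns=list("abcd"))
        treatment = rng.integers(0, 2, size=20_000)
        pairs = match_nn_replacement(rng.uniform(size=20_000), treatment)
        report = balance_report(x, treatment, pairs)
        assert report["std_diff_before"].abs().max() < 0.05

    def test_matching_reduces_confounded_imbalance(self, midsize_cohort):
        c = midsize_cohort
        fit = fit_propensity(c.covariates, c.fall)
        pairs = match_nn_replacement(fit.scores, c.fall)
        report = balance_report(c.covariates, c.fall, pairs)
        assert (
            report["std_diff_after"].abs().max()
            < report["std_diff_before"].abs().max()
        )


def test_pooled_analysis_averages_over_imputations(midsize_cohort):
    c = midsize_cohort
    result = pooled_matched_analysis(
        [c.covariates, c.covariates], c.fall, c.los, n_boot=50, seed=9
    )
    per = result["per_imputation_atet"]
    assert result["atet"].point == pytest.approx(
        np.mean([a.point for a in per]), abs=1e-12
    )
    assert len(result["pairs"]) == 2
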