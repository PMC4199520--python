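"""Metrics, intervals, the LOO harness and its nesting guarantee."""

import numpy as np
import pytest
from scipy import stats

from faimsvoc import (
    PipelineConfig,
    SyntheticConfig,
    auc_confidence_interval,
    auc_score,
    binomial_ci,
    choose_threshold,
    correlate_probability,
    evaluate,
    generate_cohort,
    rank_sum_test,
    report,
    roc_points,
    run_loo_cv,
    sensitivity_specificity,
    trapezoidal_auc,
)
from faimsvoc.evaluation import CvPrediction, fold_selected_features

from conftest import SMALL_GRID


def preds(cd_probs, ibs_probs):
    out = [CvPrediction(f"C{i}", "CD", p) for i, p in enumerate(cd_probs)]
    out += [CvPrediction(f"I{i}", "D-IBS", p) for i, p in enumerate(ibs_probs)]
    return out


TOY = preds([0.9, 0.6], [0.7, 0.2])   # 4 case/control pairs, 3 correctly ordered


class TestAuc:
    def test_perfect_separation(self):
        assert auc_score(preds([0.8, 0.9], [0.1, 0.2])) == 1.0

    def test_all_equal_probabilities_give_half(self):
        assert auc_score(preds([0.5, 0.5], [0.5, 0.5])) == 0.5

    def test_toy_set_enumerates_to_three_quarters(self):
        assert auc_score(TOY) == pytest.approx(3 / 4)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            auc_score([CvPrediction("a", "CD", 0.5)])

    def test_equals_rank_sum_u_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            cd = rng.uniform(size=rng.integers(2, 8))
            ibs = rng.uniform(size=rng.integers(2, 8))
            u, _ = rank_sum_test(cd, ibs)
            assert auc_score(preds(cd, ibs)) == pytest.approx(u / (cd.size * ibs.size))


class TestRocPoints:
    def test_starts_and_ends_at_corners_monotone(self):
        pts = roc_points(TOY)
        assert pts[0][:2] == (0.0, 0.0) and pts[-1][:2] == (1.0, 1.0)
        fpr = [p[0] for p in pts]
        tpr = [p[1] for p in pts]
        assert all(np.diff(fpr) >= 0) and all(np.diff(tpr) >= 0)

    def test_perfect_classifier_passes_through_0_1(self):
        pts = roc_points(preds([0.9, 0.8], [0.2, 0.1]))
        assert (0.0, 1.0) in [p[:2] for p in pts]

    def test_trapezoidal_area_equals_auc(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            p = preds(rng.uniform(size=5), rng.uniform(size=4))
            assert abs(trapezoidal_auc(roc_points(p)) - auc_score(p)) < 1e-12

    def test_toy_staircase_hand_enumerated(self):
        # descending scores: 0.9(CD) 0.7(IBS) 0.6(CD) 0.2(IBS)
        assert [p[:2] for p in roc_points(TOY)] == [
            (0.0, 0.0), (0.0, 0.5), (0.5, 0.5), (0.5, 1.0), (1.0, 1.0)]


class TestChooseThreshold:
    def test_perfect_classifier_sens_spec_one(self):
        t, sens, spec = choose_threshold(preds([0.9, 0.8], [0.2, 0.1]))
        assert sens == spec == 1.0

    def test_toy_optimum_threshold(self):
        t, sens, spec = choose_threshold(TOY)
        assert t == pytest.approx(0.6)
        assert sens == 1.0 and spec == 0.5

    def test_all_equal_probabilities_return_smallest(self):
        t, sens, spec = choose_threshold(preds([0.4, 0.4], [0.4, 0.4]))
        assert t == 0.4
        assert sens + spec - 1 == pytest.approx(0.0)

    def test_ties_break_to_smaller_threshold(self):
        # thresholds 0.6 and 0.9 both reach J = 0.5; 0.6 must win
        t, _, _ = choose_threshold(TOY)
        assert t < 0.9


class TestBinomialCi:
    def test_reconstructs_reported_sensitivity_interval(self):
        lo, hi = binomial_ci(23, 27, 0.95)
        assert (round(lo, 2), round(hi, 2)) == (0.66, 0.96)

    def test_reconstructs_reported_specificity_interval(self):
        lo, hi = binomial_ci(17, 20, 0.95)
        assert (round(lo, 2), round(hi, 2)) == (0.62, 0.97)

    def test_all_successes_closed_form(self):
        for n in (5, 20, 27):
            lo, hi = binomial_ci(n, n, 0.95)
            assert hi == 1.0
            assert lo == pytest.approx(0.025 ** (1 / n))

    def test_zero_successes_lower_bound_zero(self):
        lo, hi = binomial_ci(0, 10)
        assert lo == 0.0 and 0 < hi < 1

    def test_matches_statsmodels_beta_method(self):
        from statsmodels.stats.proportion import proportion_confint
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(1, 60))
            k = int(rng.integers(0, n + 1))
            lo, hi = binomial_ci(k, n)
            slo, shi = proportion_confint(k, n, alpha=0.05, method="beta")
            assert lo == pytest.approx(0.0 if k == 0 else slo, abs=1e-10)
            assert hi == pytest.approx(1.0 if k == n else shi, abs=1e-10)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            binomial_ci(5, 4)


class TestAucCi:
    def test_deterministic_per_seed(self):
        p = preds(np.linspace(0.4, 0.9, 10), np.linspace(0.1, 0.6, 8))
        assert auc_confidence_interval(p, seed=7) == auc_confidence_interval(p, seed=7)

    def test_wide_perfect_separation_hits_upper_one(self):
        p = preds(np.linspace(0.8, 0.99, 10), np.linspace(0.01, 0.2, 10))
        lo, hi = auc_confidence_interval(p, reps=200, seed=0)
        assert hi == 1.0 and lo > 0.8

    def test_interval_brackets_estimate(self):
        rng = np.random.default_rng(3)
        p = preds(rng.uniform(0.3, 1, 12), rng.uniform(0, 0.7, 10))
        lo, hi = auc_confidence_interval(p, reps=500, seed=1)
        assert lo <= auc_score(p) <= hi

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError):
            auc_confidence_interval(TOY, reps=10)


class TestCoverage:
    def test_bootstrap_interval_covers_known_auc(self):
        """Coverage of the 95% stratified bootstrap interval over cohorts of
        probability scores whose population AUC is known by construction."""
        rng = np.random.default_rng(4)
        mu = 1.2
        # closed form for binormal scores: AUC = Phi(mu / sqrt(2))
        true_auc = float(stats.norm.cdf(mu / np.sqrt(2)))
        covered = 0
        runs = 200
        for _ in range(runs):
            cd = stats.norm.cdf(rng.normal(mu, 1, 27))
            ibs = stats.norm.cdf(rng.normal(0, 1, 20))
            lo, hi = auc_confidence_interval(preds(cd, ibs), reps=300,
                                             seed=int(rng.integers(2**31)))
            covered += lo <= true_auc <= hi
        assert 0.90 * runs <= covered <= 0.99 * runs


class TestCorrelation:
    def test_identity_and_negation(self):
        p = preds([0.1, 0.5, 0.9], [])[:3]
        probs = [x.prob_cd for x in p]
        assert correlate_probability(p, probs) == pytest.approx(1.0)
        assert correlate_probability(p, [-v for v in probs]) == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        p = [CvPrediction("a", "CD", 0.1), CvPrediction("b", "CD", 0.2),
             CvPrediction("c", "CD", 0.3)]
        # probabilities (1,2,3)/10 against covariate (2,1,3): r = 0.5
        assert correlate_probability(p, [2.0, 1.0, 3.0]) == pytest.approx(0.5)

    def test_outlier_exclusion_rule(self):
        p = preds([0.2, 0.4, 0.6, 0.8], [])[:4]
        r_all = correlate_probability(p, [1, 2, 3, 100])
        r_exc = correlate_probability(p, [1, 2, 3, 100], exclude_above=60)
        assert r_exc == pytest.approx(1.0) and r_all != pytest.approx(1.0)

    def test_constant_covariate_flagged(self):
        p = preds([0.2, 0.4, 0.6], [])[:3]
        with pytest.raises(ValueError, match="constant"):
            correlate_probability(p, [1.0, 1.0, 1.0])


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(SyntheticConfig(n_cd=8, n_ibs=8, seed=21, **SMALL_GRID))


@pytest.fixture(scope="module")
def run(cohort):
    out = run_loo_cv(cohort, PipelineConfig())
    return cohort, out, report(out, cohort, PipelineConfig())


class TestLooHarness:
    def test_one_prediction_per_patient(self, cohort):
        out = run_loo_cv(cohort, PipelineConfig())
        assert [p.patient_id for p in out] == [s.patient_id for s in cohort]
        assert all(0 <= p.prob_cd <= 1 for p in out)

    def test_too_few_patients_per_class_rejected(self, cohort):
        with pytest.raises(ValueError):
            run_loo_cv(cohort[:3], PipelineConfig())

    def test_planted_signal_recovered(self, cohort):
        out = run_loo_cv(cohort, PipelineConfig())
        assert auc_score(out) > 0.8

    def test_nesting_leakage_sentinel(self, cohort):
        """Perturbing the held-out patient's matrices must not change which
        features that fold selects."""
        pipeline = PipelineConfig()
        rng = np.random.default_rng(0)
        for fold in rng.choice(len(cohort), size=3, replace=False):
            before = fold_selected_features(cohort, pipeline, int(fold))
            import copy
            mutated = copy.deepcopy(cohort)
            for rep in mutated[fold].replicates:
                rep.positive.current += rng.normal(0, 50, rep.positive.current.shape)
                rep.negative.current += rng.normal(0, 50, rep.negative.current.shape)
            after = fold_selected_features(mutated, pipeline, int(fold))
            assert set(before) == set(after)

    def test_evaluate_intervals_bracket_estimates(self, cohort):
        out = run_loo_cv(cohort, PipelineConfig())
        res = evaluate(out, ci_reps=300)
        assert res.auc_ci[0] <= res.auc <= res.auc_ci[1]
        assert res.sensitivity_ci[0] <= res.sensitivity <= res.sensitivity_ci[1]
        assert res.specificity_ci[0] <= res.specificity <= res.specificity_ci[1]
        sens, spec = sensitivity_specificity(out, res.threshold)
        assert (sens, spec) == (res.sensitivity, res.specificity)


class TestReport:
    def test_heatmap_has_one_row_per_sample_cd_first(self, run):
        cohort, _, bundle = run
        hm = bundle["heatmap"]
        assert hm.shape[0] == len(cohort)
        assert all(pid.startswith("CD") for pid in hm.index[:8])

    def test_crosstab_bins_match_reporting_convention(self, run):
        _, _, bundle = run
        assert list(bundle["crosstab"].columns) == [
            "0-0.2", "0.2-0.4", "0.4-0.6", "0.6-0.8", "0.8-1"]
        assert bundle["crosstab"].to_numpy().sum() == 8  # CD patients only

    def test_probabilities_in_one_bin_concentrate_mass(self):
        p = [CvPrediction(f"P{i}", "CD", 0.95) for i in range(5)]
        from faimsvoc.evaluation import probability_marsh_crosstab
        from conftest import make_sample
        cohort = [make_sample(f"P{i}", "CD", [np.ones((2, 2))], marsh="IIIa")
                  for i in range(5)]
        tab = probability_marsh_crosstab(p, cohort)
        assert tab["0.8-1"].sum() == 5 and tab.to_numpy().sum() == 5

    def test_group_summary_whiskers_truncated(self, run):
        _, _, bundle = run
        gs = bundle["group_summary"]
        for _, row in gs.iterrows():
            iqr = row["q3"] - row["q1"]
            assert row["whisker_low"] >= row["q1"] - 2 * iqr - 1e-12
            assert row["whisker_high"] <= row["q3"] + 2 * iqr + 1e-12
            assert row["whisker_low"] <= row["median"] <= row["whisker_high"]
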