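"""Tests for the cohort simulator and the model fit."""

import dataclasses
import math

import numpy as np
import pytest

from neutralquery import (
    Counts2x2,
    ExperimentDesign,
    FeedbackParams,
    Knowledge,
    SwitchRule,
    fit_switch_model,
    median_split_by_age,
    paper_designs,
    predicted_switch_probability,
    simulate_cohort,
    summarize_switching,
)
from neutralquery.exceptions import (
    DegenerateSplitError,
    EmptySummaryError,
    ParameterError,
)
from neutralquery.simulator import (
    TrialRecord,
    frame_to_records,
    read_records_csv,
    records_to_frame,
    write_records_csv,
)

from _oracles import grid_fit_lambda

K, I = Knowledge.KNOWLEDGEABLE, Knowledge.IGNORANT


def _big(design: ExperimentDesign, n: int) -> ExperimentDesign:
    return dataclasses.replace(design, n_per_condition=n)


def _switch_rate(records, condition, kind="test"):
    sub = [r for r in records if r.condition is condition and r.trial_kind == kind]
    return sum(r.switched for r in sub) / len(sub)


class TestSimulateCohort:
    def test_deterministic_given_seed(self, empirical_params, matching_rule):
        design = paper_designs()["exp1"]
        a = simulate_cohort(design, empirical_params, matching_rule, seed=11)
        b = simulate_cohort(design, empirical_params, matching_rule, seed=11)
        c = simulate_cohort(design, empirical_params, matching_rule, seed=12)
        assert a == b
        assert a != c

    def test_counter_based_streams_stable_under_growth(self, empirical_params, matching_rule):
        """Enlarging the cohort must not reshuffle earlier children."""
        design = paper_designs()["exp4"]
        small = simulate_cohort(_big(design, 30), empirical_params, matching_rule, seed=5)
        large = simulate_cohort(_big(design, 60), empirical_params, matching_rule, seed=5)
        by_child = {r.child_id: r for r in large}
        assert all(by_child[r.child_id] == r for r in small)

    def test_ignorant_condition_switches_at_chance(self, empirical_params, matching_rule):
        n = 10_000
        records = simulate_cohort(
            _big(paper_designs()["exp4"], n), empirical_params, matching_rule, seed=2
        )
        se = 0.5 / math.sqrt(n)
        assert _switch_rate(records, I) == pytest.approx(0.5, abs=3 * se)

    def test_knowledgeable_condition_matches_closed_form(self, matching_rule):
        params = FeedbackParams(alpha_c=0.92, beta_i=0.65)
        n = 10_000
        records = simulate_cohort(
            _big(paper_designs()["exp4"], n), params, matching_rule, seed=3
        )
        expected = 0.35 / 0.43  # 1 - posterior, probability matching
        se = math.sqrt(expected * (1 - expected) / n)
        assert _switch_rate(records, K) == pytest.approx(expected, abs=3 * se)

    def test_lln_convergence_random_parameter_draws(self, rng, matching_rule):
        """Simulated knowledgeable switch rates converge to the closed-form
        prediction across random feedback parameters (n = 20,000/condition)."""
        design = _big(paper_designs()["exp4"], 20_000)
        for _ in range(5):
            params = FeedbackParams(
                alpha_c=float(0.05 + 0.9 * rng.random()),
                beta_i=float(0.05 + 0.9 * rng.random()),
            )
            records = simulate_cohort(
                design, params, matching_rule, seed=int(rng.integers(2**31))
            )
            expected = predicted_switch_probability(params, K, matching_rule)
            se = math.sqrt(max(expected * (1 - expected), 1e-4) / design.n_per_condition)
            assert _switch_rate(records, K) == pytest.approx(expected, abs=3 * se + 1e-9)

    def test_training_compliance_without_lapse(self, empirical_params, matching_rule):
        """With no lapse, children stay after explicit confirmation and
        switch after explicit correction on every training trial."""
        design = _big(paper_designs()["exp3"], 200)
        records = simulate_cohort(design, empirical_params, matching_rule, seed=7)
        training = [r for r in records if r.trial_kind == "training"]
        assert len(training) == 2 * 2 * 200
        # exp3 delivers one confirmation and one correction per child, so
        # over each child's two training trials exactly one switch occurs
        by_child: dict[str, list] = {}
        for r in training:
            by_child.setdefault(r.child_id, []).append(r.switched)
        assert all(sum(flags) == 1 for flags in by_child.values())

    def test_training_feedback_statement_effects(self, empirical_params, matching_rule):
        design = _big(paper_designs()["exp1"], 300)  # two confirmations
        records = simulate_cohort(design, empirical_params, matching_rule, seed=8)
        training = [r for r in records if r.trial_kind == "training"]
        assert training and not any(r.switched for r in training)

    def test_ages_within_design_range(self, empirical_params, matching_rule):
        design = paper_designs()["exp1"]
        records = simulate_cohort(design, empirical_params, matching_rule, seed=9)
        lo, hi = design.age_range_months
        assert all(lo <= r.age_months <= hi for r in records)

    def test_invalid_design_rejected(self):
        with pytest.raises(ParameterError):
            ExperimentDesign("bad", n_per_condition=0)
        with pytest.raises(ParameterError):
            ExperimentDesign("bad", age_range_months=(70, 48))


class TestSummaries:
    def _records_from_counts(self, k_switch, k_total, i_switch, i_total, experiment="exp1"):
        records = []
        for cond, n_switch, n_total in ((K, k_switch, k_total), (I, i_switch, i_total)):
            for j in range(n_total):
                switched = j < n_switch
                records.append(
                    TrialRecord(
                        child_id=f"{experiment}-{cond.value}-{j:04d}",
                        experiment=experiment,
                        condition=cond,
                        age_months=50 + (j % 20),
                        trial_kind="test",
                        initial_choice="left",
                        final_choice="right" if switched else "left",
                        switched=switched,
                    )
                )
        return records

    def test_counts_match_construction(self):
        records = self._records_from_counts(14, 22, 7, 22)
        table = summarize_switching(records)["exp1"]
        assert (table.a, table.b, table.c, table.d) == (14, 8, 7, 15)

    def test_permutation_invariance(self, rng):
        records = self._records_from_counts(14, 22, 7, 22)
        shuffled = list(records)
        rng.shuffle(shuffled)
        assert summarize_switching(shuffled) == summarize_switching(records)

    def test_all_stayed(self):
        records = self._records_from_counts(0, 10, 0, 10)
        table = summarize_switching(records)["exp1"]
        assert (table.a, table.c) == (0, 0)

    def test_empty_input_rejected(self):
        with pytest.raises(EmptySummaryError):
            summarize_switching([])

    def test_median_split_engineered_counts(self):
        """Records built to carry the pooled marginals produce the published
        age-split table [[55, 57], [38, 74]]."""
        records = []
        specs = [(60, True, 55), (60, False, 57), (50, True, 38), (50, False, 74)]
        i = 0
        for age, switched, n in specs:
            for _ in range(n):
                records.append(
                    TrialRecord(
                        child_id=f"m-{i:04d}", experiment="mega", condition=K,
                        age_months=age, trial_kind="test", initial_choice="left",
                        final_choice="right" if switched else "left", switched=switched,
                    )
                )
                i += 1
        table = median_split_by_age(records)
        assert (table.a, table.b, table.c, table.d) == (55, 57, 38, 74)

    def test_median_split_age_link(self, empirical_params, matching_rule):
        """A positive age slope in the generator yields a higher switch
        proportion in the older half."""
        design = _big(paper_designs()["exp4"], 5000)
        records = simulate_cohort(
            design, empirical_params, matching_rule, seed=4, age_slope=0.08
        )
        table = median_split_by_age(records)
        older = table.a / (table.a + table.b)
        younger = table.c / (table.c + table.d)
        assert older > younger

    def test_median_split_degenerate(self):
        records = [
            TrialRecord(
                child_id=f"x-{i}", experiment="e", condition=K, age_months=60,
                trial_kind="test", initial_choice="left", final_choice="left",
                switched=False,
            )
            for i in range(5)
        ]
        with pytest.raises(DegenerateSplitError):
            median_split_by_age(records)


class TestFit:
    def test_saturates_knowledgeable_arm(self, matching_rule):
        """At the MLE the fitted knowledgeable switch probability equals the
        observed proportion (62/112 on the pooled counts)."""
        result = fit_switch_model(Counts2x2(62, 50, 31, 81), matching_rule)
        assert result.identifiable
        fitted_p = 1.0 / (1.0 + result.lambda_hat)
        assert fitted_p == pytest.approx(62 / 112, abs=1e-9)
        assert result.loglik <= 0.0

    def test_ignorant_only_counts_not_identifiable(self, matching_rule):
        result = fit_switch_model(Counts2x2(0, 0, 31, 81), matching_rule)
        assert not result.identifiable
        assert math.isnan(result.lambda_hat)

    def test_profile_interval_and_grid_oracle(self, empirical_params):
        """On a large simulated cohort the profile interval covers the true
        ratio and the MLE agrees with a dense grid search."""
        rule = SwitchRule(kind="probability_matching", lapse=0.1)
        true_lambda = 0.08 / 0.35
        design = _big(paper_designs()["exp4"], 2000)
        records = simulate_cohort(design, empirical_params, rule, seed=21)
        counts = summarize_switching(records)["exp4"]
        result = fit_switch_model(counts, rule)
        lo, hi = result.lambda_ci
        assert lo < true_lambda < hi
        oracle = grid_fit_lambda(counts.a, counts.a + counts.b, lapse=0.1)
        assert result.lambda_hat == pytest.approx(oracle, rel=5e-3)

    def test_recovery_short(self, empirical_params):
        """Quick recovery check: across 20 cohorts the median estimate sits
        near the generating ratio (the full-size check lives with the
        acceptance suite)."""
        rule = SwitchRule(kind="probability_matching", lapse=0.1)
        true_lambda = 0.08 / 0.35
        design = _big(paper_designs()["exp4"], 500)
        estimates = []
        for seed in range(20):
            records = simulate_cohort(design, empirical_params, rule, seed=seed)
            counts = summarize_switching(records)["exp4"]
            estimates.append(fit_switch_model(counts, rule).lambda_hat)
        assert np.median(estimates) == pytest.approx(true_lambda, rel=0.15)

    def test_requires_matching_rule(self):
        with pytest.raises(ParameterError):
            fit_switch_model(Counts2x2(10, 10, 10, 10), SwitchRule(kind="maximize"))


class TestCsvRoundTrip:
    def test_round_trip(self, tmp_path, empirical_params, matching_rule):
        records = simulate_cohort(
            paper_designs()["exp2"], empirical_params, matching_rule, seed=13
        )
        path = tmp_path / "records.csv"
        write_records_csv(records, path)
        assert read_records_csv(path) == records

    def test_frame_columns(self, empirical_params, matching_rule):
        records = simulate_cohort(
            paper_designs()["exp4"], empirical_params, matching_rule, seed=14
        )
        frame = records_to_frame(records)
        assert list(frame.columns) == [
            "child_id", "experiment", "condition", "age_months",
            "trial_kind", "initial_choice", "final_choice", "switched",
        ]
        assert frame_to_records(frame) == records
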