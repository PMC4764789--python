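"""Outcome statistics: t tests, responder chi-square, stratified/sensitivity
analyses, engagement metrics."""

import dataclasses
import datetime as dt
import itertools

import numpy as np
import pytest

from stepshape.outcomes import (
    change_scores,
    engagement_summary,
    pearson_chi_square_2x2,
    primary_analysis,
    responder_analysis,
    sensitivity_all_available,
    stratified_analysis,
    t_test_two_sample,
)
from stepshape.goals import GoalDecision
from stepshape.trial import apply_follow_up, apply_run_in

from conftest import START, build_dataset, make_week


class TestTTest:
    def test_identical_arms_are_degenerate_but_defined(self):
        r = t_test_two_sample([5000, 5000, 5000], [5000, 5000, 5000])
        assert r.t_statistic == 0.0 and r.p_value == 1.0

    def test_welch_matches_hand_computed_oracle(self):
        # frozen from an independent closed-form computation
        a = [4800, 5200, 5100, 4900, 5000]
        b = [5500, 6100, 5900, 5600, 5400]
        r = t_test_two_sample(a, b)
        assert r.t_statistic == pytest.approx(4.719399, abs=1e-5)
        assert r.degrees_of_freedom == pytest.approx(6.165605, abs=1e-5)
        assert r.p_value == pytest.approx(0.00303293, rel=1e-4)
        assert r.difference == pytest.approx(700.0)

    def test_pooled_matches_hand_computed_oracle(self):
        a = [4800, 5200, 5100, 4900, 5000]
        b = [5500, 6100, 5900, 5600, 5400]
        r = t_test_two_sample(a, b, method="pooled")
        assert r.t_statistic == pytest.approx(4.719399, abs=1e-5)
        assert r.degrees_of_freedom == 8
        assert r.p_value == pytest.approx(0.00150333, rel=1e-4)

    def test_summary_and_raw_entry_points_agree(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0, 1500, size=40)
        b = rng.normal(400, 1700, size=35)
        raw = t_test_two_sample(a, b)
        summ = t_test_two_sample(
            summary_a=(len(a), float(a.mean()), float(a.std(ddof=1))),
            summary_b=(len(b), float(b.mean()), float(b.std(ddof=1))),
        )
        assert raw.t_statistic == pytest.approx(summ.t_statistic)
        assert raw.p_value == pytest.approx(summ.p_value)

    def test_sign_convention_follows_difference(self):
        r = t_test_two_sample([10, 20, 30], [1, 2, 3])
        assert r.difference < 0 and r.t_statistic < 0

    def test_printed_arm_summaries_reject_below_point_001(self):
        r = t_test_two_sample(
            summary_a=(110, -661.0, 1824.0), summary_b=(107, 309.0, 1874.0)
        )
        assert r.difference == pytest.approx(970.0)
        assert r.p_value < 0.001

    def test_tiny_arms_rejected(self):
        with pytest.raises(ValueError):
            t_test_two_sample([1.0], [2.0, 3.0])


class TestChiSquare:
    def test_matches_brute_force_on_exhaustive_small_tables(self):
        for a, b, c, d in itertools.product(range(6), repeat=4):
            chi2, p = pearson_chi_square_2x2(a, b, c, d)
            n = a + b + c + d
            if n == 0 or (a + b) * (c + d) * (a + c) * (b + d) == 0:
                assert (chi2, p) == (0.0, 1.0)
                continue
            # brute force: sum (O - E)^2 / E over the four cells
            obs = np.array([[a, b], [c, d]], dtype=float)
            rows, cols = obs.sum(axis=1), obs.sum(axis=0)
            exp = np.outer(rows, cols) / n
            assert chi2 == pytest.approx(((obs - exp) ** 2 / exp).sum())

    def test_perfect_separation_table(self):
        chi2, _ = pearson_chi_square_2x2(10, 0, 0, 10)
        assert chi2 == pytest.approx(20.0)


class TestResponder:
    def test_printed_counts_give_printed_proportions_and_p(self):
        # 18/110 control vs 32/107 intervention responders
        ctrl = [1500.0] * 18 + [0.0] * 92
        interv = [1200.0] * 32 + [-300.0] * 75
        r = responder_analysis(ctrl, interv)
        assert r.proportion_control == pytest.approx(18 / 110)
        assert r.proportion_intervention == pytest.approx(32 / 107)
        assert r.chi_square == pytest.approx(5.6101, abs=1e-3)
        assert round(r.p_value, 3) == 0.018

    def test_threshold_is_inclusive(self):
        r = responder_analysis([999.9, 1000.0], [1000.0, 1000.1])
        assert r.responders_control == 1 and r.responders_intervention == 2

    def test_identical_arms_give_null_result(self):
        r = responder_analysis([0.0, 0.0], [0.0, 0.0])
        assert r.chi_square == 0.0 and r.p_value == 1.0

    def test_invariant_to_nonresponder_magnitudes(self):
        a = responder_analysis([500.0, 2000.0], [100.0, 1500.0])
        b = responder_analysis([-9000.0, 2000.0], [999.0, 1500.0])
        assert (a.chi_square, a.p_value) == (b.chi_square, b.p_value)

    def test_empty_arm_is_an_error(self):
        with pytest.raises(ValueError):
            responder_analysis([], [1000.0])


class TestDatasetAnalyses:
    def test_change_scores_arithmetic(self, two_arm_dataset):
        scores = change_scores(two_arm_dataset).set_index("participant_id")
        assert scores.loc["C1", "change"] == pytest.approx(-400)
        assert scores.loc["I1", "change"] == pytest.approx(1000)
        assert scores["included"].all()

    def test_primary_difference_matches_means(self, two_arm_dataset):
        r = primary_analysis(two_arm_dataset)
        assert r.mean_control == pytest.approx(-400)
        assert r.mean_intervention == pytest.approx(750)
        assert r.difference == pytest.approx(1150)

    def test_participant_missing_followup_is_excluded_but_kept_for_sensitivity(
        self, protocol
    ):
        fu_start = protocol.date_of(protocol.run_in_days + protocol.treatment_days)
        blocks = {}
        for pid, arm in (("C1", "control"), ("C2", "control"),
                         ("I1", "intervention"), ("I2", "intervention")):
            blocks[pid] = {
                "run_in": make_week(pid, "run_in", START, [5000] * 7),
                "follow_up": make_week(pid, "follow_up", fu_start, [6000] * 7),
            }
        # I2 only manages 2 valid follow-up days (fails the 4-day criterion)
        blocks["I2"]["follow_up"] = make_week(
            "I2", "follow_up", fu_start, [7000] * 7,
            wear=[14, 14, 3, 3, 3, 3, 3],
        )
        ds = build_dataset(blocks, protocol)
        apply_run_in(ds)
        arms = {"C1": "control", "C2": "control",
                "I1": "intervention", "I2": "intervention"}
        for p in ds.participants:
            p.arm = arms[p.participant_id]
        apply_follow_up(ds)

        scores = change_scores(ds).set_index("participant_id")
        assert not scores.loc["I2", "included"]
        sens = sensitivity_all_available(ds)
        assert sens.n_intervention == 2  # I2 re-enters with its 2 valid days
        assert sens.n_control == 2

    def test_stratified_excludes_active_and_splits_by_stratum(self, protocol):
        fu_start = protocol.date_of(protocol.run_in_days + protocol.treatment_days)
        arm_setup = {
            # sedentary pair per arm, low pair per arm, one active pair
            "S1": (4000, 4100, "control", ), "S2": (4000, 4300, "intervention"),
            "S3": (4400, 4400, "control"), "S4": (4400, 4900, "intervention"),
            "L1": (7000, 6500, "control"), "L2": (7000, 7300, "intervention"),
            "L3": (6400, 6000, "control"), "L4": (6400, 6800, "intervention"),
            "A1": (12000, 11000, "control"), "A2": (12000, 12500, "intervention"),
        }
        blocks = {
            pid: {
                "run_in": make_week(pid, "run_in", START, [v[0]] * 7),
                "follow_up": make_week(pid, "follow_up", fu_start, [v[1]] * 7),
            }
            for pid, v in arm_setup.items()
        }
        ds = build_dataset(blocks, protocol)
        apply_run_in(ds)
        for p in ds.participants:
            p.arm = arm_setup[p.participant_id][2]
        apply_follow_up(ds)

        strat = stratified_analysis(ds)
        assert set(strat) == {"sedentary", "low_to_somewhat"}
        sed = strat["sedentary"]
        assert sed.n_control == 2 and sed.n_intervention == 2
        assert sed.mean_control == pytest.approx(50)       # (100 + 0) / 2
        assert sed.mean_intervention == pytest.approx(400)  # (300 + 500) / 2
        low = strat["low_to_somewhat"]
        assert low.mean_control == pytest.approx(-450)

    def test_engagement_counts_worn_and_completed_days(self, protocol):
        t_start = protocol.date_of(protocol.run_in_days)
        fu_start = protocol.date_of(protocol.run_in_days + protocol.treatment_days)
        steps = [100, 101, 5000, 0] + [6000] * 38  # day 1: exactly 100 -> not worn
        blocks = {
            "I1": {
                "run_in": make_week("I1", "run_in", START, [5000] * 7),
                "treatment": [
                    r for i in range(6)
                    for r in make_week(
                        "I1", "treatment",
                        t_start + dt.timedelta(days=7 * i),
                        steps[7 * i : 7 * i + 7],
                    )
                ],
                "follow_up": make_week("I1", "follow_up", fu_start, [6000] * 7),
            }
        }
        ds = build_dataset(blocks, protocol)
        apply_run_in(ds)
        ds.participants[0].arm = "intervention"
        apply_follow_up(ds)
        ds.goals["I1"] = [
            GoalDecision(
                date=t_start + dt.timedelta(days=i), window_values=(),
                bound_low=None, bound_high=None, goal=5000,
                random_offset=0.0, compensated=False,
            )
            for i in range(42)
        ]
        eng = engagement_summary(ds)
        row = eng.iloc[0]
        assert row["days_worn"] == 40           # 100-step and 0-step days excluded
        assert row["goals_completed"] == 39     # steps == goal counts (day 2: 5000)
        assert bool(row["active_final_week"])
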