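"""Data treatment: RT/first-trial filters, exclusions, stay coding, Cowan K."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oilab.errors import DataError, EstimationError
from oilab.preprocess import (
    FilterConfig,
    code_stay,
    compute_learning_accuracy,
    cowan_k,
    cowan_k_hit_fa,
    estimate_capacity,
    exclude_participants,
    filter_trials,
    standardize_capacity,
)


def _toy_trial_log(rts_by_trial: dict[int, tuple[float, float]], n_trials=10, subject="S001"):
    """A one-subject, one-block log with planted per-offer RTs."""
    rows = []
    for t in range(1, n_trials + 1):
        rt1, rt2 = rts_by_trial.get(t, (700.0, 800.0))
        for oi, (rt, key) in enumerate([(rt1, "left"), (rt2, "right")], start=1):
            rows.append(
                {
                    "subject_id": subject, "session": 1, "block": 1, "trial": t,
                    "offer_index": oi, "load": "none", "card_left": 0, "card_right": 1,
                    "chosen_card": 0 if key == "left" else 1, "chosen_key": key,
                    "rt_ms": rt, "reward": t % 2, "true_p_left": 0.6, "true_p_right": 0.4,
                }
            )
    return pd.DataFrame(rows)


class TestTrialFilter:
    def test_planted_violations_are_removed_exactly(self):
        log = _toy_trial_log({3: (150.0, 800.0), 7: (700.0, 4500.0)})
        retained, report = filter_trials(log)
        # trial 1 (first of block), 3 (fast offer), 7 (slow offer)
        assert sorted(retained["trial"].unique()) == [2, 4, 5, 6, 8, 9, 10]
        assert report.n_trials_removed == 3
        assert report.removed_fraction_trials == pytest.approx(0.30)

    def test_boundary_rts_are_retained(self):
        log = _toy_trial_log({4: (200.0, 4000.0)})
        retained, _ = filter_trials(log)
        assert 4 in retained["trial"].to_numpy()

    def test_missing_rt_counts_as_invalid(self):
        log = _toy_trial_log({5: (np.nan, 900.0)})
        retained, report = filter_trials(log)
        assert 5 not in retained["trial"].to_numpy()
        assert report.n_trials_removed == 2  # first trial + the NaN trial

    def test_filtering_is_idempotent(self, default_cohort_tables):
        trial_log, _, _ = default_cohort_tables
        once, _ = filter_trials(trial_log)
        twice, report = filter_trials(once)
        # the block's new first trial is its old second trial, already >= min,
        # so a second pass removes the new first-of-block rows only if asked
        cfg = FilterConfig(drop_first_trial_of_block=False)
        again, rep2 = filter_trials(once, cfg)
        assert len(again) == len(once)
        assert rep2.n_trials_removed == 0


class TestParticipantExclusion:
    @staticmethod
    def _probe_log(subject, set4_acc=0.9, n=40):
        n_correct = int(round(set4_acc * n))
        rows = []
        for i in range(n):
            correct = int(i < n_correct)
            same = i % 2
            rows.append(
                {
                    "subject_id": subject, "task": "standalone", "block": 0, "trial": i + 1,
                    "set_size": 4, "load": "none", "probe_same": same,
                    "response_same": same if correct else 1 - same,
                    "correct": correct, "rt_ms": 600.0,
                }
            )
        return pd.DataFrame(rows)

    def test_below_chance_wm_flagged(self):
        log = pd.concat([_toy_trial_log({}), _toy_trial_log({}, subject="S002")])
        probes = pd.concat([self._probe_log("S001", 0.45), self._probe_log("S002", 0.9)])
        report = exclude_participants(log, probes)
        assert report.flags["S001"] == ["wm_below_chance"]
        assert report.flags["S002"] == []

    def test_same_key_share_uses_strict_threshold(self):
        def keylog(subject, n_left, n_total=100):
            rows = []
            for t in range(1, n_total + 1):
                for oi in (1, 2):
                    idx = (t - 1) * 2 + (oi - 1)
                    key = "left" if idx < n_left else "right"
                    rows.append(
                        {
                            "subject_id": subject, "session": 1, "block": 1, "trial": t,
                            "offer_index": oi, "load": "none", "card_left": 0,
                            "card_right": 1, "chosen_card": 0, "chosen_key": key,
                            "rt_ms": 700.0, "reward": 1, "true_p_left": 0.6,
                            "true_p_right": 0.4,
                        }
                    )
            return pd.DataFrame(rows)

        # 198 retained offers after dropping trial 1; left on 81% vs exactly 80%
        at_exact = keylog("S001", n_left=2 + int(0.80 * 198))
        above = keylog("S002", n_left=2 + int(round(0.81 * 198)))
        log = pd.concat([at_exact, above])
        probes = pd.concat([self._probe_log("S001"), self._probe_log("S002")])
        report = exclude_participants(log, probes)
        assert report.flags["S001"] == []
        assert report.flags["S002"] == ["key_repetition"]

    def test_excess_bad_trials_flagged(self):
        bad = {t: (150.0, 700.0) for t in range(2, 6)}  # 4 fast trials + first = 5/10
        log = _toy_trial_log(bad)
        report = exclude_participants(log, self._probe_log("S001"))
        assert "too_many_bad_trials" in report.flags["S001"]

    def test_subject_in_one_log_only_is_an_error(self):
        log = _toy_trial_log({})
        probes = self._probe_log("S999")
        with pytest.raises(DataError, match="S999"):
            exclude_participants(log, probes)

    def test_clean_synthetic_cohort_has_no_exclusions(self):
        from oilab.agents import CohortSpec, simulate_cohort
        from oilab.task_env import TaskConfig

        spec = CohortSpec(n_subjects=12, p_fast=0.0, p_slow=0.0, kappa_mean=3.5, seed=2)
        task = TaskConfig(n_blocks=2, trials_per_block=30, load_schedule=("none", "high"))
        trial_log, probe_log, _ = simulate_cohort(spec, task)
        report = exclude_participants(trial_log, probe_log)
        assert report.excluded_subjects == []


class TestStayCoding:
    def test_hand_coded_examples(self):
        log = _toy_trial_log({})
        log.loc[(log.trial == 2) & (log.offer_index == 1), ["chosen_key", "reward"]] = ["left", 1]
        log.loc[(log.trial == 2) & (log.offer_index == 2), "chosen_key"] = "left"
        log.loc[(log.trial == 3) & (log.offer_index == 1), ["chosen_key", "reward"]] = ["right", 0]
        log.loc[(log.trial == 3) & (log.offer_index == 2), "chosen_key"] = "left"
        stay = code_stay(log)
        row2 = stay[stay.trial == 2].iloc[0]
        row3 = stay[stay.trial == 3].iloc[0]
        assert (row2.stay, row2.prev_outcome) == (1, 1)
        assert (row3.stay, row3.prev_outcome) == (0, 0)

    def test_one_row_per_retained_trial(self, default_cohort_tables):
        trial_log, _, _ = default_cohort_tables
        retained, _ = filter_trials(trial_log)
        stay = code_stay(retained)
        n_complete = (
            retained.groupby(["subject_id", "block", "trial"])["offer_index"]
            .nunique()
            .eq(2)
            .sum()
        )
        assert len(stay) == n_complete

    def test_reward_following_agents_stay_more_after_reward(self):
        from oilab.agents import CohortSpec, simulate_cohort
        from oilab.task_env import TaskConfig

        spec = CohortSpec(
            n_subjects=8, alpha_key_mean=0.6, alpha_key_link=0.0,
            alpha_key_resid_sd=0.0, beta_mean=5.0, beta_sd=0.0, seed=4,
        )
        trial_log, _, _ = simulate_cohort(spec, TaskConfig())
        stay = code_stay(filter_trials(trial_log)[0])
        by = stay.groupby("prev_outcome")["stay"].mean()
        assert by[1] > by[0]


class TestCapacityEstimation:
    def test_perfect_and_chance_accuracy_map_to_extremes(self):
        assert cowan_k(1.0, 4) == 4.0
        assert cowan_k(0.5, 8) == 0.0

    @given(
        st.tuples(
            st.integers(0, 30), st.integers(0, 30), st.integers(min_value=1, max_value=8)
        )
    )
    def test_accuracy_form_equals_hit_minus_false_alarm(self, case):
        # balanced single-probe design: n same probes, n different probes
        n_hit, n_cr, size = case
        n = 30
        hit = n_hit / n          # correct on 'different' (change) probes
        fa = (n - n_cr) / n      # 'different' response on 'same' probes
        acc = (n_hit + n_cr) / (2 * n)
        assert cowan_k(acc, size) == pytest.approx(cowan_k_hit_fa(hit, fa, size))

    def test_standalone_estimates_recover_slot_capacity(self, default_cohort_tables):
        _, probe_log, truth = default_cohort_tables
        est = estimate_capacity(probe_log, source="standalone")
        merged = est.merge(truth, on="subject_id")
        # per-subject K from 120 trials is noisy; the cohort-level
        # association with generative kappa must be strong
        assert np.corrcoef(merged["K"], merged["kappa"])[0, 1] > 0.8

    def test_embedded_estimates_skip_no_load_and_track_capacity(self, default_cohort_tables):
        _, probe_log, truth = default_cohort_tables
        est = estimate_capacity(probe_log, source="embedded")
        merged = est.merge(truth, on="subject_id")
        assert np.corrcoef(merged["K"], merged["kappa"])[0, 1] > 0.5

    def test_missing_condition_is_an_error(self):
        probes = TestParticipantExclusion._probe_log("S001")  # set size 4 only
        with pytest.raises(EstimationError, match="K8"):
            estimate_capacity(probes, source="standalone")


class TestCovariates:
    def test_accuracy_of_greedy_and_random_choosers(self):
        log = _toy_trial_log({})
        log["chosen_card"] = 0
        log["chosen_key"] = "left"  # card 0 always has the higher true p
        retained, _ = filter_trials(log)
        acc = compute_learning_accuracy(retained)
        assert acc["accuracy"].iloc[0] == 1.0

        from oilab.agents import CohortSpec, simulate_cohort
        from oilab.task_env import TaskConfig

        spec = CohortSpec(n_subjects=6, beta_mean=0.0, beta_sd=0.0, seed=8)
        task = TaskConfig(n_blocks=2, trials_per_block=50, load_schedule=("none", "low"))
        trial_log, _, _ = simulate_cohort(spec, task)
        acc = compute_learning_accuracy(filter_trials(trial_log)[0])
        assert abs(acc["accuracy"].mean() - 0.5) < 0.05

    def test_learning_agents_beat_chance(self, default_cohort_tables):
        from scipy.stats import binomtest

        trial_log, _, _ = default_cohort_tables
        acc = compute_learning_accuracy(filter_trials(trial_log)[0])
        pooled_correct = int((acc["accuracy"] * acc["n_offers"]).sum())
        pooled_n = int(acc["n_offers"].sum())
        test = binomtest(pooled_correct, pooled_n, 0.5, alternative="greater")
        assert test.pvalue < 0.01

    def test_two_point_standardization(self):
        est = pd.DataFrame({"subject_id": ["a", "b"], "K": [2.0, 4.0]})
        z = standardize_capacity(est)["K_z"].to_numpy()
        assert z == pytest.approx([-np.sqrt(0.5), np.sqrt(0.5)])

    def test_standardization_invariants(self, default_cohort_tables):
        _, probe_log, _ = default_cohort_tables
        est = estimate_capacity(probe_log)
        z = standardize_capacity(est)["K_z"]
        assert abs(z.mean()) < 1e-12
        shifted = est.assign(K=est["K"] + 10)
        z2 = standardize_capacity(shifted)["K_z"]
        assert np.allclose(z, z2)

    def test_zero_variance_capacity_rejected(self):
        est = pd.DataFrame({"subject_id": ["a", "b"], "K": [2.0, 2.0]})
        with pytest.raises(DataError):
            standardize_capacity(est)
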