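"""Exclusion rules, behavioral statistics, psychometric function."""

import numpy as np
import pandas as pd
import pytest

from valenceddm import behavior, ddm, task


def _participant(pid, n=80, n_samples=5, accuracy=0.75, rt=2.0, rng=None, rt_jitter=True):
    rng = rng or np.random.default_rng(pid)
    acc = (rng.random(n) < accuracy).astype(int)
    true_state = rng.integers(0, 2, n)
    response = np.where(acc == 1, true_state, 1 - true_state)
    rts = rt + (rng.uniform(-0.5, 0.5, n) if rt_jitter else 0.0)
    ns = np.full(n, n_samples)
    return pd.DataFrame(
        {
            "participant_id": pid,
            "trial_index": np.arange(1, n + 1),
            "true_state": true_state,
            "desirability": (true_state == 1).astype(int),
            "items": ["10101"] * n,
            "n_samples": ns,
            "response": response,
            "rt_s": rts,
            "accuracy": acc,
            "evidence": 0.1,
        }
    )


def exclusion_fixture():
    """Participants engineered to trip each exclusion rule exactly once.

    0-5: clean; 6: early responder on 41/80 trials; 7: near-chance accuracy;
    8: metronomic identical RTs plus suspicious metadata (bot).
    """
    frames = [_participant(pid, accuracy=0.70 + 0.02 * pid) for pid in range(6)]
    early = _participant(6, accuracy=0.75)
    early.loc[: 40, "n_samples"] = 1  # 41 of 80 trials answered before item 2
    frames.append(early)
    frames.append(_participant(7, accuracy=0.30))
    bot = _participant(8, accuracy=0.72, rt_jitter=False)  # identical RTs on all trials
    frames.append(bot)
    meta = pd.DataFrame({"suspicious_metadata": [True]}, index=[8])
    return pd.concat(frames, ignore_index=True), meta


class TestExclusions:
    def test_engineered_drop_set_is_exact(self):
        raw, meta = exclusion_fixture()
        clean, report = behavior.apply_exclusions(raw, participant_meta=meta)
        assert sorted(report.dropped_participants) == [
            (6, "early_response_majority"),
            (7, "low_accuracy"),
            (8, "bot"),
        ]
        assert set(clean["participant_id"]) == set(range(6))
        # threshold is the sample mean minus two sample standard deviations
        acc = raw[~raw["participant_id"].isin([6]) & (raw["n_samples"] >= 2)].groupby("participant_id")["accuracy"].mean()
        expected = acc.mean() - 2 * acc.std(ddof=1)
        assert report.accuracy_threshold == pytest.approx(expected)

    def test_majority_early_drops_participant_minority_drops_trials(self):
        raw, _ = exclusion_fixture()
        some_early = _participant(9, accuracy=0.74)
        some_early.loc[:9, "n_samples"] = 1  # 10 of 80 -> trials dropped, participant kept
        raw = pd.concat([raw, some_early], ignore_index=True)
        clean, report = behavior.apply_exclusions(raw)
        assert 9 in set(clean["participant_id"])
        assert report.dropped_trials["early_response"] == 10
        assert len(clean[clean["participant_id"] == 9]) == 70

    def test_clean_data_unscathed_and_idempotent(self, unbiased_task_cohort):
        clean1, rep1 = behavior.apply_exclusions(unbiased_task_cohort)
        clean2, rep2 = behavior.apply_exclusions(clean1)
        pd.testing.assert_frame_equal(clean1, clean2)
        assert rep2.dropped_participants == []

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            behavior.apply_exclusions(pd.DataFrame())


class TestJudgmentStats:
    def test_false_belief_arithmetic(self):
        # participant with 10 of 40 undesirable-state trials judged desirable
        rng = np.random.default_rng(0)
        frames = []
        for pid in range(2):
            n = 80
            true_state = np.repeat([1, 0], 40)
            resp = true_state.copy()
            und = np.where(true_state == 0)[0]
            resp[und[:10]] = 1  # judged TV (desirable) on 10 undesirable trials
            frames.append(pd.DataFrame({
                "participant_id": pid, "trial_index": np.arange(1, n + 1),
                "true_state": true_state, "desirability": (true_state == 1).astype(int),
                "items": ["10101"] * n, "n_samples": 5, "response": resp,
                "rt_s": 2.0 + rng.uniform(0, 1, n),
                "accuracy": (resp == true_state).astype(int), "evidence": 0.1,
            }))
        out = behavior.desirable_judgment_stats(pd.concat(frames, ignore_index=True))
        assert out["false_beliefs"]["fpb_rate"] == pytest.approx(0.25)
        assert out["false_beliefs"]["fnb_rate"] == pytest.approx(0.0)

    def test_unbiased_cohort_null(self, unbiased_task_cohort):
        out = behavior.desirable_judgment_stats(unbiased_task_cohort)
        assert out["judged_vs_encountered"]["p"] > 0.01

    def test_biased_cohort_signatures(self, biased_task_cohort):
        out = behavior.desirable_judgment_stats(biased_task_cohort)
        jv = out["judged_vs_encountered"]
        assert jv["mean_judged"] > jv["mean_encountered"]
        ls = out["log_samples_by_judgment"]
        assert ls["mean_desirable"] < ls["mean_undesirable"]

    def test_requires_two_participants(self):
        with pytest.raises(ValueError):
            behavior.desirable_judgment_stats(_participant(0))


class TestSpeedAccuracyAnova:
    def test_median_split_balanced(self, unbiased_task_cohort):
        df = unbiased_task_cohort
        for _, g in df.groupby("participant_id"):
            order = g["rt_s"].rank(method="first")
            fast = (order <= len(g) / 2).sum()
            assert abs(fast - (len(g) - fast)) <= 1

    def test_slow_more_accurate_with_start_jitter(self):
        """Homogeneous drift plus starting-point jitter: fast errors make
        slow responses more accurate (the canonical diffusion pattern)."""
        frames = []
        for pid in range(10):
            rng = np.random.default_rng(50 + pid)
            n = 160
            des = rng.integers(0, 2, n)
            v = np.where(des > 0, 0.5, -0.5)
            resp_up, rt, _ = ddm.simulate_trials(v, 1.5, 0.5, 0.3, 0.8, rng)
            resp = resp_up  # desirable state coded 1
            frames.append(pd.DataFrame({
                "participant_id": pid, "trial_index": np.arange(1, n + 1),
                "true_state": des, "desirability": des, "items": ["10101"] * n,
                "n_samples": np.maximum(np.ceil(rt / 0.55).astype(int), 1),
                "response": resp, "rt_s": rt,
                "accuracy": (resp == des).astype(int), "evidence": 0.1,
            }))
        out = behavior.speed_accuracy_anova(pd.concat(frames, ignore_index=True))
        cells = out["cell_means"]
        slow = cells[cells["speed"] == "slow"]["accuracy"].mean()
        fast = cells[cells["speed"] == "fast"]["accuracy"].mean()
        assert slow > fast
        assert out["anova"].loc["speed", "F"] > 0

    def test_anova_structure_on_task_data(self, unbiased_task_cohort):
        out = behavior.speed_accuracy_anova(unbiased_task_cohort)
        assert list(out["anova"].index) == ["speed", "response", "speed:response"]
        assert np.isfinite(out["anova"]["F"]).all()
        assert out["n_dropped_participants"] == 0

    def test_identical_cell_means_give_no_effects(self):
        """Every participant's four cell means equal 0.5 by construction."""
        frames = []
        for pid in range(6):
            n = 80
            # 20 trials per (speed, response) cell, each cell 10 correct / 10 wrong
            idx = np.arange(n)
            cell = idx % 4
            rt = np.where(cell < 2, 1.0, 3.0) + 1e-6 * idx
            true_state = (cell % 2).astype(int)  # response desirability via state
            acc = ((idx // 4) % 2 == 0).astype(int)  # each cell: half correct
            frames.append(pd.DataFrame({
                "participant_id": pid, "trial_index": np.arange(1, n + 1),
                "true_state": true_state, "desirability": (true_state == 1).astype(int),
                "items": ["10101"] * n, "n_samples": 5,
                "response": np.where(acc == 1, true_state, 1 - true_state),
                "rt_s": rt, "accuracy": acc, "evidence": 0.1,
            }))
        out = behavior.speed_accuracy_anova(pd.concat(frames, ignore_index=True))
        assert np.nan_to_num(out["anova"]["F"].to_numpy()).max() < 1e-6


class TestPsychometric:
    @staticmethod
    def _logistic_cohort(beta0_by_group, beta1=12.0, n_pid=6, n=120, seed=0):
        """Judgments drawn from a known logistic in the TV-proportion covariate."""
        rng = np.random.default_rng(seed)
        frames = []
        pid = 0
        for group, b0 in beta0_by_group.items():
            for _ in range(n_pid):
                n_items = 8
                k = rng.binomial(n_items, 0.5, n)
                x = k / n_items - 0.5
                p = 1.0 / (1.0 + np.exp(-(beta1 * x + b0)))
                resp = (rng.random(n) < p).astype(int)
                true_state = rng.integers(0, 2, n)
                desirable_state = 1 if group == "tv_desirable" else 0
                items = ["".join(["1"] * kk + ["0"] * (n_items - kk)) for kk in k]
                frames.append(pd.DataFrame({
                    "participant_id": pid, "trial_index": np.arange(1, n + 1),
                    "true_state": true_state,
                    "desirability": (true_state == desirable_state).astype(int),
                    "items": items, "n_samples": n_items, "response": resp,
                    "rt_s": 2.0, "accuracy": (resp == true_state).astype(int),
                    "evidence": 0.0,
                }))
                pid += 1
        return pd.concat(frames, ignore_index=True)

    def test_symmetric_data_has_centred_intercept(self):
        data = self._logistic_cohort({"tv_desirable": 0.0, "tv_undesirable": 0.0}, seed=1)
        res = behavior.fit_psychometric(data, seed=1, n_samples=1200, n_burn=300)
        for r in res.values():
            assert r.beta0_ci[0] <= 0.0 <= r.beta0_ci[1]
            assert r.beta1 > 0

    def test_known_intercept_ordering_recovered(self):
        data = self._logistic_cohort({"tv_desirable": 0.8, "tv_undesirable": -0.8}, seed=2)
        res = behavior.fit_psychometric(data, seed=2, n_samples=1200, n_burn=300)
        assert res["tv_desirable"].beta0 > res["tv_undesirable"].beta0

    def test_slope_monotone_in_generating_slope(self):
        fitted = []
        for i, b1 in enumerate([4.0, 10.0, 25.0]):
            data = self._logistic_cohort({"tv_desirable": 0.0, "tv_undesirable": 0.0}, beta1=b1, seed=3 + i)
            res = behavior.fit_psychometric(data, seed=3, n_samples=1000, n_burn=250)
            fitted.append(res["tv_desirable"].beta1)
        assert fitted[0] < fitted[1] < fitted[2]

    def test_tv_proportion_covariate(self):
        df = pd.DataFrame({"items": ["1100", "1111", "0000"]})
        np.testing.assert_allclose(behavior.tv_proportion(df), [0.0, 0.5, -0.5])
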