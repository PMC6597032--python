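"""Factory Game generator: stream composition, states, trial invariants."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from valenceddm import ddm, task


@pytest.fixture()
def cfg():
    return task.TaskConfig(rng_seed=0)


class TestStream:
    def test_degenerate_probability_gives_pure_stream(self):
        c = task.TaskConfig(p_majority=1.0)
        items = task.generate_trial_stream(c, 1, 5, np.random.default_rng(0))
        assert (items == 1).all()

    def test_length_validation(self, cfg):
        with pytest.raises(ValueError):
            task.generate_trial_stream(cfg, 1, 0, np.random.default_rng(0))

    def test_composition_converges(self, cfg):
        """Law of large numbers: majority fraction within 3 SE of 0.6 at n=1e5."""
        n = 100000
        items = task.generate_trial_stream(cfg, 1, n, np.random.default_rng(1))
        frac = (items == 1).mean()
        assert abs(frac - 0.6) < 3 * np.sqrt(0.6 * 0.4 / n)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            task.TaskConfig(p_majority=0.4)
        with pytest.raises(ValueError):
            task.TaskConfig(n_trials=0)
        assert task.TaskConfig().item_period_s == pytest.approx(0.550)


class TestStates:
    def test_desirability_definition(self, cfg):
        ts, des = task.assign_states(cfg, 1000, np.random.default_rng(2))
        assert ((ts == cfg.desirable_state) == (des == 1)).all()

    def test_states_uniform(self, cfg):
        n = 100000
        ts, des = task.assign_states(cfg, n, np.random.default_rng(3))
        assert abs(des.mean() - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_single_trial(self, cfg):
        ts, des = task.assign_states(cfg, 1, np.random.default_rng(4))
        assert ts.shape == (1,) and des.shape == (1,)


class TestParticipant:
    @pytest.fixture(scope="class")
    def session(self):
        cfg = task.TaskConfig(rng_seed=5)
        return cfg, task.simulate_participant(cfg, ddm.DDMParams(), ddm.MODEL_SPECS[1], participant_id=3)

    def test_trial_invariants(self, session):
        cfg, df = session
        assert (df["n_samples"] == np.maximum(np.ceil(df["rt_s"] / cfg.item_period_s), 1).astype(int)).all()
        assert (df["accuracy"] == (df["response"] == df["true_state"]).astype(int)).all()
        assert (df["rt_s"] > 0).all()
        assert df["evidence"].between(-0.5, 0.5).all()
        assert (df["items"].str.len() == df["n_samples"]).all()

    def test_evidence_recomputed_from_seen_items(self, session):
        _, df = session
        for _, row in df.head(20).iterrows():
            seen = np.array([int(cch) for cch in row["items"]])
            prop = (seen == row["true_state"]).mean()
            assert row["evidence"] == pytest.approx(prop - 0.5)

    def test_rt_floor(self, session):
        _, df = session
        assert df["rt_s"].min() >= ddm.DDMParams().t0

    def test_reproducible(self):
        cfg = task.TaskConfig(rng_seed=6)
        d1 = task.simulate_participant(cfg, ddm.DDMParams(), ddm.MODEL_SPECS[1], participant_id=0)
        d2 = task.simulate_participant(cfg, ddm.DDMParams(), ddm.MODEL_SPECS[1], participant_id=0)
        pd.testing.assert_frame_equal(d1, d2)

    def test_nonfinite_params_rejected(self):
        cfg = task.TaskConfig()
        bad = ddm.DDMParams()
        object.__setattr__(bad, "a", np.nan)
        with pytest.raises(ValueError):
            task.simulate_participant(cfg, bad, ddm.MODEL_SPECS[1])


class TestCohortSymmetry:
    def test_unbiased_agents_show_no_valence_asymmetry(self, unbiased_task_cohort):
        """Neutral parameters: judgments, sampling and accuracy do not differ
        between desirable and undesirable states (alpha = 0.01)."""
        df = unbiased_task_cohort.copy()
        df["jd"] = task.judged_desirable(df)
        per = df.groupby("participant_id").agg(
            prop_des=("jd", "mean"),
            enc=("desirability", "mean"),
        )
        t, p = stats.ttest_rel(per["prop_des"], per["enc"])
        assert p > 0.01
        des = df[df["desirability"] == 1].groupby("participant_id")["accuracy"].mean()
        und = df[df["desirability"] == 0].groupby("participant_id")["accuracy"].mean()
        t, p = stats.ttest_rel(des, und)
        assert p > 0.01

    def test_biased_agents_judge_desirable_more(self, biased_task_cohort):
        jd = task.judged_desirable(biased_task_cohort)
        assert jd.mean() > 0.5


def test_csv_roundtrip(tmp_path):
    cfg = task.TaskConfig(rng_seed=8, n_trials=10)
    df = task.simulate_cohort(cfg, ddm.DDMParams(), ddm.MODEL_SPECS[1], 2, seed=8)
    path = tmp_path / "trials.csv"
    task.write_trials(df, path)
    back = task.read_trials(path)
    assert list(back.columns) == task.TRIAL_COLUMNS
    np.testing.assert_allclose(back["rt_s"], df["rt_s"])
    assert (back["items"] == df["items"]).all()


def test_read_trials_validates_columns(tmp_path):
    path = tmp_path / "bad.csv"
    pd.DataFrame({"participant_id": [1]}).to_csv(path, index=False)
    with pytest.raises(ValueError, match="missing columns"):
        task.read_trials(path)
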