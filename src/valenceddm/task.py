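"""Factory Game task simulator.

Generates the paced binary-stream judgment task and synthetic participants
whose choices and response times come from a valence-dependent diffusion
agent.  On every trial the participant watches a conveyor-belt stream of two
item types (coded 1 = "TV", 0 = "phone"); the stream's majority type equals
the trial's true factory state with probability ``p_majority`` per item.
One factory type is desirable for a given participant; the true state is
redrawn uniformly each trial.

The diffusion agent accumulates toward the "judged desirable" bound with a
drift driven by the running evidence of the items seen so far (the centred
proportion of seen items consistent with the true state), updated at each
item boundary.  The recorded ``evidence`` covariate is recomputed post hoc
from the items elapsed by the response time, exactly as the analysis later
uses it.  Items advance every 0.550 s (400 ms traverse + 150 ms lag);
``n_samples = ceil(rt / 0.550)``, i.e. the item on screen at the moment of
response counts as seen.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .ddm import DDMParams, ModelSpec, drift_rate, simulate_trials_piecewise

__all__ = [
    "TaskConfig",
    "TRIAL_COLUMNS",
    "generate_trial_stream",
    "assign_states",
    "simulate_participant",
    "simulate_cohort",
    "judged_desirable",
    "write_trials",
    "read_trials",
]

# 400 ms item traverse + 150 ms inter-item lag
ITEM_PERIOD_S = 0.550

TRIAL_COLUMNS = [
    "participant_id",
    "trial_index",
    "true_state",
    "desirability",
    "items",
    "n_samples",
    "response",
    "rt_s",
    "accuracy",
    "evidence",
]


@dataclass(frozen=True)
class TaskConfig:
    """Study conditions of the Factory Game.

    Defaults are the task as run: 80 trials, 0.6/0.4 item composition,
    400 ms item traverse with 150 ms lag (0.550 s per item).
    """

    n_trials: int = 80
    p_majority: float = 0.6
    item_duration_ms: int = 400
    item_lag_ms: int = 150
    desirable_state: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 < self.p_majority <= 1.0:
            raise ValueError("p_majority must lie in (0.5, 1]")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.desirable_state not in (0, 1):
            raise ValueError("desirable_state must be 0 or 1")

    @property
    def item_period_s(self) -> float:
        return (self.item_duration_ms + self.item_lag_ms) / 1000.0


def generate_trial_stream(config: TaskConfig, true_state: int, length: int, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. item stream: P(item == majority type of the true state) = p_majority."""
    if length < 1:
        raise ValueError("stream length must be >= 1")
    consistent = rng.random(length) < config.p_majority
    return np.where(consistent, true_state, 1 - true_state).astype(np.int8)


def assign_states(config: TaskConfig, n_trials: int, rng: np.random.Generator):
    """Uniform i.i.d. true states and their desirability for each trial."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    true_state = rng.integers(0, 2, size=n_trials).astype(np.int8)
    desirability = (true_state == config.desirable_state).astype(np.int8)
    return true_state, desirability


def _participant_rng(seed: int, participant_id: int) -> np.random.Generator:
    # per-participant substream of one global seed -> reproducible in parallel
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(participant_id,)))


def simulate_participant(
    config: TaskConfig,
    params: DDMParams,
    spec: ModelSpec,
    participant_id: int = 0,
    rng: np.random.Generator | None = None,
    dt: float = 1e-3,
    max_t: float = 60.0,
) -> pd.DataFrame:
    """Simulate one participant's session as a long-format trial table.

    The agent's drift follows the running evidence: during the k-th item
    period the drift is the model regression evaluated at the centred
    consistent proportion of items 1..k.  Censored trials (no bound crossed
    within ``max_t``) keep the cap RT and are flagged via ``rt_s``.
    """
    if rng is None:
        rng = _participant_rng(config.rng_seed, participant_id)
    n = config.n_trials
    period = config.item_period_s
    max_items = int(np.ceil(max_t / period)) + 1
    true_state, desirability = assign_states(config, n, rng)

    streams = np.empty((n, max_items), dtype=np.int8)
    for i in range(n):
        streams[i] = generate_trial_stream(config, int(true_state[i]), max_items, rng)
    consistent = streams == true_state[:, None]
    running_prop = np.cumsum(consistent, axis=1) / np.arange(1, max_items + 1)
    running_evidence = running_prop - 0.5

    v_sched = drift_rate(params, spec, running_evidence, desirability[:, None])
    sign = np.where(desirability > 0, 1.0, -1.0)[:, None]
    resp_up, rt, censored = simulate_trials_piecewise(
        sign * v_sched, period, params.a, params.z, params.t0, params.sz, rng, dt=dt, max_t=max_t
    )

    n_samples = np.maximum(np.ceil(rt / period).astype(int), 1)
    n_samples = np.minimum(n_samples, max_items)
    evidence = running_evidence[np.arange(n), n_samples - 1]
    # upper bound = judged desirable -> judged state
    response = np.where(resp_up == 1, config.desirable_state, 1 - config.desirable_state).astype(np.int8)
    accuracy = (response == true_state).astype(np.int8)
    items_str = ["".join(map(str, streams[i, : n_samples[i]])) for i in range(n)]

    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "trial_index": np.arange(1, n + 1),
            "true_state": true_state,
            "desirability": desirability,
            "items": items_str,
            "n_samples": n_samples,
            "response": response,
            "rt_s": rt,
            "accuracy": accuracy,
            "evidence": evidence,
        }
    )


def simulate_cohort(
    config: TaskConfig,
    params,
    spec: ModelSpec,
    n_participants: int,
    seed: int | None = None,
    alternate_desirable: bool = True,
    dt: float = 1e-3,
) -> pd.DataFrame:
    """Simulate a cohort; ``params`` is one DDMParams or a per-subject list.

    With ``alternate_desirable`` the desirable factory type alternates across
    participants (as in the between-participant counterbalancing of the
    task); each participant uses an independent substream of ``seed``.
    """
    if seed is None:
        seed = config.rng_seed
    frames = []
    for pid in range(n_participants):
        p = params[pid] if isinstance(params, (list, tuple)) else params
        des = (pid % 2) if alternate_desirable else config.desirable_state
        cfg = TaskConfig(**{**asdict(config), "desirable_state": int(des), "rng_seed": seed})
        frames.append(simulate_participant(cfg, p, spec, participant_id=pid, dt=dt))
    return pd.concat(frames, ignore_index=True)


def draw_cohort_params(
    n_participants: int,
    rng: np.random.Generator,
    mean: DDMParams | None = None,
    sd: dict | None = None,
) -> list[DDMParams]:
    """Draw per-subject parameters around group means (natural scale).

    Default between-subject spreads emulate the heterogeneity visible in
    subject-level estimate histograms for this task (starting points spread
    ~0.04 around the group mean, valence drift offsets ~0.085).
    """
    m = mean or DDMParams()
    spread = {"a": 0.6, "t0": 0.05, "z": 0.04, "sz": 0.0, "beta0": 0.1, "beta1": 0.6, "beta2": 0.085, "beta3": 0.085}
    # valence terms absent from the generating model stay exactly zero
    if m.beta2 == 0.0:
        spread["beta2"] = 0.0
    if m.beta3 == 0.0:
        spread["beta3"] = 0.0
    if m.z == 0.5:
        spread["z"] = 0.0
    if sd:
        spread.update(sd)
    out = []
    for _ in range(n_participants):
        draw = {}
        for name, s in spread.items():
            val = getattr(m, name) + (s * rng.standard_normal() if s > 0 else 0.0)
            draw[name] = val
        draw["a"] = float(np.clip(draw["a"], 0.5, 11.0))
        draw["t0"] = float(np.clip(draw["t0"], 0.05, 1.5))
        hi = 1.0 - draw["sz"] / 2 - 1e-3
        draw["z"] = float(np.clip(draw["z"], 1 - hi, hi))
        out.append(DDMParams(**draw))
    return out


def judged_desirable(df: pd.DataFrame) -> np.ndarray:
    """1 where the judged state is the participant's desirable state.

    Derivable from the stored columns: the judgment is desirable iff it
    matches the true state on desirable trials or mismatches it on
    undesirable trials.
    """
    correct = df["response"].to_numpy() == df["true_state"].to_numpy()
    des = df["desirability"].to_numpy().astype(bool)
    return (correct == des).astype(np.int8)


def write_trials(df: pd.DataFrame, path) -> None:
    """Write the long-format trial CSV (UTF-8, header, '.' decimal)."""
    df.to_csv(path, index=False, columns=TRIAL_COLUMNS)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"items": str})
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return df
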