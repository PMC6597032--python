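"""Cross-validation and recovery harness.

Even/odd-trial cross-validation: models are fitted to even trials only and
predict each odd trial by repeated simulation (with Gaussian noise added to
the drift on every repetition), summarizing predictions as mean log RT,
response probability and accuracy probability; fits are compared by mean
absolute error with paired t-tests at the trial level.

The module also provides the direct model-recovery generator: cohorts drawn
*from* a diffusion specification with exogenous per-trial evidence
covariates (unlike :mod:`valenceddm.task`, which emulates the paced item
stream and therefore couples evidence to viewing time).  Recovery studies
need the generating process to coincide exactly with the fitted model, so
truth is known by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import hierarchical
from .ddm import DDMParams, MODEL_SPECS, ModelSpec, signed_drift, simulate_trials
from .hierarchical import MCMCConfig, PosteriorFit
from .task import ITEM_PERIOD_S, draw_cohort_params, judged_desirable

__all__ = [
    "simulate_ddm_cohort",
    "even_odd_split",
    "predict_oos",
    "mae_compare",
    "CVReport",
    "RecoveryConfig",
    "recovery_suite",
]


def sample_evidence(n: int, rng: np.random.Generator, p_consistent: float = 0.6, n_items_range=(3, 10)):
    """Exogenous evidence covariates: centred binomial proportions.

    Mimics the marginal distribution of the consistent-item proportion after
    a handful of samples at the task's 0.6/0.4 composition.
    """
    lo, hi = n_items_range
    n_items = rng.integers(lo, hi + 1, size=n)
    k = rng.binomial(n_items, p_consistent)
    return k / n_items - 0.5, n_items, k


def simulate_ddm_cohort(
    subject_params,
    spec: ModelSpec | int,
    n_trials: int = 80,
    seed: int = 0,
    dt: float = 1e-3,
) -> pd.DataFrame:
    """Cohort drawn directly from a model specification (for recovery).

    Evidence and desirability are exogenous per-trial covariates; choices
    and RTs come from the first-passage simulation with the drift the model
    itself prescribes.  Returns the standard long-format trial table (the
    ``items`` column stores the covariate-defining item draws; ``rt_s`` is
    not coupled to the item pacing here).
    """
    if isinstance(spec, int):
        spec = MODEL_SPECS[spec]
    frames = []
    for pid, params in enumerate(subject_params):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(pid,)))
        desirability = rng.integers(0, 2, size=n_trials).astype(np.int8)
        evidence, n_items, k = sample_evidence(n_trials, rng)
        v = signed_drift(params, spec, evidence, desirability)
        resp_up, rt, cens = simulate_trials(v, params.a, params.z, params.t0, params.sz, rng, dt=dt)
        # desirable state coded 1: true_state == desirability
        true_state = desirability
        response = resp_up.astype(np.int8)  # upper bound = judged desirable = judged state 1
        items = []
        for i in range(n_trials):
            s = np.full(n_items[i], 1 - true_state[i], dtype=np.int8)
            s[: k[i]] = true_state[i]
            items.append("".join(map(str, s)))
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "trial_index": np.arange(1, n_trials + 1),
                    "true_state": true_state,
                    "desirability": desirability,
                    "items": items,
                    "n_samples": np.maximum(np.ceil(rt / ITEM_PERIOD_S).astype(int), 1),
                    "response": response,
                    "rt_s": rt,
                    "accuracy": (response == true_state).astype(np.int8),
                    "evidence": evidence,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def even_odd_split(data: pd.DataFrame):
    """Partition trials by parity of ``trial_index`` (per participant)."""
    even = data[data["trial_index"] % 2 == 0]
    odd = data[data["trial_index"] % 2 == 1]
    return even.reset_index(drop=True), odd.reset_index(drop=True)


def predict_oos(
    fit_result: PosteriorFit,
    odd: pd.DataFrame,
    n_rep: int = 1000,
    noise_sd: float = 0.1,
    seed: int = 0,
    dt: float = 1e-3,
) -> pd.DataFrame:
    """Out-of-sample predictions for held-out trials.

    For each held-out trial, ``n_rep`` first-passage simulations are run
    from the subject's posterior-mean parameters, adding ``N(0, noise_sd)``
    to the drift on each repetition; predictions are the repetition means of
    log RT, the desirable-judgment indicator and the accuracy indicator.
    Censored repetitions are excluded (their count is reported).
    """
    spec = fit_result.spec
    dcode = {"evidence": 0, "desirability": 1, "interaction": 2}[spec.drift_terms]
    subj = {pid: fit_result.subject_chain_mean[i] for i, pid in enumerate(fit_result.participant_ids)}
    rng = np.random.default_rng(seed)
    rows = []
    for _, tr in odd.iterrows():
        pid = tr["participant_id"]
        if pid not in subj:
            raise ValueError(f"participant {pid} missing from the even-trial fit")
        a, t0, z, sz, b0, b1, bx = subj[pid]
        ev, des = float(tr["evidence"]), float(tr["desirability"])
        v = b0 + b1 * ev
        if dcode == 1:
            v += bx * des
        elif dcode == 2:
            v += bx * des * ev
        v_signed = (1.0 if des > 0 else -1.0) * v
        v_rep = v_signed + noise_sd * rng.standard_normal(n_rep)
        resp_up, rt, cens = simulate_trials(v_rep, a, z, t0, sz, rng, dt=dt)
        ok = ~cens
        obs_desirable = bool(judged_desirable(odd.loc[[tr.name]])[0])
        pred_resp = float(resp_up[ok].mean())
        correct_is_upper = des > 0  # correct judgment hits the desirable bound iff state desirable
        pred_acc = pred_resp if correct_is_upper else 1.0 - pred_resp
        rows.append(
            {
                "participant_id": pid,
                "trial_index": tr["trial_index"],
                "pred_log_rt": float(np.mean(np.log(rt[ok]))),
                "pred_judgment": pred_resp,
                "pred_accuracy": pred_acc,
                "obs_log_rt": float(np.log(tr["rt_s"])),
                "obs_judgment": float(obs_desirable),
                "obs_accuracy": float(tr["accuracy"]),
                "n_censored": int(cens.sum()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CVReport:
    """Trial-level predictions and MAE comparison of two models."""

    predictions_a: pd.DataFrame
    predictions_b: pd.DataFrame
    mae: pd.DataFrame  # per participant x measure x model
    mae_mean: dict
    t_tests: dict


_MEASURES = {"log_rt": ("pred_log_rt", "obs_log_rt"), "judgment": ("pred_judgment", "obs_judgment"), "accuracy": ("pred_accuracy", "obs_accuracy")}


def mae_compare(pred_a: pd.DataFrame, pred_b: pd.DataFrame, labels=("model_a", "model_b")) -> CVReport:
    """Mean absolute error per measure and paired trial-level t-tests.

    Predictions must cover identical (participant, trial) sets; the paired
    t-test compares the two models' per-trial absolute errors.
    """
    key = ["participant_id", "trial_index"]
    a = pred_a.sort_values(key).reset_index(drop=True)
    b = pred_b.sort_values(key).reset_index(drop=True)
    if not (a[key].values == b[key].values).all():
        raise ValueError("prediction sets are not aligned on (participant, trial)")
    mae_rows = []
    t_tests = {}
    mae_mean = {}
    for measure, (pc, oc) in _MEASURES.items():
        err_a = (a[pc] - a[oc]).abs()
        err_b = (b[pc] - b[oc]).abs()
        t, p = stats.ttest_rel(err_a, err_b)
        t_tests[measure] = {"t": float(t), "p": float(p), "df": int(len(err_a) - 1)}
        mae_mean[measure] = {labels[0]: float(err_a.mean()), labels[1]: float(err_b.mean())}
        for lab, err, frame in ((labels[0], err_a, a), (labels[1], err_b, b)):
            g = err.groupby(frame["participant_id"]).mean()
            for pid, val in g.items():
                mae_rows.append({"participant_id": pid, "measure": measure, "model": lab, "mae": float(val)})
    return CVReport(
        predictions_a=a,
        predictions_b=b,
        mae=pd.DataFrame(mae_rows),
        mae_mean=mae_mean,
        t_tests=t_tests,
    )


@dataclass
class RecoveryConfig:
    """Scale and conditions of a parameter/model recovery study."""

    n_replicates: int = 20
    n_subjects: int = 12
    n_trials: int = 80
    generating_spec: int = 4
    truth: DDMParams = field(default_factory=lambda: DDMParams(a=1.5, z=0.55, t0=0.3, sz=0.1, beta0=0.0, beta1=3.0, beta2=0.2))
    fit_specs: tuple = (1, 2, 3, 4, 5, 6)
    n_samples: int = 2000
    n_burn: int = 500
    seed: int = 0
    sim_dt: float = 1e-3


def recovery_suite(config: RecoveryConfig) -> dict:
    """Generate -> fit -> summarize across replicates.

    Returns bias/coverage tables for the group-level starting point and
    valence drift term, the per-replicate DIC/BPIC table across fitted
    specs, and the fraction of subject-level estimates on the biased side
    of neutral.  Failures of individual replicates are logged, not raised.
    """
    gen_spec = MODEL_SPECS[config.generating_spec]
    rows, dic_rows, failures = [], [], []
    for rep in range(config.n_replicates):
        rep_seed = config.seed + 7919 * rep
        rng = np.random.default_rng(rep_seed)
        subj = draw_cohort_params(config.n_subjects, rng, mean=config.truth)
        data = simulate_ddm_cohort(subj, gen_spec, n_trials=config.n_trials, seed=rep_seed, dt=config.sim_dt)
        try:
            for spec_id in config.fit_specs:
                f = hierarchical.fit(
                    data,
                    spec_id,
                    MCMCConfig(n_samples=config.n_samples, n_burn=config.n_burn, seed=rep_seed + spec_id),
                )
                dic_rows.append({"replicate": rep, "spec": spec_id, "dic": f.dic, "bpic": f.bpic})
                if spec_id == config.generating_spec:
                    row = {"replicate": rep}
                    true_z = float(np.mean([p.z for p in subj]))
                    true_b2 = float(np.mean([p.beta2 for p in subj]))
                    for name, truth_val in (("z", true_z), ("beta_x", true_b2)):
                        if name == "z" and not gen_spec.free_z:
                            continue
                        chain = f.group_natural_chain(name)
                        lo, hi = f.group_ci95(name)
                        row[f"{name}_mean"] = float(chain.mean())
                        row[f"{name}_true"] = truth_val
                        row[f"{name}_cover"] = bool(lo <= truth_val <= hi)
                    nsubj = f.subject_chain_mean
                    row["frac_subj_z_biased"] = float(np.mean(nsubj[:, 2] > 0.5))
                    row["frac_subj_b2_biased"] = float(np.mean(nsubj[:, 6] > 0.0))
                    rows.append(row)
        except Exception as exc:  # pragma: no cover - defensive
            failures.append({"replicate": rep, "error": repr(exc)})
    params_df = pd.DataFrame(rows)
    dic_df = pd.DataFrame(dic_rows)
    report: dict = {"parameters": params_df, "dic_table": dic_df, "failures": failures}
    if not dic_df.empty:
        winners = dic_df.loc[dic_df.groupby("replicate")["dic"].idxmin(), ["replicate", "spec"]]
        report["dic_winner_counts"] = winners["spec"].value_counts().to_dict()
    if not params_df.empty:
        summary = {}
        for name in ("z", "beta_x"):
            if f"{name}_mean" in params_df:
                est = params_df[f"{name}_mean"]
                tru = params_df[f"{name}_true"]
                summary[name] = {
                    "mean_estimate": float(est.mean()),
                    "mean_truth": float(tru.mean()),
                    "bias": float((est - tru).mean()),
                    "relative_bias": float((est - tru).mean() / max(abs(tru.mean()), 1e-12)),
                    "coverage": float(params_df[f"{name}_cover"].mean()),
                }
        report["summary"] = summary
    return report
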