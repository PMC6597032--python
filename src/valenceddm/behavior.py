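"""Behavioral pipeline: exclusions, descriptive statistics, psychometrics.

Cleaning follows the task's preregistered-style rules: trials answered
before the second item are dropped; participants doing so on more than half
their trials are removed wholesale; participants whose accuracy falls more
than two standard deviations below the sample mean are removed; and
participants tripping at least two bot indicators (metronomic
identical-millisecond response times, chance-level comprehension,
implausible session metadata) are removed.

The psychometric function relates the judged state to the centred
proportion of "TV" items seen on the trial,

    P(judge TV) = 1 / (1 + exp(-(beta1 * X + beta0))),

fitted hierarchically (subject-level intercepts and slopes drawn from group
normals) separately for participants whose desirable factory is the TV vs
the phone factory.  With this sign convention a larger ``beta0`` shifts the
curve left: fewer TV items are needed to judge "TV", so a desirability bias
toward the TV factory appears as beta0(TV desirable) > beta0(TV undesirable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM

__all__ = [
    "ExclusionReport",
    "apply_exclusions",
    "desirable_judgment_stats",
    "speed_accuracy_anova",
    "PsychometricResult",
    "fit_psychometric",
    "tv_proportion",
]

from .task import judged_desirable


@dataclass
class ExclusionReport:
    """What was dropped and why; one primary reason per dropped unit."""

    n_input_trials: int
    n_input_participants: int
    dropped_trials: dict = field(default_factory=dict)  # reason -> count
    dropped_participants: list = field(default_factory=list)  # (pid, reason)
    accuracy_threshold: float = float("nan")
    accuracy_mean: float = float("nan")
    accuracy_sd: float = float("nan")
    retained_n: int = 0
    retained_trials: int = 0


def _bot_indicators(g: pd.DataFrame, meta_row) -> int:
    n = 0
    # identical-millisecond RTs in > 10% of trials
    ms = np.round(g["rt_s"].to_numpy() * 1000).astype(np.int64)
    if len(ms) and (np.bincount(ms - ms.min()).max() / len(ms)) > 0.10:
        n += 1
    if meta_row is not None:
        if bool(meta_row.get("comprehension_at_chance", False)):
            n += 1
        if bool(meta_row.get("suspicious_metadata", False)):
            n += 1
    return n


def apply_exclusions(raw: pd.DataFrame, participant_meta: pd.DataFrame | None = None):
    """Apply the cleaning rules; returns ``(clean_data, ExclusionReport)``.

    ``participant_meta`` may carry per-participant boolean columns
    ``comprehension_at_chance`` and ``suspicious_metadata`` (indexed by
    participant id) for the bot heuristics that cannot be derived from
    trial data.  Rule priority when several apply: early-response majority,
    then low accuracy, then bot.
    """
    if raw is None or len(raw) == 0:
        raise ValueError("empty trial table")
    report = ExclusionReport(
        n_input_trials=len(raw),
        n_input_participants=raw["participant_id"].nunique(),
    )
    early = raw["n_samples"] < 2
    early_frac = early.groupby(raw["participant_id"]).mean()
    drop_early_pids = set(early_frac[early_frac > 0.5].index)
    for pid in sorted(drop_early_pids):
        report.dropped_participants.append((pid, "early_response_majority"))

    kept = raw[~raw["participant_id"].isin(drop_early_pids)]
    n_early_trials = int((kept["n_samples"] < 2).sum())
    if n_early_trials:
        report.dropped_trials["early_response"] = n_early_trials
    kept = kept[kept["n_samples"] >= 2]

    if len(kept) == 0:
        report.retained_n = 0
        return kept.reset_index(drop=True), report

    acc = kept.groupby("participant_id")["accuracy"].mean()
    report.accuracy_mean = float(acc.mean())
    report.accuracy_sd = float(acc.std(ddof=1)) if len(acc) > 1 else 0.0
    report.accuracy_threshold = report.accuracy_mean - 2.0 * report.accuracy_sd
    drop_acc_pids = set(acc[acc < report.accuracy_threshold].index)
    for pid in sorted(drop_acc_pids):
        report.dropped_participants.append((pid, "low_accuracy"))
    kept = kept[~kept["participant_id"].isin(drop_acc_pids)]

    drop_bot_pids = set()
    for pid, g in kept.groupby("participant_id"):
        meta_row = None
        if participant_meta is not None and pid in participant_meta.index:
            meta_row = participant_meta.loc[pid]
        if _bot_indicators(g, meta_row) >= 2:
            drop_bot_pids.add(pid)
    for pid in sorted(drop_bot_pids):
        report.dropped_participants.append((pid, "bot"))
    kept = kept[~kept["participant_id"].isin(drop_bot_pids)]

    report.retained_n = kept["participant_id"].nunique()
    report.retained_trials = len(kept)
    return kept.reset_index(drop=True), report


def desirable_judgment_stats(data: pd.DataFrame) -> dict:
    """Group-level desirability statistics with per-participant summaries.

    Returns the proportion of desirable judgments vs the proportion of
    desirable states actually encountered (paired t-test), mean log samples
    before desirable vs undesirable judgments (paired t-test on participants
    with both judgment types), and false-positive vs false-negative belief
    rates (fraction of undesirable-state trials judged desirable and vice
    versa; paired t-test on participants with both states).
    """
    if data["participant_id"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    df = data.copy()
    df["judged_desirable"] = judged_desirable(df)
    df["log_n_samples"] = np.log(df["n_samples"].astype(float))

    per = []
    for pid, g in df.groupby("participant_id"):
        rec = {
            "participant_id": pid,
            "prop_judged_desirable": g["judged_desirable"].mean(),
            "prop_encountered_desirable": g["desirability"].mean(),
        }
        for lab, sub in (("des", g[g["judged_desirable"] == 1]), ("undes", g[g["judged_desirable"] == 0])):
            rec[f"mean_log_samples_{lab}"] = sub["log_n_samples"].mean() if len(sub) else np.nan
        und = g[g["desirability"] == 0]
        des = g[g["desirability"] == 1]
        rec["fpb_rate"] = und["judged_desirable"].mean() if len(und) else np.nan
        rec["fnb_rate"] = 1.0 - des["judged_desirable"].mean() if len(des) else np.nan
        per.append(rec)
    per = pd.DataFrame(per)

    out = {"per_participant": per}
    t, p = stats.ttest_rel(per["prop_judged_desirable"], per["prop_encountered_desirable"])
    out["judged_vs_encountered"] = {
        "mean_judged": float(per["prop_judged_desirable"].mean()),
        "mean_encountered": float(per["prop_encountered_desirable"].mean()),
        "t": float(t),
        "p": float(p),
        "df": int(len(per) - 1),
    }
    both = per.dropna(subset=["mean_log_samples_des", "mean_log_samples_undes"])
    t, p = stats.ttest_rel(both["mean_log_samples_des"], both["mean_log_samples_undes"])
    out["log_samples_by_judgment"] = {
        "mean_desirable": float(both["mean_log_samples_des"].mean()),
        "mean_undesirable": float(both["mean_log_samples_undes"].mean()),
        "t": float(t),
        "p": float(p),
        "n_excluded": int(len(per) - len(both)),
    }
    fb = per.dropna(subset=["fpb_rate", "fnb_rate"])
    t, p = stats.ttest_rel(fb["fpb_rate"], fb["fnb_rate"])
    out["false_beliefs"] = {
        "fpb_rate": float(fb["fpb_rate"].mean()),
        "fnb_rate": float(fb["fnb_rate"].mean()),
        "t": float(t),
        "p": float(p),
        "n_excluded": int(len(per) - len(fb)),
    }
    return out


def speed_accuracy_anova(data: pd.DataFrame) -> dict:
    """2x2 repeated-measures ANOVA of accuracy on speed x judged desirability.

    Trials are split fast/slow within participant by RT rank (counts differ
    by at most one); cell means feed a repeated-measures ANOVA.
    Participants with any empty cell are dropped and counted.
    """
    df = data.copy()
    df["judged_desirable"] = judged_desirable(df)
    cells = []
    n_dropped = 0
    for pid, g in df.groupby("participant_id"):
        order = g["rt_s"].rank(method="first")
        fast = order <= len(g) / 2
        gg = g.assign(speed=np.where(fast, "fast", "slow"))
        cell = gg.groupby(["speed", "judged_desirable"])["accuracy"].mean()
        if len(cell) < 4:
            n_dropped += 1
            continue
        for (speed, jd), val in cell.items():
            cells.append({"participant_id": pid, "speed": speed, "response": "desirable" if jd else "undesirable", "accuracy": val})
    cells = pd.DataFrame(cells)
    if cells.empty or cells["participant_id"].nunique() < 2:
        raise ValueError("not enough participants with all four cells")
    res = AnovaRM(cells, depvar="accuracy", subject="participant_id", within=["speed", "response"]).fit()
    table = res.anova_table.rename(columns={"F Value": "F", "Pr > F": "p"})
    # guard the degenerate zero-contrast case (0/0 inside the ANOVA)
    wide = cells.pivot_table(index="participant_id", columns=["speed", "response"], values="accuracy")
    contrasts = {
        "speed": wide["fast"].mean(axis=1) - wide["slow"].mean(axis=1),
        "response": wide.xs("desirable", axis=1, level="response").mean(axis=1)
        - wide.xs("undesirable", axis=1, level="response").mean(axis=1),
        "speed:response": (wide[("fast", "desirable")] - wide[("fast", "undesirable")])
        - (wide[("slow", "desirable")] - wide[("slow", "undesirable")]),
    }
    for effect, contrast in contrasts.items():
        if np.allclose(contrast, 0.0, atol=1e-12):
            table.loc[effect, "F"] = 0.0
            table.loc[effect, "p"] = 1.0
    return {"anova": table, "cell_means": cells, "n_dropped_participants": n_dropped}


def tv_proportion(data: pd.DataFrame) -> np.ndarray:
    """Centred proportion of TV items (type 1) among the items seen."""
    props = np.array([s.count("1") / len(s) for s in data["items"].astype(str)])
    return props - 0.5


@dataclass
class PsychometricResult:
    """Group-level psychometric parameters with 95% credible intervals."""

    group: str
    beta0: float
    beta0_ci: tuple
    beta1: float
    beta1_ci: tuple
    n_participants: int
    separation_flag: bool = False


def _hier_logistic(X, y, pid, rng, n_samples=3000, n_burn=800):
    """Hierarchical Bayesian logistic: subject (b0, b1) ~ N(mu, sigma)."""
    pids = np.unique(pid)
    S = len(pids)
    idx = {p: i for i, p in enumerate(pids)}
    si = np.array([idx[p] for p in pid])
    bounds = np.array([[-20.0, 20.0], [-10.0, 80.0]])
    B = np.zeros((S, 2))
    B[:, 1] = 10.0
    mu = np.array([0.0, 10.0])
    sigma = np.array([1.0, 3.0])
    scales = np.full((S, 2), 0.5)

    def subj_ll(s, b):
        eta = b[1] * X[si == s] + b[0]
        yy = y[si == s]
        return float(np.sum(yy * eta - np.logaddexp(0.0, eta)))

    ll = np.array([subj_ll(s, B[s]) for s in range(S)])
    kept_mu = np.empty((n_samples - n_burn, 2))
    acc = np.zeros((S, 2))
    for it in range(n_samples):
        for p in range(2):
            for s in range(S):
                prop = B[s].copy()
                prop[p] += scales[s, p] * rng.standard_normal()
                if not bounds[p, 0] <= prop[p] <= bounds[p, 1]:
                    continue
                ll_new = subj_ll(s, prop)
                dpri = -0.5 * ((prop[p] - mu[p]) ** 2 - (B[s, p] - mu[p]) ** 2) / sigma[p] ** 2
                if np.log(rng.random()) < ll_new - ll[s] + dpri:
                    B[s] = prop
                    ll[s] = ll_new
                    acc[s, p] += 1
            mu[p] = np.clip(B[:, p].mean() + sigma[p] / np.sqrt(S) * rng.standard_normal(), bounds[p, 0], bounds[p, 1])
            prop_s = sigma[p] * np.exp(0.3 * rng.standard_normal())
            if 0.05 <= prop_s <= 20.0:
                dev = B[:, p] - mu[p]
                la = (-S * np.log(prop_s) - 0.5 * np.sum(dev**2) / prop_s**2
                      + S * np.log(sigma[p]) + 0.5 * np.sum(dev**2) / sigma[p] ** 2
                      + np.log(prop_s) - np.log(sigma[p]))
                if np.log(rng.random()) < la:
                    sigma[p] = prop_s
        if it < n_burn and (it + 1) % 25 == 0:
            scales *= np.exp(0.6 * (acc / 25 - 0.44))
            np.clip(scales, 1e-3, 5.0, out=scales)
            acc[:] = 0
        if it >= n_burn:
            kept_mu[it - n_burn] = mu
    return kept_mu, S


def fit_psychometric(data: pd.DataFrame, seed: int = 0, n_samples: int = 3000, n_burn: int = 800):
    """Fit the psychometric function per desirable-factory group.

    Splits participants by which factory type is desirable for them (TV
    desirable vs TV undesirable), fits the hierarchical logistic of
    P(judge TV) on the centred TV proportion, and reports the group-level
    indifference-related intercept ``beta0`` and slope ``beta1`` with 95%
    credible intervals.
    """
    df = data.copy()
    # participant's desirable state: the true state of their desirable trials
    des_state = {}
    for pid, g in df.groupby("participant_id"):
        d = g[g["desirability"] == 1]
        u = g[g["desirability"] == 0]
        if len(d):
            des_state[pid] = int(d["true_state"].iloc[0])
        elif len(u):
            des_state[pid] = 1 - int(u["true_state"].iloc[0])
    df["desirable_state"] = df["participant_id"].map(des_state)
    df["X"] = tv_proportion(df)
    df["y"] = (df["response"] == 1).astype(float)

    results = {}
    rng = np.random.default_rng(seed)
    for label, group_val in (("tv_desirable", 1), ("tv_undesirable", 0)):
        sub = df[df["desirable_state"] == group_val]
        if sub["participant_id"].nunique() < 2:
            raise ValueError(f"group {label} needs at least 2 participants")
        kept_mu, S = _hier_logistic(
            sub["X"].to_numpy(), sub["y"].to_numpy(), sub["participant_id"].to_numpy(), rng,
            n_samples=n_samples, n_burn=n_burn,
        )
        b0, b1 = kept_mu[:, 0], kept_mu[:, 1]
        results[label] = PsychometricResult(
            group=label,
            beta0=float(b0.mean()),
            beta0_ci=(float(np.quantile(b0, 0.025)), float(np.quantile(b0, 0.975))),
            beta1=float(b1.mean()),
            beta1_ci=(float(np.quantile(b1, 0.025)), float(np.quantile(b1, 0.975))),
            n_participants=S,
            separation_flag=bool(np.quantile(b1, 0.5) > 75.0),
        )
    return results
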