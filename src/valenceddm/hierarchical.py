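"""Hierarchical Bayesian estimation of the six diffusion-model specifications.

Subject-level parameters are modelled as draws from group-level normal
distributions on an unconstrained sampling scale (log for the boundary,
logit for the starting point and its jitter fraction, natural for the
non-decision time and drift coefficients).  Group means carry flat priors
over bounded intervals; group standard deviations carry half-uniform priors.
Sampling is Metropolis-within-Gibbs with per-parameter random-walk proposals
whose scales adapt during burn-in only, plus conjugate (truncated-normal)
Gibbs updates for the group means.

Model comparison uses the deviance information criterion
``DIC = Dbar + pD`` with ``pD = Dbar - D(theta_bar)`` (posterior-mean
deviance plus effective number of parameters), and the stronger-penalty
variant ``BPIC = Dbar + 2 pD``; lower is better for both.  Convergence is
diagnosed with the classic Gelman-Rubin statistic over independent runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._fastlik import njit, loglik_kernel, _GL_NODES, _GL_WEIGHTS
from .ddm import MODEL_SPECS, ModelSpec
from .task import judged_desirable

__all__ = [
    "MCMCConfig",
    "PosteriorFit",
    "fit",
    "gelman_rubin",
    "dic",
    "bpic",
    "compare_models",
]

# parameter layout on the sampling scale (fixed width; unused slots frozen)
PARAM_NAMES = ["a", "t0", "z", "sz_frac", "beta0", "beta1", "beta_x"]
_LOGIT_99 = float(np.log(0.99 / 0.01))
# transformed-scale bounds: log a, t0, logit z, logit sz-fraction, betas
_BOUNDS = np.array(
    [
        [np.log(0.3), np.log(12.0)],
        [0.0, 2.0],
        [-_LOGIT_99, _LOGIT_99],
        [-7.0, 7.0],
        [-10.0, 10.0],
        [-10.0, 10.0],
        [-10.0, 10.0],
    ]
)
_SIGMA_MIN, _SIGMA_MAX = 0.01, 3.0
_SZ_CAP = 0.9  # sz may use at most this fraction of the feasible range


@dataclass(frozen=True)
class MCMCConfig:
    """Chain length and numerical settings for one sampling run."""

    n_samples: int = 20000
    n_burn: int = 5000
    seed: int = 0
    err: float = 1e-7
    adapt_every: int = 25
    max_init_retries: int = 20

    def __post_init__(self) -> None:
        if self.n_burn >= self.n_samples:
            raise ValueError("n_burn must be smaller than n_samples")


@dataclass
class PosteriorFit:
    """Posterior chains and summaries of one hierarchical fit."""

    spec: ModelSpec
    config: MCMCConfig
    participant_ids: list
    free_mask: np.ndarray
    group_mean_chain: np.ndarray  # (n_kept, P) sampling scale
    group_sd_chain: np.ndarray  # (n_kept, P)
    subject_chain_mean: np.ndarray  # (S, P) posterior mean, natural scale
    subject_natural_chain: np.ndarray | None
    deviance_chain: np.ndarray
    deviance_at_mean: float
    dic: float
    bpic: float
    p_d: float
    pd_warning: bool
    group_summary: pd.DataFrame
    accept_rate: float

    @property
    def n_samples(self) -> int:
        return self.config.n_samples

    @property
    def n_burn(self) -> int:
        return self.config.n_burn

    def group_natural_chain(self, name: str) -> np.ndarray:
        """Posterior chain of a group mean on the natural scale."""
        j = PARAM_NAMES.index(name)
        return _to_natural_group(self.group_mean_chain[:, j], j)

    def group_ci95(self, name: str):
        chain = self.group_natural_chain(name)
        return float(np.quantile(chain, 0.025)), float(np.quantile(chain, 0.975))

    def to_json(self, path, include_chains: bool = False) -> None:
        payload = {
            "spec": self.spec.id,
            "n_samples": self.n_samples,
            "n_burn": self.n_burn,
            "dic": self.dic,
            "bpic": self.bpic,
            "p_d": self.p_d,
            "group_summary": json.loads(self.group_summary.to_json(orient="index")),
            "accept_rate": self.accept_rate,
        }
        if include_chains:
            payload["group_mean_chain"] = self.group_mean_chain.tolist()
            payload["group_sd_chain"] = self.group_sd_chain.tolist()
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _to_natural_group(x: np.ndarray, j: int) -> np.ndarray:
    if j == 0:
        return np.exp(x)
    if j in (2, 3):
        return 1.0 / (1.0 + np.exp(-x))
    return np.asarray(x, dtype=float).copy()


@njit(cache=False)
def _natural_params(xs):
    """Sampling-scale vector -> (a, t0, z, sz, beta0, beta1, beta_x)."""
    a = np.exp(xs[0])
    t0 = xs[1]
    z = 1.0 / (1.0 + np.exp(-xs[2]))
    frac = 1.0 / (1.0 + np.exp(-xs[3]))
    sz = frac * _SZ_CAP * 2.0 * min(z, 1.0 - z)
    return a, t0, z, sz, xs[4], xs[5], xs[6]


@njit(cache=False)
def _subject_loglik(xs, rt, upper, ev, des, n_i, drift_code, nodes, weights, err):
    a, t0, z, sz, b0, b1, bx = _natural_params(xs)
    v = np.empty(n_i)
    for i in range(n_i):
        vi = b0 + b1 * ev[i]
        if drift_code == 1:
            vi += bx * des[i]
        elif drift_code == 2:
            vi += bx * des[i] * ev[i]
        v[i] = vi if des[i] > 0 else -vi
    return loglik_kernel(rt[:n_i], upper[:n_i], v, a, z, sz, t0, nodes, weights, err)


@njit(cache=False)
def _sweep(
    X,
    ll,
    scales,
    mu,
    sigma,
    free,
    bounds,
    rt,
    upper,
    ev,
    des,
    n_i,
    drift_code,
    rand_n,
    rand_u,
    nodes,
    weights,
    err,
):
    """One Metropolis-within-Gibbs sweep over all subjects and parameters."""
    S, P = X.shape
    accepted = np.zeros((S, P), dtype=np.bool_)
    for p in range(P):
        if not free[p]:
            continue
        for s in range(S):
            old = X[s, p]
            new = old + scales[s, p] * rand_n[s, p]
            if new < bounds[p, 0] or new > bounds[p, 1]:
                continue
            X[s, p] = new
            ll_new = _subject_loglik(
                X[s], rt[s], upper[s], ev[s], des[s], n_i[s], drift_code, nodes, weights, err
            )
            d_prior = -0.5 * ((new - mu[p]) ** 2 - (old - mu[p]) ** 2) / sigma[p] ** 2
            log_alpha = ll_new - ll[s] + d_prior
            if np.log(rand_u[s, p]) < log_alpha:
                ll[s] = ll_new
                accepted[s, p] = True
            else:
                X[s, p] = old
    return accepted


def _prepare_data(data: pd.DataFrame):
    """Pad per-subject trial arrays to a common width for the kernels."""
    pids = sorted(data["participant_id"].unique().tolist())
    groups = [data[data["participant_id"] == pid] for pid in pids]
    n_i = np.array([len(g) for g in groups], dtype=np.int64)
    if len(pids) < 2:
        raise ValueError("hierarchical fit requires at least 2 participants")
    if np.any(n_i == 0):
        raise ValueError("participant with zero trials")
    width = int(n_i.max())
    S = len(pids)
    rt = np.zeros((S, width))
    upper = np.zeros((S, width), dtype=np.bool_)
    ev = np.zeros((S, width))
    des = np.zeros((S, width))
    for s, g in enumerate(groups):
        m = len(g)
        rt[s, :m] = g["rt_s"].to_numpy(dtype=float)
        upper[s, :m] = judged_desirable(g).astype(bool)
        ev[s, :m] = g["evidence"].to_numpy(dtype=float)
        des[s, :m] = g["desirability"].to_numpy(dtype=float)
    return pids, rt, upper, ev, des, n_i


def _free_mask(spec: ModelSpec) -> np.ndarray:
    free = np.array([True, True, spec.free_z, True, True, True, spec.drift_terms != "evidence"])
    return free


def _drift_code(spec: ModelSpec) -> int:
    return {"evidence": 0, "desirability": 1, "interaction": 2}[spec.drift_terms]


def _init_state(rng, S, free, rt, n_i):
    X = np.zeros((S, 7))
    min_rt = np.array([rt[s, : n_i[s]].min() for s in range(S)])
    X[:, 1] = np.clip(0.6 * min_rt, 0.02, 1.9)
    mean_dt = np.array([rt[s, : n_i[s]].mean() for s in range(S)]) - X[:, 1]
    a_guess = np.clip(np.sqrt(4.0 * np.maximum(mean_dt, 0.05)), 0.8, 9.0)
    X[:, 0] = np.log(a_guess) + 0.05 * rng.standard_normal(S)
    X[:, 2] = 0.0 + (0.05 * rng.standard_normal(S) if free[2] else 0.0)
    X[:, 3] = -2.0 + 0.1 * rng.standard_normal(S)
    X[:, 4] = 0.05 * rng.standard_normal(S)
    X[:, 5] = 2.0 + 0.2 * rng.standard_normal(S)
    X[:, 6] = 0.05 * rng.standard_normal(S) if free[6] else 0.0
    mu = X.mean(axis=0)
    sigma = np.full(7, 0.3)
    return X, mu, sigma


def _trunc_normal(rng, mean, sd, lo, hi):
    from scipy.special import ndtr, ndtri

    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = rng.uniform(ndtr(a), ndtr(b))
    return mean + sd * ndtri(u)


def fit(data: pd.DataFrame, spec: ModelSpec | int, config: MCMCConfig | None = None, keep_subject_chains: bool = False) -> PosteriorFit:
    """Fit one model specification to a long-format trial table.

    ``data`` must contain the standard trial columns (see
    :data:`valenceddm.task.TRIAL_COLUMNS`); run the exclusion pipeline first
    for raw data.  Returns a :class:`PosteriorFit` with burned-in chains
    discarded from all summaries.
    """
    if isinstance(spec, int):
        spec = MODEL_SPECS[spec]
    if config is None:
        config = MCMCConfig()
    rng = np.random.default_rng(config.seed)
    pids, rt, upper, ev, des, n_i = _prepare_data(data)
    S = len(pids)
    free = _free_mask(spec)
    dcode = _drift_code(spec)
    nodes, weights = _GL_NODES, _GL_WEIGHTS

    # initialization with retries until the log-posterior is finite
    for attempt in range(config.max_init_retries):
        X, mu, sigma = _init_state(rng, S, free, rt, n_i)
        ll = np.array(
            [
                _subject_loglik(X[s], rt[s], upper[s], ev[s], des[s], n_i[s], dcode, nodes, weights, config.err)
                for s in range(S)
            ]
        )
        if np.all(np.isfinite(ll)):
            break
        # shrink non-decision times and retry
        rt_scale = 0.5**attempt
        X[:, 1] *= rt_scale
    else:
        raise RuntimeError("could not find a finite initial log-posterior; check rt_s > plausible t0")

    scales = np.full((S, 7), 0.15)
    sd_scales = np.full(7, 0.2)
    n_kept = config.n_samples - config.n_burn
    gm_chain = np.empty((n_kept, 7))
    gs_chain = np.empty((n_kept, 7))
    dev_chain = np.empty(n_kept)
    subj_nat_sum = np.zeros((S, 7))
    subj_nat_chain = np.empty((n_kept, S, 7)) if keep_subject_chains else None
    acc_window = np.zeros((S, 7))
    sd_acc_window = np.zeros(7)
    total_acc = 0.0
    total_prop = 0.0

    for it in range(config.n_samples):
        rand_n = rng.standard_normal((S, 7))
        rand_u = rng.random((S, 7))
        accepted = _sweep(
            X, ll, scales, mu, sigma, free, _BOUNDS, rt, upper, ev, des, n_i, dcode,
            rand_n, rand_u, nodes, weights, config.err,
        )
        acc_window += accepted
        total_acc += accepted[:, free].sum()
        total_prop += S * free.sum()

        # group means: conjugate truncated-normal Gibbs
        for p in np.flatnonzero(free):
            mu[p] = _trunc_normal(rng, X[:, p].mean(), sigma[p] / np.sqrt(S), _BOUNDS[p, 0], _BOUNDS[p, 1])
            # group sds: random-walk on log sigma, half-uniform prior
            prop = sigma[p] * np.exp(sd_scales[p] * rng.standard_normal())
            if _SIGMA_MIN <= prop <= _SIGMA_MAX:
                dev_old = X[:, p] - mu[p]
                log_alpha = (
                    -S * np.log(prop) - 0.5 * np.sum(dev_old**2) / prop**2
                    + S * np.log(sigma[p]) + 0.5 * np.sum(dev_old**2) / sigma[p] ** 2
                    + np.log(prop) - np.log(sigma[p])  # log-scale proposal Jacobian
                )
                if np.log(rng.random()) < log_alpha:
                    sigma[p] = prop
                    sd_acc_window[p] += 1

        if it < config.n_burn and (it + 1) % config.adapt_every == 0:
            rate = acc_window / config.adapt_every
            scales *= np.exp(0.6 * (rate - 0.44))
            np.clip(scales, 1e-3, 2.0, out=scales)
            sd_rate = sd_acc_window / config.adapt_every
            sd_scales *= np.exp(0.6 * (sd_rate - 0.44))
            np.clip(sd_scales, 1e-3, 2.0, out=sd_scales)
            acc_window[:] = 0.0
            sd_acc_window[:] = 0.0

        if it >= config.n_burn:
            k = it - config.n_burn
            gm_chain[k] = mu
            gs_chain[k] = sigma
            dev_chain[k] = -2.0 * ll.sum()
            nat = np.array([_natural_params(X[s]) for s in range(S)])
            subj_nat_sum += nat
            if keep_subject_chains:
                subj_nat_chain[k] = nat

    subj_mean = subj_nat_sum / n_kept

    # plug-in deviance at posterior-mean subject parameters (natural scale)
    dev_at_mean = 0.0
    for s in range(S):
        a, t0, z, sz, b0, b1, bx = subj_mean[s]
        xs = np.array(
            [np.log(a), t0, np.log(z / (1 - z)), 0.0, b0, b1, bx]
        )
        # reconstruct the sz fraction so _natural_params round-trips
        cap = _SZ_CAP * 2.0 * min(z, 1.0 - z)
        frac = min(max(sz / cap, 1e-9), 1 - 1e-9)
        xs[3] = np.log(frac / (1 - frac))
        dev_at_mean += _subject_loglik(xs, rt[s], upper[s], ev[s], des[s], n_i[s], dcode, nodes, weights, config.err)
    dev_at_mean *= -2.0

    dbar = float(dev_chain.mean())
    p_d = dbar - dev_at_mean
    dic_val = dbar + p_d
    bpic_val = dbar + 2.0 * p_d

    rows = {}
    for j, name in enumerate(PARAM_NAMES):
        if not free[j]:
            continue
        nat = _to_natural_group(gm_chain[:, j], j)
        rows[name] = {
            "mean": float(nat.mean()),
            "ci_lo": float(np.quantile(nat, 0.025)),
            "ci_hi": float(np.quantile(nat, 0.975)),
            "group_sd_mean": float(gs_chain[:, j].mean()),
        }
    summary = pd.DataFrame(rows).T

    return PosteriorFit(
        spec=spec,
        config=config,
        participant_ids=pids,
        free_mask=free,
        group_mean_chain=gm_chain,
        group_sd_chain=gs_chain,
        subject_chain_mean=subj_mean,
        subject_natural_chain=subj_nat_chain,
        deviance_chain=dev_chain,
        deviance_at_mean=float(dev_at_mean),
        dic=float(dic_val),
        bpic=float(bpic_val),
        p_d=float(p_d),
        pd_warning=bool(p_d < 0),
        group_summary=summary,
        accept_rate=float(total_acc / max(total_prop, 1)),
    )


def gelman_rubin(runs) -> dict[str, float]:
    """Classic Gelman-Rubin R-hat per group parameter over independent runs.

    ``R-hat = sqrt(V-hat / W)`` where W is the mean within-chain variance and
    V-hat the pooled variance estimate; requires >= 2 runs of equal length.
    Accepts :class:`PosteriorFit` objects or a mapping name -> list of 1-D
    chains.
    """
    if isinstance(runs, dict):
        chains_by_name = {k: [np.asarray(c, dtype=float) for c in v] for k, v in runs.items()}
    else:
        runs = list(runs)
        if len(runs) < 2:
            raise ValueError("gelman_rubin requires at least 2 runs")
        free = runs[0].free_mask
        chains_by_name = {}
        for j, name in enumerate(PARAM_NAMES):
            if free[j]:
                chains_by_name[name] = [f.group_mean_chain[:, j] for f in runs]
    out = {}
    for name, chains in chains_by_name.items():
        if len(chains) < 2:
            raise ValueError("gelman_rubin requires at least 2 chains per parameter")
        lengths = {len(c) for c in chains}
        if len(lengths) != 1:
            raise ValueError("chains must have equal length")
        m = len(chains)
        n = lengths.pop()
        means = np.array([c.mean() for c in chains])
        variances = np.array([c.var(ddof=1) for c in chains])
        w = variances.mean()
        b_over_n = means.var(ddof=1)
        v_hat = (n - 1) / n * w + b_over_n + b_over_n / m
        out[name] = float(np.sqrt(v_hat / w)) if w > 0 else 1.0
    return out


def dic(fit_result: PosteriorFit) -> float:
    """Deviance information criterion of a completed fit (lower is better)."""
    return fit_result.dic


def bpic(fit_result: PosteriorFit) -> float:
    """BPIC = Dbar + 2 pD; penalizes complexity twice as strongly as DIC."""
    return fit_result.bpic


def compare_models(
    data: pd.DataFrame,
    specs=(1, 2, 3, 4, 5, 6),
    config: MCMCConfig | None = None,
    rhat_runs: int = 0,
) -> pd.DataFrame:
    """Fit several specifications with identical settings; rank by DIC.

    With ``rhat_runs >= 2``, each spec is additionally refit that many times
    from different seeds and the worst group-parameter R-hat is reported;
    non-converged fits (R-hat >= 1.1) are flagged but still ranked.
    """
    if config is None:
        config = MCMCConfig()
    rows = []
    for spec_id in specs:
        spec = MODEL_SPECS[spec_id] if isinstance(spec_id, int) else spec_id
        f = fit(data, spec, config)
        row = {
            "spec": spec.id,
            "name": spec.name,
            "dic": f.dic,
            "bpic": f.bpic,
            "p_d": f.p_d,
            "pd_warning": f.pd_warning,
        }
        if rhat_runs >= 2:
            fits = [f] + [
                fit(data, spec, MCMCConfig(
                    n_samples=config.n_samples, n_burn=config.n_burn,
                    seed=config.seed + 1000 * (r + 1), err=config.err,
                ))
                for r in range(rhat_runs - 1)
            ]
            rhats = gelman_rubin(fits)
            row["rhat_max"] = max(rhats.values())
            row["converged"] = row["rhat_max"] < 1.1
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("dic").reset_index(drop=True)
    return table
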