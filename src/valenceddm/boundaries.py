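"""Discrete evidence accumulator with fixed or Weibull-collapsing thresholds.

The decision variable accumulates the per-item evidence difference plus
Gaussian noise,

    X_t = X_{t-1} + d_t + eps_t,      eps_t ~ N(0, sigma^2),

with d_t = +1 for an item supporting the positive-boundary (desirable)
state and -1 otherwise, and X_1 = x1 encoding a starting bias.  A judgment
occurs at the first item step t where |X_t| >= u_t, with the symmetric
threshold following the Weibull collapse

    u_t = a - [1 - exp(-(t / lam)^k)] * (a - a_prime),

so u_0 = a, u_t -> a_prime, and k (fixed at 3) sets the lateness of the
collapse.  The starting bias is compared against u_1 before any item
contributes, so a bias on the boundary triggers an immediate step-1
decision.

Because no closed-form likelihood exists for this process, parameters are
fitted by simulation-based maximum likelihood: for each trial the model is
simulated many times and the likelihood contribution is the fraction of
simulations whose decision step matches the observed one (within the RT
bin width; a small floor keeps the product positive), maximized by an
adaptive grid search followed by Nelder-Mead restarts from the best grid
points.  Fixed-threshold fits are the same machinery with a_prime pinned
to a (lam and a_prime then not counted as free parameters in the AIC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "WeibullBoundaryParams",
    "SimLikelihoodConfig",
    "weibull_boundary",
    "simulate_accumulator",
    "simulate_decision_steps",
    "sim_likelihood",
    "fit_ml",
    "MLFit",
]


@dataclass(frozen=True)
class WeibullBoundaryParams:
    """Threshold and accumulator parameters (time in item steps)."""

    a: float
    a_prime: float
    lam: float
    k: float = 3.0
    sigma2: float = 1.0
    x1: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("initial boundary a must be > 0")
        if not 0.0 <= self.a_prime <= self.a:
            raise ValueError("asymptotic boundary must satisfy 0 <= a_prime <= a")
        if self.lam <= 0:
            raise ValueError("scale lam must be > 0")
        if self.sigma2 < 0:
            raise ValueError("noise variance must be >= 0")


def weibull_boundary(t, p: WeibullBoundaryParams):
    """Threshold u_t at item step(s) t (non-increasing, u_0 = a)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    u = p.a - (-np.expm1(-((t / p.lam) ** p.k))) * (p.a - p.a_prime)
    return u if u.ndim else float(u)


def _extend_items(d: np.ndarray, total: int, p_plus: float, rng: np.random.Generator) -> np.ndarray:
    if len(d) >= total:
        return d[:total]
    extra = np.where(rng.random(total - len(d)) < p_plus, 1.0, -1.0)
    return np.concatenate([d, extra])


def simulate_decision_steps(
    d: np.ndarray,
    p: WeibullBoundaryParams,
    n_sim: int,
    rng: np.random.Generator,
    max_steps: int = 100,
    p_plus: float = 0.5,
):
    """Vectorized accumulator simulation on one trial's item stream.

    Returns ``(steps, responses, censored)`` arrays of length ``n_sim``;
    ``responses`` is +1/-1 for the boundary hit.  The stream is extended by
    i.i.d. generation (P(+1) = ``p_plus``) when simulations outlast it.
    """
    if n_sim < 1:
        raise ValueError("need at least one simulation")
    d_full = _extend_items(np.asarray(d, dtype=float), max_steps, p_plus, rng)
    t_grid = np.arange(1, max_steps + 1, dtype=float)
    u = weibull_boundary(t_grid, p)
    sd = np.sqrt(p.sigma2)
    noise = sd * rng.standard_normal((n_sim, max_steps)) if sd > 0 else np.zeros((n_sim, max_steps))
    X = p.x1 + np.cumsum(d_full[None, :] + noise, axis=1)

    steps = np.zeros(n_sim, dtype=np.int64)
    resp = np.zeros(n_sim, dtype=np.int8)
    censored = np.zeros(n_sim, dtype=bool)
    if abs(p.x1) >= u[0]:
        steps[:] = 1
        resp[:] = 1 if p.x1 > 0 else -1
        return steps, resp, censored
    crossed = np.abs(X) >= u[None, :]
    any_cross = crossed.any(axis=1)
    first = np.argmax(crossed, axis=1)
    steps[any_cross] = first[any_cross] + 1
    resp[any_cross] = np.sign(X[any_cross, first[any_cross]]).astype(np.int8)
    censored[~any_cross] = True
    steps[~any_cross] = max_steps
    return steps, resp, censored


def simulate_accumulator(
    d: np.ndarray,
    p: WeibullBoundaryParams,
    rng: np.random.Generator,
    max_steps: int = 100,
    p_plus: float = 0.5,
):
    """One accumulator run; returns ``(response, decision_step, censored)``."""
    steps, resp, cens = simulate_decision_steps(d, p, 1, rng, max_steps=max_steps, p_plus=p_plus)
    return int(resp[0]), int(steps[0]), bool(cens[0])


@dataclass(frozen=True)
class SimLikelihoodConfig:
    """Settings of the simulation-based likelihood and its optimizer.

    ``final_eval_factor`` controls the fresh-seed re-evaluation of the
    likelihood at the optimum (with that many times ``n_sim_per_trial``
    simulations); reporting AIC from an independent, larger simulation set
    removes most of the optimism that maximizing a noisy surface induces,
    which would otherwise favor the more flexible model.
    """

    n_sim_per_trial: int = 1000
    rt_match_rule: int = 1  # RT bin width in item steps
    epsilon_floor: float | None = None  # default 1 / (2 n_sim)
    grid_points: int = 8
    grid_passes: int = 2
    simplex_starts: int = 5
    simplex_maxiter: int = 500
    max_steps: int = 100
    final_eval_factor: int = 5
    fix_sigma2: float | None = None
    fix_x1: float | None = None

    def __post_init__(self) -> None:
        if self.n_sim_per_trial < 100:
            raise ValueError("n_sim_per_trial must be >= 100")
        floor = self.epsilon_floor
        if floor is None:
            object.__setattr__(self, "epsilon_floor", 1.0 / (2.0 * self.n_sim_per_trial))
        elif floor <= 0:
            raise ValueError("epsilon_floor must be > 0")


def sim_likelihood(
    trials,
    p: WeibullBoundaryParams,
    config: SimLikelihoodConfig,
    rng: np.random.Generator,
    p_plus: float = 0.5,
) -> float:
    """Log likelihood sum_i log max(p_i, floor) over one data subset.

    ``trials`` is an iterable of ``(d_items, observed_step)`` pairs; p_i is
    the fraction of simulations whose decision step falls in the observed
    step's RT bin.  One set of accumulator noise (and one stream extension)
    is drawn up front and shared by every trial, so the value is exactly
    invariant to trial order for a given ``rng`` state.
    """
    if config.n_sim_per_trial <= 0:
        raise ValueError("zero simulations requested")
    trials = list(trials)
    if not trials:
        raise ValueError("no trials")
    w = config.rt_match_rule
    T = config.max_steps
    ext_items = np.where(rng.random(T) < p_plus, 1.0, -1.0)
    sd = np.sqrt(p.sigma2)
    noise = sd * rng.standard_normal((config.n_sim_per_trial, T)) if sd > 0 else np.zeros((config.n_sim_per_trial, T))
    t_grid = np.arange(1, T + 1, dtype=float)
    u = weibull_boundary(t_grid, p)
    total = 0.0
    for d, obs in trials:
        d_arr = np.asarray(d, dtype=float)[:T]
        d_full = np.concatenate([d_arr, ext_items[len(d_arr):]])
        if abs(p.x1) >= u[0]:
            p_i = 1.0 if int(obs) == 1 else 0.0
        else:
            X = p.x1 + np.cumsum(d_full[None, :] + noise, axis=1)
            crossed = np.abs(X) >= u[None, :]
            any_cross = crossed.any(axis=1)
            first = np.argmax(crossed, axis=1) + 1
            match = any_cross & (np.abs(first - int(obs)) < w)
            p_i = match.mean()
        total += np.log(max(p_i, config.epsilon_floor))
    return float(total)


@dataclass
class MLFit:
    """Best-fitting parameters of a simulation-based ML fit."""

    model: str
    params: WeibullBoundaryParams
    loglik: float
    aic: float
    n_free: int
    n_trials: int
    converged: bool


_FIXED_LAM = 5.0  # irrelevant when a_prime == a; kept constant for fixed fits


def _vector_to_params(x, model, config) -> WeibullBoundaryParams | None:
    sig = config.fix_sigma2
    fx1 = config.fix_x1
    i = 0
    a = x[i]; i += 1
    if model == "collapsing":
        frac = x[i]; i += 1
        lam = x[i]; i += 1
    else:
        frac, lam = 1.0, _FIXED_LAM
    sigma2 = sig if sig is not None else x[i]
    if sig is None:
        i += 1
    x1 = fx1 if fx1 is not None else x[i]
    try:
        return WeibullBoundaryParams(a=a, a_prime=frac * a, lam=lam, sigma2=sigma2, x1=x1)
    except ValueError:
        return None


def _grid_axes(model, config):
    axes = [("a", 0.5, 12.0)]
    if model == "collapsing":
        axes += [("a_prime_frac", 0.0, 1.0), ("lam", 0.5, 20.0)]
    if config.fix_sigma2 is None:
        axes += [("sigma2", 0.1, 4.0)]
    if config.fix_x1 is None:
        axes += [("x1", -2.0, 2.0)]
    return axes


class _CRNLikelihood:
    """Common-random-numbers likelihood evaluator for one data subset.

    The accumulator is linear in its noise: X_t = x1 + cumsum(d)_t +
    sigma * cumsum(N)_t with N standard normal.  Drawing N once and
    reusing it for every proposal makes the simulated likelihood a smooth
    deterministic function of the parameters, which grid search and
    Nelder-Mead can optimize reliably.
    """

    def __init__(self, trials, config, rng, p_plus, n_sim):
        self.config = config
        self.obs = np.array([int(s) for _, s in trials])
        T = config.max_steps
        d_full = np.stack([_extend_items(np.asarray(d, dtype=float), T, p_plus, rng) for d, _ in trials])
        self.D = np.cumsum(d_full, axis=1)  # (n_trials, T)
        self.CN = np.cumsum(rng.standard_normal((len(trials), n_sim, T)), axis=2)
        self.t_grid = np.arange(1, T + 1, dtype=float)
        self.n_sim = n_sim

    def loglik(self, p: WeibullBoundaryParams) -> float:
        u = weibull_boundary(self.t_grid, p)
        if abs(p.x1) >= u[0]:
            # immediate step-1 decision in every simulation
            p_i = (self.obs == 1).astype(float)
            return float(np.sum(np.log(np.maximum(p_i, self.config.epsilon_floor))))
        X = p.x1 + self.D[:, None, :] + np.sqrt(p.sigma2) * self.CN
        crossed = np.abs(X) >= u[None, None, :]
        any_cross = crossed.any(axis=2)
        first = np.argmax(crossed, axis=2) + 1  # (n_trials, n_sim)
        w = self.config.rt_match_rule
        match = any_cross & (np.abs(first - self.obs[:, None]) < w)
        p_i = match.mean(axis=1)
        return float(np.sum(np.log(np.maximum(p_i, self.config.epsilon_floor))))


def fit_ml(
    trials,
    model: str = "collapsing",
    config: SimLikelihoodConfig | None = None,
    seed: int = 0,
    p_plus: float = 0.5,
) -> MLFit:
    """Simulation-based maximum likelihood for one participant/response set.

    An adaptive grid (span halved around the incumbent each pass) seeds
    Nelder-Mead restarts from the best grid points.  One fixed set of
    simulation noise is reused for every proposal (common random numbers),
    so the objective is deterministic given ``seed``; the reported log
    likelihood and AIC come from a larger, independent simulation set at
    the optimum.
    """
    if model not in ("fixed", "collapsing"):
        raise ValueError("model must be 'fixed' or 'collapsing'")
    if config is None:
        config = SimLikelihoodConfig()
    trials = list(trials)
    if not trials:
        raise ValueError("no trials to fit")
    ss = np.random.SeedSequence(seed)
    rng_opt, rng_final = (np.random.default_rng(c) for c in ss.spawn(2))
    crn = _CRNLikelihood(trials, config, rng_opt, p_plus, config.n_sim_per_trial)

    def neg_ll(x):
        p = _vector_to_params(x, model, config)
        if p is None:
            return 1e12
        return -crn.loglik(p)

    axes = _grid_axes(model, config)
    centers = np.array([(lo + hi) / 2 for _, lo, hi in axes])
    spans = np.array([(hi - lo) / 2 for _, lo, hi in axes])
    evaluated = []
    for _ in range(config.grid_passes):
        grids = [np.linspace(c - s, c + s, config.grid_points) for c, s in zip(centers, spans)]
        # clip to the original global ranges
        grids = [np.clip(g, lo, hi) for g, (_, lo, hi) in zip(grids, axes)]
        mesh = np.meshgrid(*grids, indexing="ij")
        points = np.stack([m.ravel() for m in mesh], axis=1)
        vals = np.array([neg_ll(pt) for pt in points])
        evaluated.extend(zip(vals.tolist(), points.tolist()))
        centers = points[np.argmin(vals)]
        spans = spans / 2.0

    evaluated.sort(key=lambda t: t[0])
    best_val, best_x = evaluated[0][0], np.array(evaluated[0][1])
    converged = False
    for _, start in evaluated[: config.simplex_starts]:
        res = minimize(
            neg_ll,
            np.array(start),
            method="Nelder-Mead",
            options={"maxiter": config.simplex_maxiter, "xatol": 1e-3, "fatol": 1e-3},
        )
        if res.fun < best_val:
            best_val, best_x = res.fun, res.x
        converged = converged or bool(res.success)

    params = _vector_to_params(best_x, model, config)
    if params is None:  # pragma: no cover - grid points are always valid
        params = _vector_to_params(np.array(evaluated[0][1]), model, config)
    n_free = len(axes)
    # unbiased final evaluation: fresh noise, larger simulation count
    crn_final = _CRNLikelihood(
        trials, config, rng_final, p_plus, config.n_sim_per_trial * config.final_eval_factor
    )
    logl = crn_final.loglik(params)
    return MLFit(
        model=model,
        params=params,
        loglik=float(logl),
        aic=float(2 * n_free - 2 * logl),
        n_free=n_free,
        n_trials=len(trials),
        converged=converged,
    )


def trials_from_dataframe(df, by_response: bool = True, p_plus: float = 0.6):
    """Build accumulator trials from the standard trial table.

    Items are recoded to +1 when supporting the participant's desirable
    state.  Returns ``{(participant_id, response_type): [(d, step), ...]}``
    with ``response_type`` in {"desirable", "undesirable"} (or "all").
    """
    from .task import judged_desirable

    out: dict = {}
    jd = judged_desirable(df)
    for (i, row), j in zip(df.iterrows(), jd):
        # desirable state of this participant on this trial
        ts, des = int(row["true_state"]), int(row["desirability"])
        desirable_state = ts if des == 1 else 1 - ts
        d = np.array([1.0 if ch == str(desirable_state) else -1.0 for ch in str(row["items"])])
        key_resp = ("desirable" if j else "undesirable") if by_response else "all"
        out.setdefault((row["participant_id"], key_resp), []).append((d, int(row["n_samples"])))
    return out
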