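"""Drift-diffusion process with valence-dependent starting point and drift.

The decision variable is a Wiener process with diffusion coefficient 1
between absorbing bounds at 0 and ``a``; the upper bound is the "judged
desirable" response.  The drift magnitude on a trial follows a regression on
the evidence covariate (proportion of seen items consistent with the true
state, centred to [-0.5, 0.5]) and on the desirability of the true state:

    v = beta0 + beta1 * evidence + beta2 * desirability            (additive)
    v = beta0 + beta1 * evidence + beta3 * desirability * evidence (interaction)

The regression drift is symmetric across states: the effective drift toward
the *upper* (desirable) bound is ``+v`` when the true state is desirable and
``-v`` when it is undesirable, so positive evidence always pushes toward the
correct bound, and a positive ``beta2`` strengthens accumulation toward the
desirable conclusion on desirable trials.

Six model specifications combine a free vs fixed (0.5) starting point with
the three drift structures (evidence-only, + desirability, + interaction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DDMParams",
    "ModelSpec",
    "MODEL_SPECS",
    "drift_rate",
    "signed_drift",
    "simulate_trials",
    "simulate_trial",
    "absorption_prob_upper",
]


@dataclass(frozen=True)
class DDMParams:
    """Parameters of one diffusion agent (or one subject's estimates).

    ``z`` and ``sz`` are fractions of the boundary separation ``a``;
    ``z`` is measured toward the desirable (upper) bound.
    """

    a: float = 6.0
    z: float = 0.5
    t0: float = 0.35
    sz: float = 0.1
    beta0: float = 0.0
    beta1: float = 6.0
    beta2: float = 0.0
    beta3: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.a, self.z, self.t0, self.sz, self.beta0, self.beta1, self.beta2, self.beta3)
        if not all(np.isfinite(vals)):
            raise ValueError("non-finite DDM parameter")
        if self.a <= 0:
            raise ValueError("boundary separation a must be > 0")
        if not 0 < self.z < 1:
            raise ValueError("relative starting point z must lie in (0, 1)")
        if self.t0 < 0:
            raise ValueError("non-decision time t0 must be >= 0")
        if self.sz < 0:
            raise ValueError("starting-point range sz must be >= 0")
        if self.z - self.sz / 2 <= 0 or self.z + self.sz / 2 >= 1:
            raise ValueError("z +/- sz/2 must stay inside (0, 1)")


@dataclass(frozen=True)
class ModelSpec:
    """One of the six model specifications.

    ``drift_terms`` is one of ``"evidence"`` (evidence-only),
    ``"desirability"`` (additive valence term beta2) or ``"interaction"``
    (valence x evidence term beta3).
    """

    id: int
    free_z: bool
    drift_terms: str

    @property
    def name(self) -> str:
        z_part = "valence-dependent z" if self.free_z else "z = 0.5"
        return f"spec {self.id} ({z_part}, drift: {self.drift_terms})"

    @property
    def n_group_params(self) -> int:
        n = 5  # a, t0, sz, beta0, beta1
        if self.free_z:
            n += 1
        if self.drift_terms in ("desirability", "interaction"):
            n += 1
        return n


MODEL_SPECS: dict[int, ModelSpec] = {
    1: ModelSpec(1, free_z=False, drift_terms="evidence"),
    2: ModelSpec(2, free_z=False, drift_terms="desirability"),
    3: ModelSpec(3, free_z=True, drift_terms="evidence"),
    4: ModelSpec(4, free_z=True, drift_terms="desirability"),
    5: ModelSpec(5, free_z=False, drift_terms="interaction"),
    6: ModelSpec(6, free_z=True, drift_terms="interaction"),
}


def _check_spec_params(params: DDMParams, spec: ModelSpec) -> None:
    if not spec.free_z and params.z != 0.5:
        raise ValueError(f"{spec.name} fixes z = 0.5 but params.z = {params.z}")
    if spec.drift_terms != "desirability" and params.beta2 != 0.0:
        raise ValueError(f"{spec.name} has no additive desirability term; beta2 must be 0")
    if spec.drift_terms != "interaction" and params.beta3 != 0.0:
        raise ValueError(f"{spec.name} has no interaction term; beta3 must be 0")


def drift_rate(params: DDMParams, spec: ModelSpec, evidence, desirability):
    """Regression drift magnitude v for given evidence and state desirability.

    ``evidence`` is the centred consistent-proportion covariate in
    [-0.5, 0.5]; ``desirability`` is 1 for a desirable true state, 0
    otherwise.  Vectorized over both covariates.
    """
    _check_spec_params(params, spec)
    evidence = np.asarray(evidence, dtype=float)
    desirability = np.asarray(desirability, dtype=float)
    if np.any(evidence < -0.5 - 1e-12) or np.any(evidence > 0.5 + 1e-12):
        raise ValueError("evidence covariate must lie in [-0.5, 0.5]")
    v = params.beta0 + params.beta1 * evidence
    if spec.drift_terms == "desirability":
        v = v + params.beta2 * desirability
    elif spec.drift_terms == "interaction":
        v = v + params.beta3 * desirability * evidence
    return v


def signed_drift(params: DDMParams, spec: ModelSpec, evidence, desirability):
    """Effective drift toward the upper (desirable) bound: +v / -v by state."""
    v = drift_rate(params, spec, evidence, desirability)
    sign = np.where(np.asarray(desirability, dtype=float) > 0, 1.0, -1.0)
    return sign * v


def absorption_prob_upper(v, a, z):
    """Probability of absorption at the upper bound for constant drift.

    Closed form for a Wiener process with drift ``v`` and unit diffusion
    started at ``z * a`` between absorbing bounds {0, a}:
    ``(1 - exp(-2 v z a)) / (1 - exp(-2 v a))``, continuous at v = 0 (-> z).
    """
    v = np.asarray(v, dtype=float)
    a = np.asarray(a, dtype=float)
    z = np.asarray(z, dtype=float)
    small = np.abs(v) < 1e-10
    vv = np.where(small, 1.0, v)
    p = np.where(small, z, -np.expm1(-2.0 * vv * z * a) / -np.expm1(-2.0 * vv * a))
    return p if p.ndim else float(p)


def simulate_trials(
    v_signed,
    a: float,
    z: float,
    t0: float,
    sz: float,
    rng: np.random.Generator,
    dt: float = 1e-3,
    max_t: float = 60.0,
    bridge: bool = True,
    engine: str = "fast",
):
    """Euler-Maruyama first-passage simulation for many trials at once.

    ``v_signed`` is a scalar or 1-D array of per-trial constant drifts
    toward the upper bound (use :func:`simulate_trials_piecewise` for
    drifts that change while the stimulus stream unfolds).

    A Brownian-bridge correction accounts for boundary crossings between
    discrete steps, removing the leading-order discretization bias of the
    first-passage distribution.  ``engine="fast"`` uses the compiled
    per-trial kernel; ``engine="numpy"`` keeps the vectorized reference
    implementation (the two are checked against each other in the tests).

    Returns ``(response, rt, censored)`` where ``response`` is 1 for the
    upper (desirable) bound, ``rt`` includes ``t0`` and ``censored`` flags
    trials that never crossed within ``max_t`` of decision time.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    v = np.atleast_1d(np.asarray(v_signed, dtype=float))
    if not np.all(np.isfinite([a, z, t0, sz])) or not np.all(np.isfinite(v)):
        raise ValueError("non-finite simulation parameter")
    n = v.shape[0]
    x = (z + sz * (rng.random(n) - 0.5)) * a
    if engine == "fast" and bridge:
        from ._fastlik import _HAVE_NUMBA, fp_kernel

        if _HAVE_NUMBA:
            seed = int(rng.integers(0, 2**31 - 1))
            return fp_kernel(np.ascontiguousarray(v), np.ascontiguousarray(x), float(a), float(t0),
                             float(dt), int(np.ceil(max_t / dt)), seed)
    return _run_fp(lambda step, idx: v[idx], x, a, t0, rng, dt, max_t, bridge)


def _run_fp(drift_fn, x0, a, t0, rng, dt, max_t, bridge):
    """Shared first-passage loop over an active set of trials."""
    n = x0.shape[0]
    x = x0.copy()
    rt = np.full(n, np.nan)
    resp = np.zeros(n, dtype=np.int8)
    active = np.arange(n)
    sqdt = np.sqrt(dt)
    n_steps = int(np.ceil(max_t / dt))
    for step in range(n_steps):
        if active.size == 0:
            break
        v_now = drift_fn(step, active)
        x_old = x[active]
        x_new = x_old + v_now * dt + sqdt * rng.standard_normal(active.size)
        t_now = (step + 1) * dt
        hit_up = x_new >= a
        hit_lo = x_new <= 0.0
        if bridge:
            inside = ~(hit_up | hit_lo)
            if np.any(inside):
                xo = x_old[inside]
                xn = x_new[inside]
                with np.errstate(over="ignore", under="ignore"):
                    p_up = np.exp(-2.0 * (a - xo) * (a - xn) / dt)
                    p_lo = np.exp(-2.0 * xo * xn / dt)
                u = rng.random(xo.size)
                crossed_up = u < p_up
                crossed_lo = (u >= p_up) & (u < p_up + p_lo)
                tmp_up = hit_up[inside]
                tmp_lo = hit_lo[inside]
                tmp_up |= crossed_up
                tmp_lo |= crossed_lo
                hit_up[inside] = tmp_up
                hit_lo[inside] = tmp_lo
        done = hit_up | hit_lo
        if np.any(done):
            idx_done = active[done]
            rt[idx_done] = t_now + t0
            resp[idx_done] = hit_up[done].astype(np.int8)
            keep = ~done
            x[active[keep]] = x_new[keep]
            active = active[keep]
        else:
            x[active] = x_new
    censored = np.isnan(rt)
    rt[censored] = max_t + t0
    return resp, rt, censored


def simulate_trials_piecewise(
    drift_schedule: np.ndarray,
    epoch_s: float,
    a: float,
    z: float,
    t0: float,
    sz: float,
    rng: np.random.Generator,
    dt: float = 1e-3,
    max_t: float = 60.0,
    bridge: bool = True,
):
    """First-passage simulation with per-trial drift that switches each epoch.

    ``drift_schedule`` has shape ``(n_trials, n_epochs)``; during decision
    time in ``[k * epoch_s, (k+1) * epoch_s)`` the drift of trial i is
    ``drift_schedule[i, min(k, n_epochs - 1)]``.
    """
    sched = np.asarray(drift_schedule, dtype=float)
    if sched.ndim != 2:
        raise ValueError("drift_schedule must be 2-D (n_trials, n_epochs)")
    if not np.all(np.isfinite(sched)):
        raise ValueError("non-finite drift schedule")
    if not np.all(np.isfinite([a, z, t0, sz])):
        raise ValueError("non-finite simulation parameter")
    n, n_epochs = sched.shape
    steps_per_epoch = max(int(round(epoch_s / dt)), 1)
    x0 = (z + sz * (rng.random(n) - 0.5)) * a
    if bridge:
        from ._fastlik import _HAVE_NUMBA, fp_kernel_piecewise

        if _HAVE_NUMBA:
            seed = int(rng.integers(0, 2**31 - 1))
            return fp_kernel_piecewise(
                np.ascontiguousarray(sched), steps_per_epoch, np.ascontiguousarray(x0),
                float(a), float(t0), float(dt), int(np.ceil(max_t / dt)), seed,
            )

    def drift_fn(step, idx):
        k = min(step // steps_per_epoch, n_epochs - 1)
        return sched[idx, k]

    return _run_fp(drift_fn, x0, a, t0, rng, dt, max_t, bridge)


def simulate_trial(
    params: DDMParams,
    spec: ModelSpec,
    evidence: float,
    desirability: int,
    rng: np.random.Generator,
    dt: float = 1e-3,
    max_t: float = 60.0,
):
    """Simulate a single trial; returns ``(response, rt_s, censored)``."""
    v = signed_drift(params, spec, evidence, desirability)
    resp, rt, cens = simulate_trials(
        np.atleast_1d(v), params.a, params.z, params.t0, params.sz, rng, dt=dt, max_t=max_t
    )
    return int(resp[0]), float(rt[0]), bool(cens[0])
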