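"""Compiled inner loop for the Wiener likelihood.

Same series expansions and starting-point quadrature as
:mod:`valenceddm.wiener`, specialized to the summed log-likelihood of one
subject's trials, which dominates MCMC run time.  The numpy implementation
in :mod:`valenceddm.wiener` is the reference; the two paths are checked
against each other in the test suite.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(11)


@njit(cache=False)
def _point_density(tau: float, a: float, v: float, w: float, err: float) -> float:
    """Lower-bound FPT density, point start; see wiener._density_point."""
    if tau <= 0.0:
        return 0.0
    u = tau / (a * a)
    # term-count bounds for the two series
    ks = 2.0 + math.sqrt(max(-2.0 * u * math.log(2.0 * err * math.sqrt(2.0 * math.pi * u)), 0.0))
    if ks < math.sqrt(u) + 1.0:
        ks = math.sqrt(u) + 1.0
    arg = math.pi * u * err
    if arg < 1.0:
        kl = math.sqrt(max(-2.0 * math.log(arg), 0.0) / (math.pi * math.pi * u))
        lo = 1.0 / (math.pi * math.sqrt(u))
        if kl < lo:
            kl = lo
    else:
        kl = 1.0 / (math.pi * math.sqrt(u))
    if ks < kl:
        K = int(math.ceil(ks))
        lo_k = -((K - 1) // 2)
        hi_k = (K - 1) // 2 + (K - 1) % 2
        acc = 0.0
        for k in range(lo_k, hi_k + 1):
            q = w + 2.0 * k
            acc += q * math.exp(-q * q / (2.0 * u))
        f1 = acc / math.sqrt(2.0 * math.pi * u * u * u)
    else:
        K = int(math.ceil(kl))
        acc = 0.0
        for k in range(1, K + 1):
            acc += k * math.exp(-(k * k) * math.pi * math.pi * u / 2.0) * math.sin(k * math.pi * w)
        f1 = math.pi * acc
    if f1 < 0.0:
        f1 = 0.0
    return f1 * math.exp(-v * a * w - v * v * tau / 2.0) / (a * a)


@njit(cache=False)
def loglik_kernel(
    rt: np.ndarray,
    upper: np.ndarray,
    v: np.ndarray,
    a: float,
    z: float,
    sz: float,
    t0: float,
    nodes: np.ndarray,
    weights: np.ndarray,
    err: float,
) -> float:
    """Summed log density over trials; -inf on any zero-density trial."""
    total = 0.0
    n = rt.shape[0]
    for i in range(n):
        tau = rt[i] - t0
        if tau <= 0.0:
            return -np.inf
        if upper[i]:
            v_eff = -v[i]
            w_c = 1.0 - z
            sgn = -1.0
        else:
            v_eff = v[i]
            w_c = z
            sgn = 1.0
        if sz == 0.0:
            dens = _point_density(tau, a, v_eff, w_c, err)
        else:
            dens = 0.0
            for j in range(nodes.shape[0]):
                w_j = w_c + sgn * sz * nodes[j] / 2.0
                dens += weights[j] / 2.0 * _point_density(tau, a, v_eff, w_j, err)
        if dens <= 0.0:
            return -np.inf
        total += math.log(dens)
    return total


def loglik_sum_fast(rt, upper, v, a, z, sz=0.0, t0=0.0, err=1e-7):
    """Summed Wiener log-likelihood (compiled when numba is available)."""
    rt = np.ascontiguousarray(rt, dtype=np.float64)
    upper = np.ascontiguousarray(upper, dtype=np.bool_)
    v = np.ascontiguousarray(np.broadcast_to(np.asarray(v, dtype=np.float64), rt.shape))
    return float(
        loglik_kernel(rt, upper, v, float(a), float(z), float(sz), float(t0), _GL_NODES, _GL_WEIGHTS, float(err))
    )


@njit(cache=False)
def fp_kernel(v, x0, a, t0, dt, max_steps, seed):
    """First-passage simulation, constant per-trial drift, bridge-corrected.

    The between-step crossing probability exp(-2 d1 d2 / dt) is only
    evaluated when the path is close enough to a bound for it to be
    non-negligible (d1 * d2 < 16 * dt, i.e. p > ~1e-14).
    """
    np.random.seed(seed)
    n = v.shape[0]
    resp = np.zeros(n, dtype=np.int8)
    rt = np.empty(n)
    censored = np.zeros(n, dtype=np.bool_)
    sqdt = math.sqrt(dt)
    near = 16.0 * dt
    for i in range(n):
        x = x0[i]
        vi = v[i]
        done = False
        for step in range(max_steps):
            xn = x + vi * dt + sqdt * np.random.standard_normal()
            if xn >= a:
                resp[i] = 1
                rt[i] = (step + 1) * dt + t0
                done = True
                break
            if xn <= 0.0:
                resp[i] = 0
                rt[i] = (step + 1) * dt + t0
                done = True
                break
            du = (a - x) * (a - xn)
            dl = x * xn
            if du < near or dl < near:
                p_up = math.exp(-2.0 * du / dt) if du < near else 0.0
                p_lo = math.exp(-2.0 * dl / dt) if dl < near else 0.0
                u = np.random.random()
                if u < p_up:
                    resp[i] = 1
                    rt[i] = (step + 1) * dt + t0
                    done = True
                    break
                elif u < p_up + p_lo:
                    resp[i] = 0
                    rt[i] = (step + 1) * dt + t0
                    done = True
                    break
            x = xn
        if not done:
            censored[i] = True
            rt[i] = max_steps * dt + t0
    return resp, rt, censored


@njit(cache=False)
def fp_kernel_piecewise(sched, steps_per_epoch, x0, a, t0, dt, max_steps, seed):
    """As fp_kernel but drift switches every ``steps_per_epoch`` steps."""
    np.random.seed(seed)
    n, n_epochs = sched.shape
    resp = np.zeros(n, dtype=np.int8)
    rt = np.empty(n)
    censored = np.zeros(n, dtype=np.bool_)
    sqdt = math.sqrt(dt)
    near = 16.0 * dt
    for i in range(n):
        x = x0[i]
        done = False
        for step in range(max_steps):
            k = step // steps_per_epoch
            if k >= n_epochs:
                k = n_epochs - 1
            vi = sched[i, k]
            xn = x + vi * dt + sqdt * np.random.standard_normal()
            if xn >= a:
                resp[i] = 1
                rt[i] = (step + 1) * dt + t0
                done = True
                break
            if xn <= 0.0:
                resp[i] = 0
                rt[i] = (step + 1) * dt + t0
                done = True
                break
            du = (a - x) * (a - xn)
            dl = x * xn
            if du < near or dl < near:
                p_up = math.exp(-2.0 * du / dt) if du < near else 0.0
                p_lo = math.exp(-2.0 * dl / dt) if dl < near else 0.0
                u = np.random.random()
                if u < p_up:
                    resp[i] = 1
                    rt[i] = (step + 1) * dt + t0
                    done = True
                    break
                elif u < p_up + p_lo:
                    resp[i] = 0
                    rt[i] = (step + 1) * dt + t0
                    done = True
                    break
            x = xn
        if not done:
            censored[i] = True
            rt[i] = max_steps * dt + t0
    return resp, rt, censored
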