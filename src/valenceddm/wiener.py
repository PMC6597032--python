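"""First-passage-time density of the Wiener diffusion between two absorbing bounds.

The density is evaluated with the classical pair of series expansions
(a small-time expansion in image terms and a large-time eigenfunction
expansion), switching per evaluation point to whichever series needs fewer
terms for a requested truncation error.  Diffusion coefficient is fixed at 1,
so boundary separation ``a``, drift ``v`` and relative start ``z`` are all
expressed in that scale.

Boundary labelling convention: the *upper* boundary is the "judged desirable"
response.  Densities for the upper boundary are obtained from the lower-bound
series by the exact reflection (v, z) -> (-v, 1 - z).

Trial-to-trial uniform jitter of the starting point (range ``sz``, a fraction
of ``a`` like ``z``) is integrated out by fixed-order Gauss-Legendre
quadrature, which is exact enough for the smooth integrand involved and
reduces to the point-start density when ``sz == 0``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fpt_density", "trial_loglik", "loglik_sum"]

# Gauss-Legendre nodes/weights on [-1, 1] for the sz quadrature.
_GL_ORDER = 11
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(_GL_ORDER)


def _f1_lower(u: np.ndarray, w: np.ndarray, err: float) -> np.ndarray:
    """Density of first passage through the lower bound for a = 1, v = 0.

    ``u`` is time in normalized units (t / a^2), ``w`` the relative start.
    Series truncation follows the usual rule: pick the expansion whose
    term-count bound for truncation error ``err`` is smaller.
    """
    u = np.asarray(u, dtype=float)
    w = np.broadcast_to(np.asarray(w, dtype=float), u.shape)
    out = np.zeros(u.shape, dtype=float)
    ok = u > 0
    if not np.any(ok):
        return out
    uu = u[ok]
    ww = w[ok]

    # term-count bounds
    with np.errstate(invalid="ignore"):
        ks = 2.0 + np.sqrt(np.maximum(-2.0 * uu * np.log(2.0 * err * np.sqrt(2.0 * np.pi * uu)), 0.0))
        ks = np.maximum(ks, np.sqrt(uu) + 1.0)
        arg = np.pi * uu * err
        kl = np.where(
            arg < 1.0,
            np.maximum(np.sqrt(np.maximum(-2.0 * np.log(arg), 0.0) / (np.pi**2 * uu)), 1.0 / (np.pi * np.sqrt(uu))),
            1.0 / (np.pi * np.sqrt(uu)),
        )
    small = ks < kl
    res = np.empty(uu.shape, dtype=float)

    if np.any(small):
        us, ws = uu[small], ww[small]
        K = int(np.ceil(ks[small].max()))
        ks_lo = -((K - 1) // 2)
        ks_hi = (K - 1) // 2 + (K - 1) % 2
        acc = np.zeros(us.shape)
        for k in range(ks_lo, ks_hi + 1):
            q = ws + 2.0 * k
            acc += q * np.exp(-q * q / (2.0 * us))
        res[small] = acc / np.sqrt(2.0 * np.pi * us**3)

    large = ~small
    if np.any(large):
        ul, wl = uu[large], ww[large]
        K = int(np.ceil(kl[large].max()))
        acc = np.zeros(ul.shape)
        for k in range(1, K + 1):
            acc += k * np.exp(-(k * k) * np.pi**2 * ul / 2.0) * np.sin(k * np.pi * wl)
        res[large] = np.pi * acc

    out[ok] = np.maximum(res, 0.0)
    return out


def _density_point(tau, a, v, w, err):
    """Lower-bound FPT density at decision time tau for point start w."""
    u = tau / (a * a)
    f1 = _f1_lower(u, w, err)
    with np.errstate(over="ignore", under="ignore"):
        scale = np.exp(-v * a * w - v * v * tau / 2.0) / (a * a)
    return f1 * scale


def fpt_density(rt, response, a, v, z, sz=0.0, t0=0.0, err=1e-7):
    """Defective FPT density (1/s) of hitting a given boundary at ``rt``.

    Parameters
    ----------
    rt : array_like
        Observed response times in seconds (including non-decision time).
    response : array_like of {0, 1}
        1 = upper boundary ("desirable" judgment), 0 = lower boundary.
    a, v, z, sz, t0 : float or array_like broadcastable to ``rt``
        Boundary separation, (signed) drift toward the upper bound, relative
        starting point, starting-point range, non-decision time.
    err : float
        Series truncation error per density evaluation.

    Returns zero density for ``rt <= t0``; the two boundary densities
    integrate jointly to one over decision time.
    """
    rt = np.asarray(rt, dtype=float)
    response = np.asarray(response)
    a = np.asarray(a, dtype=float)
    v = np.asarray(v, dtype=float)
    tau = rt - t0
    upper = response.astype(bool)
    # reflection for the upper bound
    v_eff = np.where(upper, -v, v)
    w_eff_center = np.where(upper, 1.0 - z, z)

    sz = np.asarray(sz, dtype=float)
    if np.all(sz == 0.0):
        dens = _density_point(np.maximum(tau, 0.0), a, v_eff, w_eff_center, err)
    else:
        dens = np.zeros(np.broadcast(tau, v_eff, w_eff_center).shape)
        for node, weight in zip(_GL_NODES, _GL_WEIGHTS):
            w_j = w_eff_center + np.where(upper, -1.0, 1.0) * (sz * node / 2.0)
            dens = dens + (weight / 2.0) * _density_point(np.maximum(tau, 0.0), a, v_eff, w_j, err)
    return np.where(tau > 0.0, dens, 0.0)


def trial_loglik(rt, response, a, v, z, sz=0.0, t0=0.0, err=1e-7):
    """Per-trial log density; ``-inf`` where the density is zero (rt <= t0)."""
    dens = fpt_density(rt, response, a, v, z, sz=sz, t0=t0, err=err)
    with np.errstate(divide="ignore"):
        return np.log(dens)


def loglik_sum(rt, response, a, v, z, sz=0.0, t0=0.0, err=1e-7):
    """Summed log-likelihood over trials (scalar; ``-inf`` if any trial is)."""
    ll = trial_loglik(rt, response, a, v, z, sz=sz, t0=t0, err=err)
    return float(np.sum(ll))
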