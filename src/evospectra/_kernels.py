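"""Compiled inner loop of the GLV integrator.

A Dormand-Prince 5(4) adaptive Runge-Kutta with FSAL, extinction-event
localisation by bisection on the step, truncation of negative biomass
excursions, and an optional convergence check against the analytic
steady state.  Webs are tiny (n of order 10) but single relaxations can
take millions of steps, so the whole stepping loop is jitted.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Terminal statuses of the stepping loop.
STATUS_TMAX = 0  # reached the requested end time
STATUS_EXTINCTION = 1  # some biomass crossed the extinction threshold
STATUS_CONVERGED = 2  # all |S - S*|/S* below the convergence tolerance
STATUS_UNDERFLOW = 3  # step size underflow (integrator failure)
STATUS_MAXSTEPS = 4  # step budget exhausted

_SAFETY = 0.9
_MIN_FACTOR = 0.2
_MAX_FACTOR = 5.0


@njit(cache=True)
def glv_deriv(S, is_prod, alpha, eta, beta, k, out):
    """dS/dt = S * per-capita growth, written into ``out``."""
    n = S.shape[0]
    total_prod = 0.0
    for j in range(n):
        if is_prod[j]:
            total_prod += S[j]
    for i in range(n):
        loss = 0.0
        for j in range(n):
            loss += eta[j, i] * S[j]
        if is_prod[i]:
            f = k * (1.0 - total_prod) - alpha[i] - loss
        else:
            gain = 0.0
            for m in range(n):
                gain += eta[i, m] * S[m]
            f = beta * gain - alpha[i] - loss
        out[i] = S[i] * f
    return out


@njit(cache=True)
def _rk_step(S, is_prod, alpha, eta, beta, k, h, k1, out):
    """One Dormand-Prince step of size ``h`` from ``S`` (k1 = f(S)).

    Writes the 5th-order solution into ``out`` and returns the scaled
    error estimate stage combination in a fresh array (k7 = f(out)).
    """
    n = S.shape[0]
    y = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    k5 = np.empty(n)
    k6 = np.empty(n)
    k7 = np.empty(n)

    for i in range(n):
        y[i] = S[i] + h * 0.2 * k1[i]
    glv_deriv(y, is_prod, alpha, eta, beta, k, k2)
    for i in range(n):
        y[i] = S[i] + h * (3.0 / 40.0 * k1[i] + 9.0 / 40.0 * k2[i])
    glv_deriv(y, is_prod, alpha, eta, beta, k, k3)
    for i in range(n):
        y[i] = S[i] + h * (44.0 / 45.0 * k1[i] - 56.0 / 15.0 * k2[i] + 32.0 / 9.0 * k3[i])
    glv_deriv(y, is_prod, alpha, eta, beta, k, k4)
    for i in range(n):
        y[i] = S[i] + h * (
            19372.0 / 6561.0 * k1[i]
            - 25360.0 / 2187.0 * k2[i]
            + 64448.0 / 6561.0 * k3[i]
            - 212.0 / 729.0 * k4[i]
        )
    glv_deriv(y, is_prod, alpha, eta, beta, k, k5)
    for i in range(n):
        y[i] = S[i] + h * (
            9017.0 / 3168.0 * k1[i]
            - 355.0 / 33.0 * k2[i]
            + 46732.0 / 5247.0 * k3[i]
            + 49.0 / 176.0 * k4[i]
            - 5103.0 / 18656.0 * k5[i]
        )
    glv_deriv(y, is_prod, alpha, eta, beta, k, k6)
    for i in range(n):
        out[i] = S[i] + h * (
            35.0 / 384.0 * k1[i]
            + 500.0 / 1113.0 * k3[i]
            + 125.0 / 192.0 * k4[i]
            - 2187.0 / 6784.0 * k5[i]
            + 11.0 / 84.0 * k6[i]
        )
    glv_deriv(out, is_prod, alpha, eta, beta, k, k7)
    err = np.empty(n)
    for i in range(n):
        err[i] = h * (
            71.0 / 57600.0 * k1[i]
            - 71.0 / 16695.0 * k3[i]
            + 71.0 / 1920.0 * k4[i]
            - 17253.0 / 339200.0 * k5[i]
            + 22.0 / 525.0 * k6[i]
            - 1.0 / 40.0 * k7[i]
        )
    return err, k7


@njit(cache=True)
def _min_biomass(S):
    m = S[0]
    for i in range(1, S.shape[0]):
        if S[i] < m:
            m = S[i]
    return m


@njit(cache=True)
def _locate_extinction(S_prev, is_prod, alpha, eta, beta, k, h, k1, ext_thresh):
    """First fraction of the step at which some biomass hits the threshold.

    Bisection on theta in (0, 1], re-taking a single (error-uncontrolled)
    step of size theta*h from the pre-step state each probe; the step was
    already accepted by the error test so intermediate solutions are
    accurate enough for event localisation.
    """
    n = S_prev.shape[0]
    trial = np.empty(n)
    lo = 0.0
    hi = 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        _rk_step(S_prev, is_prod, alpha, eta, beta, k, mid * h, k1, trial)
        if _min_biomass(trial) <= ext_thresh:
            hi = mid
        else:
            lo = mid
        if (hi - lo) * abs(h) < 1e-12 * max(1.0, abs(h)):
            break
    _rk_step(S_prev, is_prod, alpha, eta, beta, k, hi * h, k1, trial)
    return hi, trial


@njit(cache=True)
def integrate_glv(
    S,
    is_prod,
    alpha,
    eta,
    beta,
    k,
    t0,
    t_end,
    s_star,
    conv_tol,
    check_conv,
    ext_thresh,
    rtol,
    atol,
    max_steps,
):
    """Integrate the GLV system in place from ``t0`` until an event.

    Returns ``(t, status)``; ``S`` holds the terminal biomasses.  When
    ``check_conv`` is true the loop also stops once every species is
    within ``conv_tol`` relative deviation of ``s_star``.
    """
    n = S.shape[0]
    t = t0
    k1 = np.empty(n)
    S_new = np.empty(n)
    glv_deriv(S, is_prod, alpha, eta, beta, k, k1)
    h = min(1e-2, t_end - t0)
    steps = 0
    while t < t_end:
        if h > t_end - t:
            h = t_end - t
        err_arr, k7 = _rk_step(S, is_prod, alpha, eta, beta, k, h, k1, S_new)
        # scaled RMS error
        acc = 0.0
        for i in range(n):
            sc = atol + rtol * max(abs(S[i]), abs(S_new[i]))
            e = err_arr[i] / sc
            acc += e * e
        err = np.sqrt(acc / n)
        if err <= 1.0:
            # accepted
            crossed = _min_biomass(S_new) <= ext_thresh
            if crossed:
                theta, S_event = _locate_extinction(
                    S, is_prod, alpha, eta, beta, k, h, k1, ext_thresh
                )
                for i in range(n):
                    S[i] = max(S_event[i], 0.0)
                return t + theta * h, STATUS_EXTINCTION
            t += h
            for i in range(n):
                S[i] = max(S_new[i], 0.0)
                k1[i] = k7[i]  # FSAL
            if check_conv:
                ok = True
                for i in range(n):
                    if abs(S[i] - s_star[i]) > conv_tol * s_star[i]:
                        ok = False
                        break
                if ok:
                    return t, STATUS_CONVERGED
            if err == 0.0:
                factor = _MAX_FACTOR
            else:
                factor = min(_MAX_FACTOR, max(_MIN_FACTOR, _SAFETY * err ** -0.2))
            h *= factor
        else:
            h *= max(_MIN_FACTOR, _SAFETY * err ** -0.2)
        if h < 1e-13 * max(1.0, abs(t)):
            return t, STATUS_UNDERFLOW
        steps += 1
        if steps >= max_steps:
            return t, STATUS_MAXSTEPS
    return t, STATUS_TMAX
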