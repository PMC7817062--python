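"""Compiled inner loops for the simulators.

Fixed-step integration kernels (classic RK4 for the deterministic and
delayed variants, Euler–Maruyama for the Langevin variant) and the
Gillespie direct method, compiled with numba.  All kernels take the
kinetic constants as scalars; model variants are selected by an integer
code:

``model`` codes: 0 = transition (dX_T/dt = k_X), 1 = oscillator with the
-X^2 term dropped, 2 = oscillator keeping the -X^2 term.

The delayed basal rate a(t) = H(X_T(t - tau)) is evaluated from a cubic
Hermite interpolation of the stored X_T history (constant pre-history).
Setting ``tau = 0`` short-circuits the history lookup so a zero-delay
run is bit-identical to an instantaneous-modulation run.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = [
    "ode_rk4",
    "three_eq_rk4",
    "langevin_em",
    "ssa_direct",
]


@njit(cache=True, inline="always")
def _f_rate(X, a, b, Kn, n):
    # Kn is the precomputed K**n
    if X < 0.0:
        X = 0.0
    Xn = X**n
    return a + b * Xn / (Kn + Xn)


@njit(cache=True, inline="always")
def _g_rate(X, ap, bp, Km, m):
    # Km is the precomputed K'**m
    if X < 0.0:
        X = 0.0
    return ap + bp * Km / (Km + X**m)


@njit(cache=True, inline="always")
def _mod_a(XT, a_bar, da, kappa, Xc):
    return a_bar + da * math.tanh(kappa * (XT - Xc))


@njit(cache=True, inline="always")
def _hist_XT(s, tau, dt, i, XT_hist, dXT_hist, XT0):
    """X_T at time s - tau from the stored step history."""
    sd = s - tau
    if sd <= 0.0:
        return XT0
    jr = sd / dt
    j = int(jr)
    if j >= i:  # beyond the last accepted step: extrapolate linearly
        return XT_hist[i] + (sd - i * dt) * dXT_hist[i]
    th = jr - j
    h00 = (1.0 + 2.0 * th) * (1.0 - th) ** 2
    h10 = th * (1.0 - th) ** 2
    h01 = th * th * (3.0 - 2.0 * th)
    h11 = th * th * (th - 1.0)
    return (
        h00 * XT_hist[j]
        + h10 * dt * dXT_hist[j]
        + h01 * XT_hist[j + 1]
        + h11 * dt * dXT_hist[j + 1]
    )


@njit(cache=True, inline="always")
def _deriv(model, X, XT, a, b, Kn, n, ap, bp, Km, m, eps, k_X):
    f = _f_rate(X, a, b, Kn, n)
    g = _g_rate(X, ap, bp, Km, m)
    dX = (f * (XT - X) - g * X) / eps
    if model == 2:
        dX -= X * X
    if model == 0:
        dXT = k_X
    else:
        dXT = k_X - XT * X
    return dX, dXT


@njit(cache=True)
def ode_rk4(
    model,
    b, K, n, ap, bp, Kp, m, eps,
    a_bar, da, kappa, Xc, tau,
    k_X,
    X0, XT0,
    dt, nsteps, store_every,
):
    """RK4 integration of the two-variable models, optional delayed a.

    Returns (t_out, X_out, XT_out, a_out) sampled every ``store_every``
    steps (first and last point always included).
    """
    K = K**n   # precompute Hill denominators; only the powers are used
    Kp = Kp**m
    nout = nsteps // store_every + 1
    t_out = np.empty(nout)
    X_out = np.empty(nout)
    XT_out = np.empty(nout)
    a_out = np.empty(nout)

    XT_hist = np.empty(nsteps + 1)
    dXT_hist = np.empty(nsteps + 1)

    X = X0
    XT = XT0
    XT_hist[0] = XT0
    if tau > 0.0:
        a0 = _mod_a(XT0, a_bar, da, kappa, Xc)
    else:
        a0 = _mod_a(XT0, a_bar, da, kappa, Xc)
    dX0, dXT0 = _deriv(model, X, XT, a0, b, K, n, ap, bp, Kp, m, eps, k_X)
    dXT_hist[0] = dXT0

    t_out[0] = 0.0
    X_out[0] = X
    XT_out[0] = XT
    a_out[0] = a0
    iout = 1

    for i in range(nsteps):
        t = i * dt
        if tau > 0.0:
            a1 = _mod_a(_hist_XT(t, tau, dt, i, XT_hist, dXT_hist, XT0), a_bar, da, kappa, Xc)
            ah = _mod_a(_hist_XT(t + 0.5 * dt, tau, dt, i, XT_hist, dXT_hist, XT0), a_bar, da, kappa, Xc)
            a4 = _mod_a(_hist_XT(t + dt, tau, dt, i, XT_hist, dXT_hist, XT0), a_bar, da, kappa, Xc)
            k1x, k1t = _deriv(model, X, XT, a1, b, K, n, ap, bp, Kp, m, eps, k_X)
            k2x, k2t = _deriv(model, X + 0.5 * dt * k1x, XT + 0.5 * dt * k1t, ah, b, K, n, ap, bp, Kp, m, eps, k_X)
            k3x, k3t = _deriv(model, X + 0.5 * dt * k2x, XT + 0.5 * dt * k2t, ah, b, K, n, ap, bp, Kp, m, eps, k_X)
            k4x, k4t = _deriv(model, X + dt * k3x, XT + dt * k3t, a4, b, K, n, ap, bp, Kp, m, eps, k_X)
        else:
            a1 = _mod_a(XT, a_bar, da, kappa, Xc)
            k1x, k1t = _deriv(model, X, XT, a1, b, K, n, ap, bp, Kp, m, eps, k_X)
            XT2 = XT + 0.5 * dt * k1t
            a2 = _mod_a(XT2, a_bar, da, kappa, Xc)
            k2x, k2t = _deriv(model, X + 0.5 * dt * k1x, XT2, a2, b, K, n, ap, bp, Kp, m, eps, k_X)
            XT3 = XT + 0.5 * dt * k2t
            a3 = _mod_a(XT3, a_bar, da, kappa, Xc)
            k3x, k3t = _deriv(model, X + 0.5 * dt * k2x, XT3, a3, b, K, n, ap, bp, Kp, m, eps, k_X)
            XT4 = XT + dt * k3t
            a4 = _mod_a(XT4, a_bar, da, kappa, Xc)
            k4x, k4t = _deriv(model, X + dt * k3x, XT4, a4, b, K, n, ap, bp, Kp, m, eps, k_X)
        X = X + dt * (k1x + 2.0 * k2x + 2.0 * k3x + k4x) / 6.0
        XT = XT + dt * (k1t + 2.0 * k2t + 2.0 * k3t + k4t) / 6.0
        if not (math.isfinite(X) and math.isfinite(XT)):
            # blow-up guard: truncate output at the last finite sample
            for j in range(iout, nout):
                t_out[j] = np.nan
                X_out[j] = np.nan
                XT_out[j] = np.nan
                a_out[j] = np.nan
            return t_out, X_out, XT_out, a_out
        XT_hist[i + 1] = XT
        dX_end, dXT_end = _deriv(
            model, X, XT,
            _mod_a(XT, a_bar, da, kappa, Xc) if tau == 0.0
            else _mod_a(_hist_XT((i + 1) * dt, tau, dt, i, XT_hist, dXT_hist, XT0), a_bar, da, kappa, Xc),
            b, K, n, ap, bp, Kp, m, eps, k_X,
        )
        dXT_hist[i + 1] = dXT_end
        if (i + 1) % store_every == 0:
            t_out[iout] = (i + 1) * dt
            X_out[iout] = X
            XT_out[iout] = XT
            if tau > 0.0:
                a_out[iout] = _mod_a(
                    _hist_XT((i + 1) * dt, tau, dt, i + 1, XT_hist, dXT_hist, XT0),
                    a_bar, da, kappa, Xc,
                )
            else:
                a_out[iout] = _mod_a(XT, a_bar, da, kappa, Xc)
            iout += 1
    return t_out[:iout], X_out[:iout], XT_out[:iout], a_out[:iout]


@njit(cache=True)
def three_eq_rk4(
    b, K, n, ap, bp, Kp, m, eps,
    a_bar, da, kappa, Xc,
    k_X, delta,
    X0, XT0, a0,
    dt, nsteps, store_every,
):
    """RK4 for the three-variable model with slowly relaxing basal rate."""
    K = K**n
    Kp = Kp**m
    nout = nsteps // store_every + 1
    t_out = np.empty(nout)
    X_out = np.empty(nout)
    XT_out = np.empty(nout)
    a_out = np.empty(nout)

    X = X0
    XT = XT0
    a = a0
    t_out[0] = 0.0
    X_out[0] = X
    XT_out[0] = XT
    a_out[0] = a
    iout = 1
    inv_delta = 1.0 / delta
    for i in range(nsteps):
        k1x, k1t = _deriv(1, X, XT, a, b, K, n, ap, bp, Kp, m, eps, k_X)
        k1a = (_mod_a(XT, a_bar, da, kappa, Xc) - a) * inv_delta
        X2 = X + 0.5 * dt * k1x
        XT2 = XT + 0.5 * dt * k1t
        a2 = a + 0.5 * dt * k1a
        k2x, k2t = _deriv(1, X2, XT2, a2, b, K, n, ap, bp, Kp, m, eps, k_X)
        k2a = (_mod_a(XT2, a_bar, da, kappa, Xc) - a2) * inv_delta
        X3 = X + 0.5 * dt * k2x
        XT3 = XT + 0.5 * dt * k2t
        a3 = a + 0.5 * dt * k2a
        k3x, k3t = _deriv(1, X3, XT3, a3, b, K, n, ap, bp, Kp, m, eps, k_X)
        k3a = (_mod_a(XT3, a_bar, da, kappa, Xc) - a3) * inv_delta
        X4 = X + dt * k3x
        XT4 = XT + dt * k3t
        a4 = a + dt * k3a
        k4x, k4t = _deriv(1, X4, XT4, a4, b, K, n, ap, bp, Kp, m, eps, k_X)
        k4a = (_mod_a(XT4, a_bar, da, kappa, Xc) - a4) * inv_delta
        X = X + dt * (k1x + 2 * k2x + 2 * k3x + k4x) / 6.0
        XT = XT + dt * (k1t + 2 * k2t + 2 * k3t + k4t) / 6.0
        a = a + dt * (k1a + 2 * k2a + 2 * k3a + k4a) / 6.0
        if not (math.isfinite(X) and math.isfinite(XT) and math.isfinite(a)):
            for j in range(iout, nout):
                t_out[j] = np.nan
                X_out[j] = np.nan
                XT_out[j] = np.nan
                a_out[j] = np.nan
            return t_out, X_out, XT_out, a_out
        if (i + 1) % store_every == 0:
            t_out[iout] = (i + 1) * dt
            X_out[iout] = X
            XT_out[iout] = XT
            a_out[iout] = a
            iout += 1
    return t_out[:iout], X_out[:iout], XT_out[:iout], a_out[:iout]


@njit(cache=True)
def langevin_em(
    model,
    b, K, n, ap, bp, Kp, m, eps,
    a_bar, da, kappa, Xc,
    k_X, sigma,
    X0, XT0,
    dt, nsteps, store_every, seed,
):
    """Stochastic Heun scheme for the Langevin variants.

    Noise of magnitude ``sigma`` enters the fast variable only (additive,
    so the predictor-corrector drift keeps strong order and reduces to a
    second-order deterministic scheme at sigma = 0); X_T evolves
    deterministically.  X is clipped at zero to keep the concentration
    physical.
    """
    np.random.seed(seed)
    K = K**n
    Kp = Kp**m
    nout = nsteps // store_every + 1
    t_out = np.empty(nout)
    X_out = np.empty(nout)
    XT_out = np.empty(nout)

    X = X0
    XT = XT0
    t_out[0] = 0.0
    X_out[0] = X
    XT_out[0] = XT
    iout = 1
    sqdt = math.sqrt(dt)
    for i in range(nsteps):
        a = _mod_a(XT, a_bar, da, kappa, Xc)
        dX1, dXT1 = _deriv(model, X, XT, a, b, K, n, ap, bp, Kp, m, eps, k_X)
        if sigma > 0.0:
            dW = sigma * sqdt * np.random.normal()
        else:
            dW = 0.0
        Xp = X + dt * dX1 + dW
        XTp = XT + dt * dXT1
        ap2 = _mod_a(XTp, a_bar, da, kappa, Xc)
        dX2, dXT2 = _deriv(model, Xp, XTp, ap2, b, K, n, ap, bp, Kp, m, eps, k_X)
        X = X + 0.5 * dt * (dX1 + dX2) + dW
        XT = XT + 0.5 * dt * (dXT1 + dXT2)
        if X < 0.0:
            X = 0.0
        if (i + 1) % store_every == 0:
            t_out[iout] = (i + 1) * dt
            X_out[iout] = X
            XT_out[iout] = XT
            iout += 1
    return t_out[:iout], X_out[:iout], XT_out[:iout]


@njit(cache=True)
def ssa_direct(
    include_degradation,
    b, K, n, ap, bp, Kp, m, eps,
    a_bar, da, kappa, Xc,
    k_X, omega,
    nX0, nY0,
    t_end, dt_out, seed,
):
    """Gillespie direct method for the molecule-count model.

    Reactions: activation Y->X at (1/eps) f(n_X) n_Y, inactivation X->Y
    at (1/eps) g(n_X) n_X, production 0->Y at k_X * Omega, and (for the
    oscillator) degradation of inactive protein at n_X n_Y / Omega and of
    active protein at n_X (n_X - 1) / Omega.  Each degradation event
    removes one molecule of the degraded species; the active protein
    acts catalytically.  Concentration-scale constants are multiplied by
    Omega, 1/concentration constants divided by Omega.  The modulated
    basal rate uses a = a_bar + da * tanh((kappa/Omega)(n_X + n_Y -
    Omega * X_c)).

    The state is sampled onto a regular grid of spacing ``dt_out``
    (previous-value interpolation, as the state is piecewise constant).
    """
    np.random.seed(seed)
    nout = int(t_end / dt_out) + 1
    t_out = np.empty(nout)
    nX_out = np.empty(nout, dtype=np.int64)
    nY_out = np.empty(nout, dtype=np.int64)
    for j in range(nout):
        t_out[j] = j * dt_out

    OK = omega * K
    OKp = omega * Kp
    kap = kappa / omega
    OXc = omega * Xc

    nX = nX0
    nY = nY0
    t = 0.0
    iout = 0
    while True:
        a = a_bar + da * math.tanh(kap * (nX + nY - OXc))
        fX = float(nX)
        fn = fX**n
        p1 = (a + b * fn / (OK**n + fn)) * nY / eps
        gm = OKp**m
        p2 = (ap + bp * gm / (gm + fX**m)) * nX / eps
        p3 = k_X * omega
        if include_degradation:
            p4 = nX * nY / omega
            p5 = nX * (nX - 1.0) / omega
        else:
            p4 = 0.0
            p5 = 0.0
        ptot = p1 + p2 + p3 + p4 + p5
        if ptot <= 0.0:
            break
        t_next = t + np.random.exponential(1.0 / ptot)
        while iout < nout and t_out[iout] < t_next:
            nX_out[iout] = nX
            nY_out[iout] = nY
            iout += 1
        if iout >= nout or t_next > t_end:
            break
        t = t_next
        r = np.random.random() * ptot
        if r < p1:
            nX += 1
            nY -= 1
        elif r < p1 + p2:
            nX -= 1
            nY += 1
        elif r < p1 + p2 + p3:
            nY += 1
        elif r < p1 + p2 + p3 + p4:
            nY -= 1
        else:
            nX -= 1
    while iout < nout:
        nX_out[iout] = nX
        nY_out[iout] = nY
        iout += 1
    return t_out, nX_out, nY_out
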