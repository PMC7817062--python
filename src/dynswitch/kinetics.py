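"""Rate laws and right-hand sides of the non-spatial deterministic models.

Three model variants share the same scalar kinetics
``F(X; X_T, a) = f(X)(X_T - X) - g(X) X``:

* ``transition``: total protein accumulates linearly, ``dX_T/dt = k_X``.
* ``oscillator``: production balanced by active-form-driven degradation,
  ``dX_T/dt = k_X - X_T X``.  By default the ``-X^2`` degradation term in
  the fast equation is dropped so the static response curve is exactly a
  nullcline; the full variant keeps it.
* ``three_equation``: the modulation target is tracked by a relaxation
  equation ``da/dt = (H(X_T) - a) / delta`` instead of instantaneously.

All right-hand sides take the state as a plain sequence so they can be
handed directly to ODE integrators.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .params import FeedbackParams, SwitchModulation

__all__ = [
    "activation_rate",
    "inactivation_rate",
    "modulated_a",
    "rhs_transition",
    "rhs_oscillator",
    "rhs_three_equation",
]


def _check_nonnegative(X) -> None:
    if np.any(np.asarray(X) < 0):
        raise ValueError("concentration X must be >= 0")


def activation_rate(X, params: FeedbackParams, a_value: Optional[float] = None):
    """Activation rate f(X) = a + b X^n / (K^n + X^n).

    ``a_value`` overrides the basal rate stored in ``params`` so that
    static, instantaneously modulated, delayed and slowly relaxing
    basal rates all go through the same code path.  Accepts scalars or
    arrays; strictly increasing in X and bounded by ``a_value + b``.
    """
    _check_nonnegative(X)
    a = params.a if a_value is None else a_value
    Xn = np.power(X, params.n)
    return a + params.b * Xn / (params.K**params.n + Xn)


def inactivation_rate(X, params: FeedbackParams):
    """Inactivation rate g(X) = a' + b' K'^m / (K'^m + X^m).

    Strictly decreasing in X, decaying from ``a' + b'`` at X = 0 to the
    residual rate ``a'``.
    """
    _check_nonnegative(X)
    Km = params.K_prime**params.m
    return params.a_prime + params.b_prime * Km / (Km + np.power(X, params.m))


def modulated_a(X_T, mod: SwitchModulation):
    """Dynamic basal activation rate a(X_T) = a_bar + Δa tanh(κ(X_T - X_c))."""
    return mod.a_bar + mod.delta_a * np.tanh(mod.kappa * (np.asarray(X_T) - mod.X_c))


def _resolve_a(X_T: float, params: FeedbackParams, mod: Optional[SwitchModulation]):
    return params.a if mod is None else modulated_a(X_T, mod)


def _fast_term(X: float, X_T: float, params: FeedbackParams, a_value: float) -> float:
    """f(X)(X_T - X) - g(X) X, with X clipped at 0 before the powers."""
    Xc = max(X, 0.0)
    f = activation_rate(Xc, params, a_value)
    g = inactivation_rate(Xc, params)
    return f * (X_T - X) - g * X


def rhs_transition(
    state: Sequence[float],
    params: FeedbackParams,
    mod: Optional[SwitchModulation] = None,
    k_X: float = 0.2,
) -> np.ndarray:
    """Time derivative of (X, X_T) for the transition model.

    dX/dt = ε⁻¹ (f(X)(X_T − X) − g(X) X),  dX_T/dt = k_X.  When ``mod``
    is given, the basal rate follows a(X_T) instantaneously.
    """
    X, X_T = state[0], state[1]
    a = _resolve_a(X_T, params, mod)
    return np.array([_fast_term(X, X_T, params, a) / params.epsilon, k_X])


def rhs_oscillator(
    state: Sequence[float],
    params: FeedbackParams,
    mod: Optional[SwitchModulation] = None,
    k_X: float = 1.7,
    full_model: bool = False,
) -> np.ndarray:
    """Time derivative of (X, X_T) for the production/degradation model.

    dX_T/dt = k_X − X_T X.  With ``full_model`` the fast equation keeps
    the −X² loss of active protein to degradation; otherwise that term is
    dropped, which only perturbs the switch shape at O(ε) (it can be
    absorbed into g as g + εX).
    """
    X, X_T = state[0], state[1]
    a = _resolve_a(X_T, params, mod)
    dX = _fast_term(X, X_T, params, a) / params.epsilon
    if full_model:
        dX -= X * X
    return np.array([dX, k_X - X_T * X])


def rhs_three_equation(
    state: Sequence[float],
    params: FeedbackParams,
    mod: SwitchModulation,
    k_X: float = 1.7,
    delta: float = 1.0,
) -> np.ndarray:
    """Time derivative of (X, X_T, a) with a slowly relaxing basal rate.

    The basal rate relaxes towards H(X_T) = a_bar + Δa tanh(κ(X_T − X_c))
    on timescale ``delta``: da/dt = δ⁻¹ (H(X_T) − a).  As δ → 0 this
    reduces to the two-equation oscillator with instantaneous modulation.
    """
    if not delta > 0:
        raise ValueError(f"relaxation timescale delta must be > 0, got {delta}")
    X, X_T, a = state[0], state[1], state[2]
    dX = _fast_term(X, X_T, params, a) / params.epsilon
    target = modulated_a(X_T, mod)
    return np.array([dX, k_X - X_T * X, (target - a) / delta])
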