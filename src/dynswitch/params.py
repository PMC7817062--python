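"""Parameter containers for the bistable-switch models.

The core model describes a protein that interconverts between an active
form (concentration ``X``) and an inactive form, with total concentration
``X_T``.  Activation is autocatalytic and inactivation is suppressed by
the active form, both through Hill kinetics; together these feedbacks make
the steady-state response of ``X`` to ``X_T`` (or to the basal activation
rate ``a``) bistable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

__all__ = [
    "FeedbackParams",
    "SwitchModulation",
    "SystemState",
    "STANDARD_PARAMS",
]


@dataclass(frozen=True)
class FeedbackParams:
    """Constants of the activation/inactivation rate laws.

    The activation rate is ``f(X) = a + b X^n / (K^n + X^n)`` and the
    inactivation rate is ``g(X) = a' + b' K'^m / (K'^m + X^m)``.  The
    factor ``epsilon`` sets the timescale separation between the fast
    activation/inactivation dynamics and slow changes in total protein.

    Units: rates (``a``, ``b``, ``a_prime``, ``b_prime``) are 1/time,
    half-saturation constants (``K``, ``K_prime``) are concentrations,
    Hill exponents (``n``, ``m``) and ``epsilon`` are dimensionless.
    """

    a: float = 0.3
    b: float = 1.0
    K: float = 1.0
    n: float = 5.0
    a_prime: float = 0.1
    b_prime: float = 1.0
    K_prime: float = 1.0
    m: float = 5.0
    epsilon: float = 0.05

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError(f"basal activation rate a must be >= 0, got {self.a}")
        for name in ("b", "K", "a_prime", "b_prime", "K_prime", "epsilon"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if self.n < 1 or self.m < 1:
            raise ValueError("Hill exponents n, m must be >= 1")
        if self.epsilon > 1:
            raise ValueError(f"epsilon must be <= 1, got {self.epsilon}")

    def with_a(self, a: float) -> "FeedbackParams":
        """Copy of these parameters with a different basal activation rate."""
        return replace(self, a=a)


#: Standard feedback constants used throughout unless stated otherwise
#: (b = K = b' = K' = 1, n = m = 5, a' = 0.1, epsilon = 0.05), with the
#: reference basal activation rate a = 0.3.
STANDARD_PARAMS = FeedbackParams()


@dataclass(frozen=True)
class SwitchModulation:
    """Law coupling the basal activation rate ``a`` to total protein.

    ``a(X_T) = a_bar + delta_a * tanh(kappa * (X_T - X_c))``, optionally
    evaluated with a time lag ``tau`` so that ``a(t)`` follows
    ``X_T(t - tau)``.  ``delta_a`` sets the modulation amplitude (it may
    be negative, which moves the activation threshold away from an
    approaching ``X_T``), ``kappa`` the steepness, and ``X_c`` the
    midpoint, conventionally the middle of the saddle-node ``X_T``
    coordinates of the static switch at ``a = a_bar``.
    """

    a_bar: float = 0.3
    delta_a: float = 0.0
    kappa: float = 5.0
    X_c: float = 0.0
    tau: float = 0.0

    def __post_init__(self) -> None:
        if not self.a_bar > 0:
            raise ValueError(f"a_bar must be > 0, got {self.a_bar}")
        if self.tau < 0:
            raise ValueError(f"delay tau must be >= 0, got {self.tau}")

    def __call__(self, X_T: float) -> float:
        """Evaluate a(X_T)."""
        from .kinetics import modulated_a

        return modulated_a(X_T, self)


@dataclass
class SystemState:
    """Instantaneous state of a non-spatial model variant.

    ``a_slow`` is only meaningful for the three-equation model, where the
    modulation relaxes towards its target instead of tracking it
    instantaneously.
    """

    X: float
    X_T: float
    a_slow: Optional[float] = None
    t: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.X) and math.isfinite(self.X_T)):
            raise ValueError("state must be finite")
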