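"""Two-compartment (nucleus/cytoplasm) model of mitotic entry.

Cdk1 bound to Cyclin B is activated by the phosphatase Cdc25 and
inhibited by the kinase Wee1; Cdk1 in turn activates Cdc25 and
inactivates Wee1, closing double-positive and double-negative feedback
loops that make the steady-state Cdk1 activity bistable in total
Cyclin B.  Here each compartment carries its own copy of that switch,
with fixed Wee1 levels (higher in the nucleus) and a shuttling pool of
Cdc25, so each compartment has its own instantaneous response curve
whose shape changes as Cdc25 relocalizes:

* Cyclin B–Cdk1 is synthesized in the cytoplasm only (rate ``k_s``).
* Nuclear import of Cyclin B–Cdk1 is enhanced by active nuclear Cdk1,
  import of Cdc25 by active cytoplasmic Cdk1 (linear modulation factors
  ``I_Cyc = 0.1 + c_cyc * Cdk1_n`` and ``I_Cdc = 1 + c_cdc * Cdk1_c``).
* Cdk1 activation scales with the compartment's Cdc25 level times a
  Cdk1-dependent Hill activity; inactivation with the Wee1 level times
  a decreasing Hill activity.

Because the cytoplasm starts with more Cdc25 and less Wee1, its
activation threshold is lower: Cdk1 activates there first, the jump
boosts Cdc25 import, the nuclear threshold drops, and nuclear Cdk1
activation follows — after which enhanced Cyclin import keeps nuclear
activity rising while cytoplasmic activity plateaus.

Concentrations are in nM (Cdc25 and Wee1 are scaled levels, 1 = the
reference level), time in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .continuation import ResponseCurve, switch_folds_exact, trace_response_curve
from .dynamics import Trajectory
from .params import FeedbackParams

__all__ = [
    "MitoticParams",
    "CompartmentState",
    "import_modulation",
    "rhs_mitotic",
    "simulate_mitotic_entry",
    "instantaneous_response_curve",
    "compartment_feedback_params",
]


@dataclass(frozen=True)
class MitoticParams:
    """Rate constants of the two-compartment mitotic-entry model.

    The Cdc25/Wee1 Hill constants follow the classic Cdk1-oscillator
    parameterization (basal and maximal activities in 1/min, EC50s in
    nM, steep activation and shallower inhibition); Wee1 levels are
    fixed, higher in the nucleus.  Import/export rates (1/min) are slow
    compared with the activation kinetics so each compartment stays
    near its instantaneous response curve; the subscript of a transport
    rate names the destination compartment.
    """

    k_s: float = 1.5
    wee1_n: float = 1.3
    wee1_c: float = 1.0
    a_cdc25: float = 0.16
    b_cdc25: float = 0.8
    K_cdc25: float = 35.0
    m_cdc25: float = 11.0
    a_wee1: float = 0.08
    b_wee1: float = 0.4
    K_wee1: float = 30.0
    m_wee1: float = 3.5
    kn_cyc: float = 0.2
    kc_cyc: float = 0.1
    kn_cdc: float = 0.05
    kc_cdc: float = 0.1
    c_cyc: float = 1.0 / 30.0
    c_cdc: float = 1.0 / 60.0

    def __post_init__(self) -> None:
        for name in (
            "k_s", "wee1_n", "wee1_c", "a_cdc25", "b_cdc25", "K_cdc25",
            "m_cdc25", "a_wee1", "b_wee1", "K_wee1", "m_wee1",
            "kn_cyc", "kc_cyc", "kn_cdc", "kc_cdc", "c_cyc", "c_cdc",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not self.wee1_n > self.wee1_c:
            raise ValueError("the model assumes Wee1_n > Wee1_c")


@dataclass
class CompartmentState:
    """Nuclear/cytoplasmic concentrations: total Cyclin B–Cdk1, active
    Cdk1 and the (scaled) Cdc25 level."""

    cyc_n: float = 0.0
    cyc_c: float = 0.0
    cdk1_n: float = 0.0
    cdk1_c: float = 0.0
    cdc25_n: float = 1.0
    cdc25_c: float = 2.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.cyc_n, self.cyc_c, self.cdk1_n, self.cdk1_c,
             self.cdc25_n, self.cdc25_c]
        )


_FIELDS = ["cyc_n", "cyc_c", "cdk1_n", "cdk1_c", "cdc25_n", "cdc25_c"]


def import_modulation(cdk1: float, which: str, params: MitoticParams = MitoticParams()):
    """Import-rate multiplier: I_Cyc(Cdk1_n) = 0.1 + c_cyc Cdk1_n,
    I_Cdc(Cdk1_c) = 1 + c_cdc Cdk1_c; both strictly increasing."""
    if which == "Cyc":
        return 0.1 + params.c_cyc * np.asarray(cdk1)
    if which == "Cdc":
        return 1.0 + params.c_cdc * np.asarray(cdk1)
    raise ValueError("which must be 'Cyc' or 'Cdc'")


def _cdc25_activity(cdk1: float, p: MitoticParams) -> float:
    h = max(cdk1, 0.0) ** p.m_cdc25
    return p.a_cdc25 + p.b_cdc25 * h / (p.K_cdc25**p.m_cdc25 + h)


def _wee1_activity(cdk1: float, p: MitoticParams) -> float:
    Km = p.K_wee1**p.m_wee1
    return p.a_wee1 + p.b_wee1 * Km / (Km + max(cdk1, 0.0) ** p.m_wee1)


def rhs_mitotic(state, params: MitoticParams) -> np.ndarray:
    """Time derivative of (Cyc_n, Cyc_c, Cdk1_n, Cdk1_c, Cdc25_n, Cdc25_c).

    Synthesis of active complexes occurs in the cytoplasm only; Cyclin
    B–Cdk1 and Cdk1 move with the same transport rates, Cdc25 with its
    own; total Cdc25 is conserved by construction and total Cyclin
    grows exactly at k_s.
    """
    cyc_n, cyc_c, cdk1_n, cdk1_c, cdc25_n, cdc25_c = state
    p = params

    imp_cyc = p.kn_cyc * float(import_modulation(cdk1_n, "Cyc", p))
    imp_cdc = p.kn_cdc * float(import_modulation(cdk1_c, "Cdc", p))

    act_n = cdc25_n * _cdc25_activity(cdk1_n, p) * (cyc_n - cdk1_n)
    act_c = cdc25_c * _cdc25_activity(cdk1_c, p) * (cyc_c - cdk1_c)
    inact_n = p.wee1_n * _wee1_activity(cdk1_n, p) * cdk1_n
    inact_c = p.wee1_c * _wee1_activity(cdk1_c, p) * cdk1_c

    d_cyc_n = imp_cyc * cyc_c - p.kc_cyc * cyc_n
    d_cyc_c = -imp_cyc * cyc_c + p.kc_cyc * cyc_n + p.k_s
    d_cdk1_n = imp_cyc * cdk1_c - p.kc_cyc * cdk1_n + act_n - inact_n
    d_cdk1_c = -imp_cyc * cdk1_c + p.kc_cyc * cdk1_n + p.k_s + act_c - inact_c
    d_cdc25_n = imp_cdc * cdc25_c - p.kc_cdc * cdc25_n
    d_cdc25_c = -imp_cdc * cdc25_c + p.kc_cdc * cdc25_n

    return np.array([d_cyc_n, d_cyc_c, d_cdk1_n, d_cdk1_c, d_cdc25_n, d_cdc25_c])


def compartment_feedback_params(
    cdc25_level: float, wee1_level: float, params: MitoticParams = MitoticParams()
) -> FeedbackParams:
    """Map one compartment's instantaneous kinetics onto the generic
    activation/inactivation form.

    With Cdc25 and Wee1 levels held fixed, dCdk1/dt = Cdc25 * phi(Cdk1)
    (Cyc - Cdk1) - Wee1 * psi(Cdk1) Cdk1 has exactly the structure
    f(X)(X_T - X) - g(X) X, so the continuation machinery applies with
    rescaled Hill constants.
    """
    p = params
    return FeedbackParams(
        a=cdc25_level * p.a_cdc25,
        b=cdc25_level * p.b_cdc25,
        K=p.K_cdc25,
        n=p.m_cdc25,
        a_prime=wee1_level * p.a_wee1,
        b_prime=wee1_level * p.b_wee1,
        K_prime=p.K_wee1,
        m=p.m_wee1,
        epsilon=1.0,
    )


def _jump_threshold(
    cdc25_level: float, wee1_level: float, params: MitoticParams
) -> Optional[float]:
    """Transition threshold for one compartment: the average vertical
    (Cdk1) coordinate of the saddle nodes of its instantaneous response
    curve; None if that curve is monotone."""
    fp = compartment_feedback_params(cdc25_level, wee1_level, params)
    folds = switch_folds_exact(fp, X_max=500.0, n_grid=4000)
    if len(folds) != 2:
        return None
    return 0.5 * (folds[0].X + folds[1].X)


def simulate_mitotic_entry(
    params: MitoticParams = MitoticParams(),
    initial: Optional[CompartmentState] = None,
    t_end: float = 120.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_out: int = 2000,
) -> Tuple[Trajectory, Dict[str, Optional[float]]]:
    """Integrate the model and detect the compartmental activation jumps.

    Jump times are the first crossings of each compartment's Cdk1
    activity above its transition threshold, computed from that
    compartment's instantaneous response curve at t = 0.  Returns the
    trajectory and an event dictionary with the thresholds and jump
    times (None where no jump occurs).
    """
    if initial is None:
        initial = CompartmentState()
    t_eval = np.linspace(0.0, t_end, n_out)
    sol = solve_ivp(
        lambda t, y: rhs_mitotic(y, params),
        (0.0, t_end),
        initial.as_array(),
        method="LSODA",
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
    )
    if not sol.success:
        raise RuntimeError(f"mitotic-entry integration failed: {sol.message}")
    data = {name: sol.y[i] for i, name in enumerate(_FIELDS)}
    traj = Trajectory(times=sol.t, data=data, metadata={"model": "mitotic_entry",
                                                        "params": params})

    thr_n = _jump_threshold(initial.cdc25_n, params.wee1_n, params)
    thr_c = _jump_threshold(initial.cdc25_c, params.wee1_c, params)
    events: Dict[str, Optional[float]] = {
        "threshold_nucleus": thr_n,
        "threshold_cytoplasm": thr_c,
        "t_jump_nucleus": _first_crossing(sol.t, data["cdk1_n"], thr_n),
        "t_jump_cytoplasm": _first_crossing(sol.t, data["cdk1_c"], thr_c),
    }
    return traj, events


def _first_crossing(t: np.ndarray, x: np.ndarray, level: Optional[float]) -> Optional[float]:
    if level is None:
        return None
    above = x >= level
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    frac = (level - x[i - 1]) / (x[i] - x[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def instantaneous_response_curve(
    state: CompartmentState,
    compartment: str,
    params: MitoticParams = MitoticParams(),
    cyc_max: float = 120.0,
) -> ResponseCurve:
    """Steady-state Cdk1 versus total Cyclin B for one compartment.

    Holds the compartment's current Cdc25 and Wee1 levels fixed
    (quasi-steady-state view: transport is slow against activation) and
    traces the response curve by continuation.  A non-bistable snapshot
    yields a monotone curve with zero folds.
    """
    if compartment == "nucleus":
        cdc25, wee1 = state.cdc25_n, params.wee1_n
    elif compartment == "cytoplasm":
        cdc25, wee1 = state.cdc25_c, params.wee1_c
    else:
        raise ValueError("compartment must be 'nucleus' or 'cytoplasm'")
    fp = compartment_feedback_params(cdc25, wee1, params)
    return trace_response_curve(fp, "X_T", fp.a, p_range=(0.0, cyc_max), ds=0.5, ds_max=2.0)
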