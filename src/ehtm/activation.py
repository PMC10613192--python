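"""Stimulation-to-activation dynamics.

Neural stimulation STIM(t) in [0, 1] is transformed into the mechanical
activation q(t) by one of two low-pass models:

* **Hatze** (recommended): a first-order free-calcium state
  ``dgamma/dt = m (STIM - gamma)`` followed by the saturating nonlinearity
  ``q = (q0 + (rho gamma)^nu) / (1 + (rho gamma)^nu)`` with the simplified,
  linear length sensitivity ``rho(l_CE_rel) = c eta l_CE_rel``.
* **Zajac**: first-order relaxation of q itself toward STIM, with time
  constant ``tau_q`` during activation and ``tau_q / beta_q`` during
  deactivation.

Either way q is continuous, stays within [q0, 1) and never overshoots a
constant STIM, which is what turns the bang-bang reflex stimulation into a
smooth activation signal.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ActivationParams",
    "hatze_rho",
    "hatze_q",
    "activation_rate",
    "activation_from_state",
    "initial_activation_state",
]


@dataclass(frozen=True)
class ActivationParams:
    """Constants of the activation dynamics (kg-mm-ms-kN defaults)."""

    mode: str = "hatze"      # "hatze" | "zajac" | "direct"
    q0: float = 0.005        # basic activity [-]
    c: float = 1.37e-4       # free-calcium concentration scale [mol/L]
    eta: float = 52700.0     # inverse concentration scale [L/mol]
    nu_hatze: float = 2.9    # saturation exponent [-]
    m_hatze: float = 0.0113  # calcium rate constant [1/ms]
    tau_q: float = 25.0      # Zajac activation time constant [ms]
    beta_q: float = 0.5      # Zajac deactivation ratio [-]

    def __post_init__(self) -> None:
        if self.mode not in ("hatze", "zajac", "direct"):
            raise ValueError(f"unknown activation mode {self.mode!r}")
        if not 0 < self.q0 < 1:
            raise ValueError("q0 must lie in (0, 1)")
        if self.tau_q <= 0 or self.m_hatze <= 0:
            raise ValueError("time constants must be positive")
        if not 0 < self.beta_q <= 1:
            raise ValueError("beta_q must lie in (0, 1]")


def hatze_rho(l_CE_rel: float, p: ActivationParams) -> float:
    """Simplified calcium sensitivity: linear in the relative fibre
    length, ``rho = c * eta * l_CE_rel``."""
    if l_CE_rel < 0:
        raise ValueError("l_CE_rel must be non-negative")
    return p.c * p.eta * l_CE_rel


def hatze_q(gamma: float, l_CE_rel: float, p: ActivationParams) -> float:
    """Activation from the free-calcium state: saturating map
    ``q = (q0 + (rho gamma)^nu) / (1 + (rho gamma)^nu)`` in [q0, 1)."""
    x = (hatze_rho(l_CE_rel, p) * max(gamma, 0.0)) ** p.nu_hatze
    return (p.q0 + x) / (1.0 + x)


def activation_rate(act_state: float, stim: float, l_CE_rel: float,
                    p: ActivationParams) -> float:
    """Time derivative of the activation state.

    In Hatze mode the state is gamma and the rate is ``m (STIM - gamma)``;
    in Zajac mode the state is q itself, relaxing toward
    ``max(STIM, q0)`` with the activation or deactivation time constant.
    In direct mode the state is slaved to STIM (rate 0; see
    :func:`activation_from_state`).
    """
    if p.mode == "hatze":
        return p.m_hatze * (stim - act_state)
    if p.mode == "zajac":
        target = max(stim, p.q0)
        tau = p.tau_q if target >= act_state else p.tau_q / p.beta_q
        return (target - act_state) / tau
    return 0.0


def activation_from_state(act_state: float, stim: float, l_CE_rel: float,
                          p: ActivationParams) -> float:
    """Mechanical activation q for the current activation state."""
    if p.mode == "hatze":
        return hatze_q(act_state, l_CE_rel, p)
    if p.mode == "zajac":
        return min(max(act_state, p.q0), 1.0)
    return min(max(stim, p.q0), 1.0)  # direct STIM/q input


def initial_activation_state(p: ActivationParams, stim0: float = 0.0) -> float:
    """Steady activation state for a constant initial stimulation."""
    if p.mode == "hatze":
        return min(max(stim0, 0.0), 1.0)
    return max(stim0, p.q0)
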