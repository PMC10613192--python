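"""Equilibrium-point (EP) machinery.

Under the equilibrium-point hypothesis the nervous system drives motion by
switching between postures in which internal muscle forces and external
loads balance.  This module optimises constant open-loop stimulation
vectors that steer a rig into such postures, records the EP mapping
``[STIM_opt, l_CE] -> phi`` (the steady fibre lengths become the lambda
targets of the length-feedback controller), generates step movements by
EP switching under alpha, lambda or hybrid control, and transfers lambda
targets between geometrically similar rigs by initial-length scaling.

The optimiser is a derivative-free seeded random search followed by
constrained COBYLA refinement of the most promising candidates; every
incumbent is verified by re-simulation, never trusted from the
optimiser's bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .control import ControllerConfig, Schedule
from .rigs import JointRig, SimResult, simulate_rig

__all__ = [
    "EPProblem",
    "EquilibriumPoint",
    "InfeasibleEPError",
    "find_ep",
    "stiffness_score",
    "generate_motion",
    "transfer_lambdas",
    "simulate_with_stim",
]


@dataclass(frozen=True)
class EPProblem:
    """Specification of one equilibrium-point search."""

    phi_target: float              # target joint coordinate [rad]
    t1: float = 1500.0             # settle time at which constraints hold [ms]
    eps_phi: float = 0.035         # angle tolerance [rad] (~2 deg)
    # velocity tolerance: with settling constants of a few hundred ms the
    # residual post-t1 drift is ~ eps_phi_dot * tau, so "settled" must
    # mean a drift rate well under eps_phi per settling constant
    eps_phi_dot: float = 3e-5      # angular-velocity tolerance [rad/ms]
    criterion: str = "min_effort"  # "min_effort" | "max_stiffness"
    disturbance: float = 0.5       # external torque after t1 [kN mm]
    disturbance_window: float = 400.0  # how long the disturbance acts [ms]
    seed: int = 0
    n_init: int = 12               # seeded random candidates
    n_refine: int = 4              # restarts of the constrained refinement
    max_refine_iter: int = 150
    margin: float = 0.8            # fraction of the tolerances targeted
    dt: float = 0.5                # optimisation step size [ms]

    def __post_init__(self) -> None:
        if self.eps_phi <= 0 or self.eps_phi_dot <= 0:
            raise ValueError("tolerances must be positive")
        if self.criterion not in ("min_effort", "max_stiffness"):
            raise ValueError(f"unknown criterion {self.criterion!r}")


@dataclass(frozen=True)
class EquilibriumPoint:
    """One optimised equilibrium point of a rig."""

    stim_opt: tuple[float, ...]   # stimulation per muscle [-]
    lam: tuple[float, ...]        # steady fibre lengths = lambda targets [mm]
    phi: float                    # achieved joint coordinate [rad]


class InfeasibleEPError(RuntimeError):
    """No stimulation vector within bounds satisfied the constraints;
    carries the best residual found."""

    def __init__(self, msg: str, best_residual: float, best_stim):
        super().__init__(msg)
        self.best_residual = best_residual
        self.best_stim = tuple(best_stim)


def simulate_with_stim(rig: JointRig, stim: Sequence[float], duration: float,
                       dt: float) -> SimResult:
    """Run the rig open-loop under a constant stimulation vector."""
    ctrls = [
        ControllerConfig(mode="alpha", stim_open=Schedule.constant(float(s)))
        for s in stim
    ]
    return simulate_rig(rig.with_controllers(ctrls), duration, dt)


def _settle_metrics(res: SimResult, t1: float):
    idx = int(np.searchsorted(res.t, t1 - 1e-9))
    idx = min(idx, len(res.t) - 1)
    lam = tuple(float(res.muscles[m]["l_CE"][idx]) for m in res.muscles)
    return float(res.coord[idx]), float(res.coord_vel[idx]), lam


def _constraint_residual(phi, phi_dot, prob: EPProblem) -> float:
    r_phi = max(0.0, abs(phi - prob.phi_target) - prob.eps_phi)
    r_vel = max(0.0, abs(phi_dot) - prob.eps_phi_dot)
    return r_phi / prob.eps_phi + r_vel / prob.eps_phi_dot


def find_ep(problem: EPProblem, rig: JointRig) -> EquilibriumPoint:
    """Optimise a constant stimulation vector whose forward simulation
    settles at the target posture, then record the EP.

    Constraints: |phi(t1) - phi_target| < eps_phi and |phi_dot(t1)| <
    eps_phi_dot.  The search is seeded random sampling followed by
    constrained derivative-free refinement (COBYLA), targeting a safety
    margin inside the tolerances so the verified solution sits strictly
    within them; the incumbent is always verified by re-simulation.
    Criterion ``min_effort`` minimises the summed stimulation;
    ``max_stiffness`` minimises the posture deviation under a constant
    disturbance torque applied after t1.
    """
    if not rig.muscles:
        raise ValueError("rig has no muscles")
    n = len(rig.muscles)
    rng = np.random.default_rng(problem.seed)
    duration = problem.t1 + 50.0
    target = problem.phi_target
    m_phi = problem.margin * problem.eps_phi
    m_vel = problem.margin * problem.eps_phi_dot

    memo: dict[tuple, tuple[float, float]] = {}

    def metrics(x) -> tuple[float, float]:
        key = tuple(np.round(np.clip(x, 0.0, 1.0), 10))
        if key not in memo:
            res = simulate_with_stim(rig, key, duration, problem.dt)
            memo[key] = _settle_metrics(res, problem.t1)[:2]
        return memo[key]

    def margin_infeasibility(x) -> float:
        phi, vel = metrics(x)
        return (max(0.0, abs(phi - target) - m_phi) / problem.eps_phi
                + max(0.0, abs(vel) - m_vel) / problem.eps_phi_dot)

    def objective(x) -> float:
        xc = np.clip(x, 0.0, 1.0)
        if problem.criterion == "min_effort":
            return float(np.sum(xc))
        return stiffness_score(rig, xc, problem)

    constraints = [
        {"type": "ineq", "fun": lambda x: m_phi - abs(metrics(x)[0] - target)},
        {"type": "ineq", "fun": lambda x: m_vel - abs(metrics(x)[1])},
        {"type": "ineq", "fun": lambda x: float(np.min(x))},
        {"type": "ineq", "fun": lambda x: float(1.0 - np.max(x))},
    ]

    candidates = [np.zeros(n)] + [rng.random(n) for _ in range(problem.n_init - 1)]
    candidates.sort(key=lambda c: (margin_infeasibility(c), float(np.sum(c))))

    best_x = candidates[0]
    best_residual = math.inf
    for start in candidates[: problem.n_refine]:
        out = minimize(
            objective, start, method="COBYLA", constraints=constraints,
            options={"rhobeg": 0.08, "maxiter": problem.max_refine_iter,
                     "tol": 1e-4},
        )
        x = np.clip(out.x, 0.0, 1.0)
        phi, vel = metrics(x)
        residual = _constraint_residual(phi, vel, problem)
        if residual < best_residual:
            best_residual, best_x = residual, x
        if residual == 0.0:
            break
    if best_residual > 0:
        raise InfeasibleEPError(
            f"no feasible stimulation found for target {target:.3f} rad"
            f" (best residual {best_residual:.3g})",
            best_residual, best_x,
        )

    # verify the incumbent from scratch and record the EP at t1
    res = simulate_with_stim(rig, best_x, duration, problem.dt)
    phi, phi_dot, lam = _settle_metrics(res, problem.t1)
    if _constraint_residual(phi, phi_dot, problem) > 0:
        raise InfeasibleEPError(
            f"incumbent failed re-verification for target {target:.3f} rad",
            _constraint_residual(phi, phi_dot, problem), best_x,
        )
    return EquilibriumPoint(tuple(float(s) for s in best_x), lam, phi)


def stiffness_score(rig: JointRig, stim: Sequence[float],
                    problem: EPProblem) -> float:
    """Low-frequency joint stiffness score: the steady posture deviation
    |phi - phi_disturb| caused by a constant disturbance torque applied
    after t1 (smaller deviation = stiffer joint)."""
    if problem.disturbance == 0.0:
        return 0.0
    t1 = problem.t1

    def ext(t: float) -> float:
        return problem.disturbance if t >= t1 else 0.0

    rig_d = replace(rig, external_load=ext)
    duration = t1 + problem.disturbance_window
    res = simulate_with_stim(rig_d, stim, duration, problem.dt)
    phi_before, _, _ = _settle_metrics(res, t1)
    phi_after = float(res.coord[-1])
    return abs(phi_after - phi_before)


def generate_motion(eps: Sequence[EquilibriumPoint],
                    switch_times: Sequence[float],
                    controller_variant: str = "hybrid_kistemaker",
                    k_p: float = 0.0, k_d: float = 0.0,
                    delta: float = 0.0) -> list[ControllerConfig]:
    """Piecewise-constant stimulation and lambda schedules realising a
    movement through the given EPs.

    Returns one ControllerConfig per muscle.  ``controller_variant`` is
    ``alpha`` (open-loop only), ``lambda`` (length feedback only) or one
    of the hybrid modes; lambda-based variants take the PD gains and the
    electromechanical delay.
    """
    if not eps:
        raise ValueError("need at least one equilibrium point")
    if len(switch_times) != len(eps) - 1:
        raise ValueError("need exactly len(eps) - 1 switch times")
    if any(b <= a for a, b in zip(switch_times, list(switch_times)[1:])):
        raise ValueError("switch times must be strictly increasing")
    if controller_variant not in ("alpha", "lambda", "hybrid_kistemaker",
                                  "hybrid_standard"):
        raise ValueError(f"unknown controller variant {controller_variant!r}")

    n = len(eps[0].stim_opt)
    if any(len(ep.stim_opt) != n or len(ep.lam) != n for ep in eps):
        raise ValueError("all EPs must cover the same muscles")

    times = (0.0,) + tuple(float(t) for t in switch_times)
    configs = []
    for i in range(n):
        stim_sched = Schedule(times, tuple(ep.stim_opt[i] for ep in eps))
        lam_sched = Schedule(times, tuple(ep.lam[i] for ep in eps))
        configs.append(ControllerConfig(
            mode=controller_variant if controller_variant != "lambda" else "lambda",
            stim_open=stim_sched,
            lam=lam_sched,
            k_p=k_p, k_d=k_d, delta=delta,
        ))
    return configs


def transfer_lambdas(lam_src: Sequence[float], init_len_src: Sequence[float],
                     init_len_dst: Sequence[float]) -> tuple[float, ...]:
    """Scale lambda targets from a source model to a similar destination
    model by the ratio of initial fibre lengths:
    ``lam_dst[i] = lam_src[i] * init_len_dst[i] / init_len_src[i]``."""
    if not (len(lam_src) == len(init_len_src) == len(init_len_dst)):
        raise ValueError("muscle counts must match")
    if any(l <= 0 for l in init_len_src) or any(l <= 0 for l in init_len_dst):
        raise ValueError("initial lengths must be positive")
    return tuple(
        l * d / s for l, s, d in zip(lam_src, init_len_src, init_len_dst)
    )
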