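"""Toy musculoskeletal rigs and simulation protocols.

A :class:`JointRig` is a single-degree-of-freedom skeleton — either a
revolute joint (angle phi [rad], rotational inertia [kg mm^2]) or a
translating mass (coordinate x [mm], mass [kg]) — actuated by
muscle-tendon units routed along via-point polylines.  Muscle, activation
and joint states are integrated simultaneously with a fixed-step RK4
scheme; the stimulation computed by each muscle's internal controller is
held over the step (zero-order hold), which keeps ring-buffer delays
sample-aligned and runs bitwise reproducible.

Sign conventions for the revolute rig: the body frame rotates about the
origin, phi = 0 pointing straight down, positive phi flexing toward +x;
gravity acts along -y.  A muscle's generalized force is
``-dL/dphi * F_MTU`` so shortening muscles pull the joint the way their
geometry dictates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .activation import (
    ActivationParams,
    activation_from_state,
    activation_rate,
    initial_activation_state,
)
from .control import Controller, ControllerConfig, DelayBuffer, Schedule
from .muscle import (
    MuscleParams,
    _f_ce_of_v,
    _solve_v_ce,
    f_pee,
    pee_energy,
    see_energy,
    static_fibre_length,
)

__all__ = [
    "ViaPointRouting",
    "LinearRouting",
    "macro_element_kinematics",
    "MuscleUnit",
    "JointRig",
    "SimResult",
    "IntegrationError",
    "simulate_rig",
    "simulate_mtu_bench",
    "simulate_elbow",
    "simulate_reflex_drop",
    "energy_series",
]


class IntegrationError(RuntimeError):
    """Raised when the state integration blows up; carries the last valid
    state snapshot in ``last_state``."""

    def __init__(self, msg: str, last_state: dict):
        super().__init__(msg)
        self.last_state = last_state


# ---------------------------------------------------------------------------
# muscle routing
# ---------------------------------------------------------------------------

_GRAD_H = 1e-5  # central-difference step for dL/dphi [rad]


@dataclass(frozen=True)
class ViaPointRouting:
    """Polyline muscle path through via-points fixed to the ground or to
    the rotating body segment.

    The whole polyline is treated as one macro-element: the MTU sees the
    summed straight-segment length and its rate, while force is
    transmitted along the first and last segments.  Points are
    ``(frame, (x, y))`` with frame ``"ground"`` or ``"body"``; body points
    are expressed in the segment frame whose +x axis points along the
    segment (phi = 0: straight down).
    """

    points: tuple[tuple[str, tuple[float, float]], ...]

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("a muscle path needs at least two via-points")
        for frame, _ in self.points:
            if frame not in ("ground", "body"):
                raise ValueError(f"unknown via-point frame {frame!r}")

    def world_points(self, phi: float) -> list[tuple[float, float]]:
        s, c = math.sin(phi), math.cos(phi)
        out = []
        for frame, (x, y) in self.points:
            if frame == "ground":
                out.append((x, y))
            else:
                # body frame: local +x -> (sin phi, -cos phi)
                out.append((x * s + y * c, -x * c + y * s))
        return out

    def length(self, phi: float) -> float:
        pts = self.world_points(phi)
        total = 0.0
        for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
            seg = math.hypot(x1 - x0, y1 - y0)
            if seg < 1e-9:
                raise ValueError("coincident consecutive via-points")
            total += seg
        return total

    def grad(self, phi: float) -> float:
        return (self.length(phi + _GRAD_H) - self.length(phi - _GRAD_H)) / (2 * _GRAD_H)


@dataclass(frozen=True)
class LinearRouting:
    """Straight-line path for translating rigs: L(x) = l0 + gain * x."""

    l0: float
    gain: float = 1.0

    def length(self, x: float) -> float:
        return self.l0 + self.gain * x

    def grad(self, x: float) -> float:
        return self.gain


def macro_element_kinematics(polyline, phi: float, phi_dot: float = 0.0):
    """Total averaged macro-element length and lengthening rate of a
    via-point polyline at joint angle phi."""
    if not isinstance(polyline, (ViaPointRouting, LinearRouting)):
        polyline = ViaPointRouting(tuple(polyline))
    return polyline.length(phi), polyline.grad(phi) * phi_dot


# ---------------------------------------------------------------------------
# rig definition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MuscleUnit:
    """One muscle of a rig: mechanics, activation, controller, routing."""

    name: str
    params: MuscleParams
    act: ActivationParams
    ctrl: ControllerConfig
    routing: ViaPointRouting | LinearRouting

    def with_ctrl(self, ctrl: ControllerConfig) -> "MuscleUnit":
        return replace(self, ctrl=ctrl)


@dataclass(frozen=True)
class JointRig:
    """Single-DOF musculoskeletal toy model.

    ``kind="rotation"``: coordinate is the joint angle [rad], ``inertia``
    in kg mm^2, gravity torque ``-mass g com_dist sin(phi)``.
    ``kind="translation"``: coordinate is a displacement [mm] (positive
    down), ``inertia`` is the mass [kg], gravity force ``+mass g``.
    """

    inertia: float
    muscles: tuple[MuscleUnit, ...]
    kind: str = "rotation"
    rest_angle: float = 0.0            # initial coordinate
    mass: float = 0.0                  # segment mass for gravity [kg]
    com_dist: float = 0.0              # joint-to-COM distance [mm]
    g: float = 9.81e-3                 # gravity [mm/ms^2]
    joint_damping: float = 0.0         # viscous joint torque [kN mm ms/rad]
    external_load: Callable[[float], float] | None = None  # torque(t)

    def __post_init__(self) -> None:
        if self.kind not in ("rotation", "translation"):
            raise ValueError(f"unknown rig kind {self.kind!r}")
        if self.inertia <= 0:
            raise ValueError("inertia must be positive")

    def gravity_force(self, coord: float) -> float:
        if self.mass == 0.0 or self.g == 0.0:
            return 0.0
        if self.kind == "rotation":
            return -self.mass * self.g * self.com_dist * math.sin(coord)
        return self.mass * self.g

    def with_controllers(self, ctrls: Sequence[ControllerConfig]) -> "JointRig":
        if len(ctrls) != len(self.muscles):
            raise ValueError("one controller config per muscle required")
        return replace(
            self,
            muscles=tuple(m.with_ctrl(c) for m, c in zip(self.muscles, ctrls)),
        )

    def scaled(self, factor: float) -> "JointRig":
        """Geometrically similar rig: all muscle lengths and via-point
        coordinates scaled by ``factor`` (same topology, same forces)."""
        new_muscles = []
        for m in self.muscles:
            if isinstance(m.routing, ViaPointRouting):
                pts = tuple(
                    (fr, (x * factor, y * factor)) for fr, (x, y) in m.routing.points
                )
                routing = ViaPointRouting(pts)
            else:
                routing = replace(m.routing, l0=m.routing.l0 * factor)
            new_muscles.append(
                replace(m, params=m.params.with_scale(factor), routing=routing)
            )
        return replace(
            self,
            muscles=tuple(new_muscles),
            com_dist=self.com_dist * factor,
            inertia=self.inertia * factor ** 2,
        )


# ---------------------------------------------------------------------------
# results container
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    """Uniformly sampled trajectories of one simulation run.

    ``coord``/``coord_vel`` are the joint coordinate and its rate (angle
    [rad] and [rad/ms] for revolute rigs, displacement [mm] and [mm/ms]
    for translating ones, MTU length for the bench).  Per-muscle series:
    l_CE, v_CE, stim, q, force.
    """

    t: np.ndarray
    coord: np.ndarray
    coord_vel: np.ndarray
    muscles: dict[str, dict[str, np.ndarray]]
    meta: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else 0.0

    def to_frame(self):
        import pandas as pd

        unit_c, unit_v = ("rad", "rad_per_ms")
        if self.meta.get("kind") == "translation":
            unit_c, unit_v = ("mm", "mm_per_ms")
        elif self.meta.get("kind") == "bench":
            unit_c, unit_v = ("mm", "mm_per_ms")
        cols = {
            "time_ms": self.t,
            f"coord_{unit_c}": self.coord,
            f"coord_vel_{unit_v}": self.coord_vel,
        }
        for name, series in self.muscles.items():
            cols[f"{name}_l_ce_mm"] = series["l_CE"]
            cols[f"{name}_v_ce_mm_per_ms"] = series["v_CE"]
            cols[f"{name}_stim"] = series["stim"]
            cols[f"{name}_q"] = series["q"]
            cols[f"{name}_force_kn"] = series["force"]
        return pd.DataFrame(cols)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# core fixed-step integrator
# ---------------------------------------------------------------------------

def simulate_rig(rig: JointRig, duration: float, dt: float,
                 record_every: int = 1, initial_l_CE: Sequence[float] | None = None,
                 meta: dict | None = None) -> SimResult:
    """Forward dynamics of a rig: coupled joint + muscle + activation
    states under the muscles' internal controllers.

    The joint coordinate starts at ``rig.rest_angle`` with zero velocity;
    fibre lengths initialize to the passive static equilibrium of each
    muscle at that posture unless ``initial_l_CE`` is given.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > 1.0:
        raise ValueError("step size capped at 1 ms for activation stability")
    n_steps = int(round(duration / dt))

    muscles = rig.muscles
    nm = len(muscles)
    routings = [m.routing for m in muscles]
    params = [m.params for m in muscles]
    acts = [m.act for m in muscles]
    ctrls = [Controller(m.ctrl, m.params.l_CE_opt) for m in muscles]

    coord = rig.rest_angle
    vel = 0.0
    l_ce = []
    a_state = []
    for i, m in enumerate(muscles):
        L0 = routings[i].length(coord)
        if initial_l_CE is not None:
            l_ce.append(float(initial_l_CE[i]))
        else:
            l_ce.append(static_fibre_length(L0, acts[i].q0, params[i]))
        a_state.append(initial_activation_state(acts[i], 0.0))

    buf_l = [DelayBuffer(dt, m.ctrl.max_delay + 2 * dt, l_ce[i])
             for i, m in enumerate(muscles)]
    buf_v = [DelayBuffer(dt, m.ctrl.max_delay + 2 * dt, 0.0)
             for i, m in enumerate(muscles)]

    inv_inertia = 1.0 / rig.inertia
    ext = rig.external_load
    c_joint = rig.joint_damping

    def rhs(t: float, y: list[float], stim: list[float]) -> list[float]:
        c, w = y[0], y[1]
        torque = rig.gravity_force(c) - c_joint * w
        if ext is not None:
            torque += ext(t)
        out = [w, 0.0] + [0.0] * (2 * nm)
        for i in range(nm):
            l = y[2 + 2 * i]
            a = y[3 + 2 * i]
            p = params[i]
            L = routings[i].length(c)
            dL = routings[i].grad(c)
            v_mtu = dL * w
            lrel = l / p.l_CE_opt
            q = activation_from_state(a, stim[i], lrel, acts[i])
            v = _solve_v_ce(l, L, v_mtu, q, p)
            force = _f_ce_of_v(v, max(l, 1e-9 * p.l_CE_opt), q, p) + f_pee(max(l, 1e-9), p)
            torque += -dL * force
            out[2 + 2 * i] = v
            out[3 + 2 * i] = activation_rate(a, stim[i], lrel, acts[i])
        out[1] = torque * inv_inertia
        # gravity/external already included before muscle loop; damping too
        return out

    n_rec = n_steps // record_every + 1
    t_out = np.empty(n_rec)
    c_out = np.empty(n_rec)
    v_out = np.empty(n_rec)
    m_out = {
        m.name: {k: np.empty(n_rec) for k in ("l_CE", "v_CE", "stim", "q", "force")}
        for m in muscles
    }
    rec = 0

    y = [coord, vel] + [x for pair in zip(l_ce, a_state) for x in pair]
    half = dt / 2.0
    sixth = dt / 6.0

    for k in range(n_steps + 1):
        t = k * dt
        # per-muscle observables at the step head (pre-controller)
        stims = [0.0] * nm
        obs = []
        for i in range(nm):
            l = y[2 + 2 * i]
            a = y[3 + 2 * i]
            p = params[i]
            L = routings[i].length(y[0])
            dL = routings[i].grad(y[0])
            v_mtu = dL * y[1]
            lrel = l / p.l_CE_opt
            q = activation_from_state(a, 0.0, lrel, acts[i])
            v = _solve_v_ce(l, L, v_mtu, q, p)
            force = _f_ce_of_v(v, max(l, 1e-9 * p.l_CE_opt), q, p) + f_pee(max(l, 1e-9), p)
            obs.append((l, v, q, force))
            buf_l[i].record(l)
            buf_v[i].record(v)
        for i in range(nm):
            stims[i] = ctrls[i].stim(t, buf_l[i], buf_v[i])

        if k % record_every == 0:
            t_out[rec] = t
            c_out[rec] = y[0]
            v_out[rec] = y[1]
            for i, m in enumerate(muscles):
                l, v, q, force = obs[i]
                s = m_out[m.name]
                s["l_CE"][rec] = l
                s["v_CE"][rec] = v
                s["stim"][rec] = stims[i]
                s["q"][rec] = q
                s["force"][rec] = force
            rec += 1

        if k == n_steps:
            break

        k1 = rhs(t, y, stims)
        y2 = [yi + half * ki for yi, ki in zip(y, k1)]
        k2 = rhs(t + half, y2, stims)
        y3 = [yi + half * ki for yi, ki in zip(y, k2)]
        k3 = rhs(t + half, y3, stims)
        y4 = [yi + dt * ki for yi, ki in zip(y, k3)]
        k4 = rhs(t + dt, y4, stims)
        y = [
            yi + sixth * (a + 2 * b + 2 * c2 + d)
            for yi, a, b, c2, d in zip(y, k1, k2, k3, k4)
        ]
        if not all(math.isfinite(v) for v in y):
            raise IntegrationError(
                f"state blew up at t={t + dt:.3f} ms",
                {"t": t, "coord": c_out[max(rec - 1, 0)],
                 "y": [float(v) for v in y]},
            )

    full_meta = {"dt": dt, "duration": duration, "kind": rig.kind,
                 "n_muscles": nm}
    if meta:
        full_meta.update(meta)
    return SimResult(t_out, c_out, v_out, m_out, full_meta)


# ---------------------------------------------------------------------------
# MTU test bench
# ---------------------------------------------------------------------------

def _inverse_see(force: float, p: MuscleParams) -> float:
    """Tendon length carrying a given SEE force."""
    if force <= 0:
        return p.l_SEE_0
    if force < p.dF_SEE_0:
        dl = (force / p.K_SEE_nl) ** (1.0 / p.nu_SEE)
    else:
        dl = p.dU_SEE_nll * p.l_SEE_0 + (force - p.dF_SEE_0) / p.K_SEE_l
    return p.l_SEE_0 + dl


def simulate_mtu_bench(protocol: str, p: MuscleParams, act: ActivationParams,
                       duration: float, dt: float,
                       l_mtu: float | None = None,
                       stim_schedule: Schedule | None = None,
                       release_time: float | None = None,
                       load: float = 0.0) -> SimResult:
    """Single-MTU bench protocols.

    ``isometric``: both ends clamped at ``l_mtu`` under a stimulation
    schedule.  ``ramp``: isometric with a stimulation ramp 0 -> 1 over
    [300, 700] ms unless a schedule is given.  ``quick_release``:
    isometric hold until ``release_time``, then the tendon force is forced
    to ``load`` (default 0) and the MTU end follows the fibre.
    """
    if protocol not in ("isometric", "quick_release", "ramp"):
        raise ValueError(f"unknown protocol {protocol!r}")
    if l_mtu is None:
        l_mtu = p.l_CE_opt + p.l_SEE_0 * (1.0 + p.dU_SEE_nll)
    if stim_schedule is None:
        if protocol == "ramp":
            steps = [(0.0, 0.0)] + [
                (300.0 + 400.0 * i / 40.0, i / 40.0) for i in range(1, 41)
            ]
            stim_schedule = Schedule.from_pairs(steps)
        elif protocol == "quick_release":
            stim_schedule = Schedule.constant(1.0)
        else:
            stim_schedule = Schedule.constant(0.0)
    if protocol == "quick_release" and release_time is None:
        release_time = duration / 2.0

    n_steps = int(round(duration / dt))
    l_ce = static_fibre_length(l_mtu, act.q0, p)
    a = initial_activation_state(act, 0.0)
    l_see_load = _inverse_see(load, p)
    # after release the tendon length is constant (end follows the fibre),
    # so the SDE transmits no force: solve the balance without it
    p_nosde = replace(p, D_SDE=0.0)

    n = n_steps + 1
    t_out = np.empty(n)
    c_out = np.empty(n)
    v_out = np.empty(n)
    series = {k: np.empty(n) for k in ("l_CE", "v_CE", "stim", "q", "force")}

    released = False
    for k in range(n):
        t = k * dt
        stim = min(max(stim_schedule(t), 0.0), 1.0)
        if protocol == "quick_release" and t >= release_time:
            released = True
        lrel = l_ce / p.l_CE_opt
        q = activation_from_state(a, stim, lrel, act)

        if released:
            L = l_ce + l_see_load
            v = _solve_v_ce(l_ce, L, 0.0, q, p_nosde)
            v_mtu = v
        else:
            L = l_mtu
            v_mtu = 0.0
            v = _solve_v_ce(l_ce, L, v_mtu, q, p)

        force = _f_ce_of_v(v, max(l_ce, 1e-9 * p.l_CE_opt), q, p) + f_pee(max(l_ce, 1e-9), p)
        t_out[k] = t
        c_out[k] = L
        v_out[k] = v_mtu
        series["l_CE"][k] = l_ce
        series["v_CE"][k] = v
        series["stim"][k] = stim
        series["q"][k] = q
        series["force"][k] = force

        if k == n_steps:
            break
        # RK4 on (l_ce, a) with stim held; in the released phase the MTU
        # end tracks the fibre so l_MTU = l_CE + const
        def bench_rhs(_t, l, av):
            lr = l / p.l_CE_opt
            qq = activation_from_state(av, stim, lr, act)
            if released:
                vv = _solve_v_ce(l, l + l_see_load, 0.0, qq, p_nosde)
            else:
                vv = _solve_v_ce(l, l_mtu, 0.0, qq, p)
            return vv, activation_rate(av, stim, lr, act)

        h = dt / 2.0
        d1l, d1a = bench_rhs(t, l_ce, a)
        d2l, d2a = bench_rhs(t + h, l_ce + h * d1l, a + h * d1a)
        d3l, d3a = bench_rhs(t + h, l_ce + h * d2l, a + h * d2a)
        d4l, d4a = bench_rhs(t + dt, l_ce + dt * d3l, a + dt * d3a)
        l_ce += dt / 6.0 * (d1l + 2 * d2l + 2 * d3l + d4l)
        a += dt / 6.0 * (d1a + 2 * d2a + 2 * d3a + d4a)
        if not (math.isfinite(l_ce) and math.isfinite(a)):
            raise IntegrationError(
                f"bench state blew up at t={t + dt:.3f} ms",
                {"t": t, "l_CE": float(c_out[k]), "protocol": protocol},
            )

    return SimResult(
        t_out, c_out, v_out, {"mtu": series},
        {"dt": dt, "duration": duration, "kind": "bench", "protocol": protocol,
         "l_mtu": l_mtu, "load": load, "release_time": release_time},
    )


# ---------------------------------------------------------------------------
# scenario wrappers
# ---------------------------------------------------------------------------

def simulate_elbow(rig: JointRig, duration: float, dt: float,
                   record_every: int = 1) -> SimResult:
    """Forward dynamics of the antagonistic single-joint elbow rig."""
    if rig.kind != "rotation":
        raise ValueError("elbow simulation expects a revolute rig")
    return simulate_rig(rig, duration, dt, record_every=record_every)


def simulate_reflex_drop(rig: JointRig, omega_sweep: Sequence[float],
                         duration: float, dt: float,
                         record_every: int = 1) -> list[SimResult]:
    """Gravity drop of an inertial load held by reflex-controlled muscles,
    one run per strain threshold; each result carries the peak
    displacement in ``meta["peak_displacement"]``."""
    for m in rig.muscles:
        if m.ctrl.mode != "reflex":
            raise ValueError("all muscles must be in reflex mode")
    results = []
    for omega in omega_sweep:
        ctrls = [replace(m.ctrl, omega=omega) for m in rig.muscles]
        run = simulate_rig(rig.with_controllers(ctrls), duration, dt,
                           record_every=record_every, meta={"omega": omega})
        # displacement along gravity (positive coordinate = downward)
        run.meta["peak_displacement"] = float(
            np.max(run.coord - run.coord[0])
        )
        results.append(run)
    return results


def energy_series(rig: JointRig, result: SimResult) -> np.ndarray:
    """Total mechanical energy along a trajectory: kinetic + gravity
    potential + elastic energy stored in PEE and SEE [kN mm]."""
    e = 0.5 * rig.inertia * result.coord_vel ** 2
    if rig.kind == "rotation":
        e = e + rig.mass * rig.g * rig.com_dist * (-np.cos(result.coord))
    else:
        e = e - rig.mass * rig.g * result.coord
    for m in rig.muscles:
        series = result.muscles[m.name]
        l_ce = series["l_CE"]
        l_mtu = np.array([m.routing.length(c) for c in result.coord])
        l_see = np.maximum(l_mtu - l_ce, 0.0)
        e = e + np.array([
            pee_energy(l, m.params) + see_energy(s, m.params)
            for l, s in zip(l_ce, l_see)
        ])
    return e
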