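"""Deterministic generators for every test input.

All rigs, parameter sets, stimulation schedules and reference signals the
test suite and examples use come from here; the same (name, seed) always
yields the same objects, and no external data files are involved.

The muscle-specific values (F_max, l_CE_opt, l_SEE_0) and the rig
anthropometry are documented surrogate choices for a scaled-down
single-joint bench — they are NOT measured human parameters.  The
non-specific constants are the shipped kg-mm-ms-kN defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activation import ActivationParams
from .control import ControllerConfig
from .muscle import MuscleParams
from .rigs import JointRig, LinearRouting, MuscleUnit, ViaPointRouting

__all__ = [
    "FixtureSpec",
    "default_muscle",
    "make_rig",
    "make_reference",
    "ELBOW_GAINS",
    "LAMBDA_GAINS",
]

# PD gains and electromechanical delay used by the elbow fixtures.
# The dominant loop lag is the activation dynamics (~90 ms for the
# calcium pathway), which caps the usable proportional gain; the large
# derivative/proportional ratio (40 ms lead) compensates part of that
# lag.  ELBOW_GAINS drive the hybrid controller on top of the open-loop
# equilibrium-point stimulation; LAMBDA_GAINS are for the pure
# length-feedback servo, which needs more DC gain (droop ~ stim/k_p) and
# is paired with the faster, linear first-order activation mode.
ELBOW_GAINS = {"k_p": 1.0, "k_d": 40.0, "delta": 10.0}
LAMBDA_GAINS = {"k_p": 8.0, "k_d": 48.0, "delta": 0.0}

# surrogate muscle-specific values [kN, mm, mm]
_MUSCLES = {
    "generic": (1.0, 45.0, 45.0),
    "elbow_flexor": (1.0, 45.0, 50.0),
    "elbow_extensor": (1.2, 50.0, 85.0),
    "neck_like": (0.25, 40.0, 60.0),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Identifier + seed + sparse overrides for a reproducible fixture."""

    name: str
    seed: int = 0
    overrides: dict = field(default_factory=dict)


def default_muscle(name: str = "generic") -> tuple[MuscleParams, ActivationParams]:
    """Muscle + activation parameter set for a named fixture muscle.

    Non-specific constants are the shipped defaults; F_max / l_CE_opt /
    l_SEE_0 are the documented surrogate choices above; dF_SEE_0 follows
    the 0.4 * F_max rule.
    """
    try:
        F_max, l_opt, l_see0 = _MUSCLES[name]
    except KeyError:
        raise ValueError(
            f"unknown muscle fixture {name!r}; known: {sorted(_MUSCLES)}"
        ) from None
    return (
        MuscleParams(F_max=F_max, l_CE_opt=l_opt, l_SEE_0=l_see0),
        ActivationParams(),
    )


def _elbow_pair(spec: FixtureSpec) -> JointRig:
    """Antagonistic 1-DOF elbow surrogate.

    Forearm: 1.1 kg, COM 110 mm from the joint, inertia 2.3e4 kg mm^2
    (slender-rod scale for a ~250 mm forearm+hand).  Flexor inserts 28 mm
    along the forearm; the extensor wraps a ground via-point behind the
    joint and inserts on the olecranon side, giving a ~10 mm moment arm.
    """
    p_flex, act = default_muscle("elbow_flexor")
    p_ext, _ = default_muscle("elbow_extensor")
    if spec.overrides.get("activation") == "zajac":
        act = ActivationParams(mode="zajac")
    none = ControllerConfig(mode="none")
    flexor = MuscleUnit(
        "flexor", p_flex, act, none,
        ViaPointRouting((("ground", (0.0, 80.0)), ("body", (28.0, 0.0)))),
    )
    extensor = MuscleUnit(
        "extensor", p_ext, act, none,
        ViaPointRouting((
            ("ground", (-20.0, 80.0)),
            ("ground", (-28.0, -5.0)),
            ("body", (30.0, -12.0)),
        )),
    )
    rig = JointRig(
        inertia=23000.0,
        muscles=(flexor, extensor),
        rest_angle=float(spec.overrides.get("rest_angle", 1.40)),  # ~80 deg
        mass=1.1,
        com_dist=110.0,
    )
    scale = spec.overrides.get("scale")
    return rig.scaled(scale) if scale else rig


def _symmetric_pair(spec: FixtureSpec) -> JointRig:
    """Mirror-symmetric antagonistic pair, gravity off.

    The mirror x -> -x maps phi -> -phi and swaps the two muscles, so
    under equal co-stimulation the joint equilibrium is phi = 0.
    """
    _, act = default_muscle("generic")
    # tendon sized so both muscles stay taut over roughly +/- 0.25 rad
    # about phi = 0 while the fibres work on the ascending limb, where
    # co-activation adds (rather than removes) joint stiffness
    p = MuscleParams(F_max=1.0, l_CE_opt=45.0, l_SEE_0=82.5)
    none = ControllerConfig(mode="none")
    insertion = ("body", (30.0, 0.0))
    left = MuscleUnit(
        "left", p, act, none,
        ViaPointRouting((("ground", (-120.0, 0.0)), insertion)),
    )
    right = MuscleUnit(
        "right", p, act, none,
        ViaPointRouting((("ground", (120.0, 0.0)), insertion)),
    )
    return JointRig(
        inertia=15000.0,
        muscles=(right, left),
        rest_angle=float(spec.overrides.get("rest_angle", 0.0)),
        mass=0.0,
        g=0.0,
    )


def _drop_mass(spec: FixtureSpec) -> JointRig:
    """Vertical 1-DOF mass caught by two reflex muscles — a lumped
    head-drop surrogate: 4.2 kg released under gravity, held by two
    parallel neck-like MTUs whose stretch reflex must arrest the fall."""
    p, act = default_muscle("neck_like")
    omega = float(spec.overrides.get("omega", 0.05))
    reflex = ControllerConfig(
        mode="reflex", omega=omega,
        tau_reflex=float(spec.overrides.get("tau_reflex", 10.0)),
        t_contr=0.0,
    )
    l0 = p.l_CE_opt + p.l_SEE_0  # taut but unloaded at x = 0
    muscles = tuple(
        MuscleUnit(f"holder{i}", p, act, reflex, LinearRouting(l0=l0, gain=1.0))
        for i in (1, 2)
    )
    return JointRig(
        inertia=4.2,           # mass [kg]
        muscles=muscles,
        kind="translation",
        rest_angle=0.0,
        mass=4.2,
        g=9.81e-3,
    )


def _pendulum(spec: FixtureSpec) -> JointRig:
    """Passive gravity pendulum (no muscles) for integrator checks."""
    return JointRig(
        inertia=23000.0,
        muscles=(),
        rest_angle=float(spec.overrides.get("rest_angle", 0.15)),
        mass=1.1,
        com_dist=110.0,
    )


_RIGS = {
    "elbow_pair": _elbow_pair,
    "symmetric_pair": _symmetric_pair,
    "drop_mass": _drop_mass,
    "pendulum": _pendulum,
}


def make_rig(spec: FixtureSpec | str) -> JointRig:
    """Build a named rig fixture, reproducibly.

    Names: ``elbow_pair``, ``symmetric_pair``, ``drop_mass``,
    ``pendulum``; a suffix ``_x<factor>`` (e.g. ``elbow_pair_x1.2``)
    yields the geometrically scaled variant.
    """
    if isinstance(spec, str):
        spec = FixtureSpec(spec)
    name = spec.name
    if "_x" in name:
        base, _, factor = name.rpartition("_x")
        if base in _RIGS:
            spec = FixtureSpec(base, spec.seed,
                               {**spec.overrides, "scale": float(factor)})
            name = base
    try:
        builder = _RIGS[name]
    except KeyError:
        raise ValueError(
            f"unknown rig fixture {spec.name!r}; known: {sorted(_RIGS)}"
        ) from None
    return builder(spec)


def make_reference(signal: str, params: dict | None = None, seed: int = 0):
    """Analytic reference series for evaluation tests.

    ``step_response``: second-order underdamped step of amplitude A,
    natural frequency wn [rad/ms], damping ratio zeta.
    ``damped_oscillation``: free decay from amplitude A.
    Optional additive Gaussian noise (std ``noise``) is seeded.
    Returns (t, y) arrays.
    """
    p = {"A": 1.0, "wn": 0.01, "zeta": 0.2, "duration": 2000.0,
         "dt": 1.0, "noise": 0.0}
    p.update(params or {})
    t = np.arange(0.0, p["duration"] + p["dt"] / 2, p["dt"])
    zeta, wn, A = p["zeta"], p["wn"], p["A"]
    wd = wn * np.sqrt(1.0 - zeta ** 2)
    env = np.exp(-zeta * wn * t)
    if signal == "step_response":
        y = A * (1.0 - env * (np.cos(wd * t) + zeta * wn / wd * np.sin(wd * t)))
    elif signal == "damped_oscillation":
        y = A * env * np.cos(wd * t)
    else:
        raise ValueError(f"unknown reference signal {signal!r}")
    if p["noise"] > 0:
        y = y + np.random.default_rng(seed).normal(0.0, p["noise"], len(t))
    return t, y
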