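"""Internal physiological muscle controllers.

Each muscle computes its own stimulation signal STIM(t) in [0, 1] every
simulation step from one of:

* ``alpha``   — open-loop: a predefined stimulation schedule, clamped.
* ``lambda``  — closed-loop PD law on the delayed fibre length error
  against a target length (the equilibrium-point target), normalized by
  the optimal fibre length.
* ``hybrid_kistemaker`` — alpha + signed lambda term, clamped once.
* ``hybrid_standard``   — clamped alpha term + lambda term clamped to be
  non-negative (the muscle can only pull), then clamped again.
* ``reflex``  — monosynaptic stretch reflex: binary 0/1 stimulation when
  the delayed fibre strain exceeds a threshold omega, gated until the
  controller activation time plus the neural delay has passed.

Proprioceptive feedback (fibre length and velocity) arrives through a
ring buffer that reproduces the electromechanical/neural delay exactly at
the simulation step (zero-order hold).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "Schedule",
    "ControllerConfig",
    "DelayBuffer",
    "Controller",
    "stim_alpha",
    "stim_lambda",
    "stim_hybrid",
    "strain_ce",
    "stim_reflex",
    "delayed_signal",
]

_MODES = ("alpha", "lambda", "hybrid_kistemaker", "hybrid_standard",
          "reflex", "none")


def _clamp01(x: float) -> float:
    return 0.0 if x < 0.0 else 1.0 if x > 1.0 else x


@dataclass(frozen=True)
class Schedule:
    """Piecewise-constant schedule: value of the last breakpoint at or
    before t.  Before the first breakpoint the first value holds."""

    times: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values) or not self.times:
            raise ValueError("times and values must be equal-length, non-empty")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("breakpoint times must be strictly increasing")

    @classmethod
    def constant(cls, value: float) -> "Schedule":
        return cls((0.0,), (float(value),))

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[float, float]]) -> "Schedule":
        ts, vs = zip(*pairs)
        return cls(tuple(float(t) for t in ts), tuple(float(v) for v in vs))

    def __call__(self, t: float) -> float:
        v = self.values[0]
        for tk, vk in zip(self.times, self.values):
            if tk <= t:
                v = vk
            else:
                break
        return v


@dataclass(frozen=True)
class ControllerConfig:
    """Control mode plus every controller constant.

    Gains follow the PD law normalization: the length error is divided by
    the optimal fibre length, so ``k_p`` is dimensionless and ``k_d``
    carries ms.  ``lam`` may be a constant [mm] or a Schedule for
    equilibrium-point switching.
    """

    mode: str = "none"
    stim_open: Schedule = field(default_factory=lambda: Schedule.constant(0.0))
    lam: Schedule | float = 0.0        # target fibre length [mm]
    lam_dot: float = 0.0               # target fibre velocity [mm/ms]
    k_p: float = 0.0                   # proportional gain [-]
    k_d: float = 0.0                   # derivative gain [ms]
    delta: float = 0.0                 # electromechanical delay [ms]
    omega: float = 0.0                 # reflex strain threshold [-]
    tau_reflex: float = 0.0            # reflex neural delay [ms]
    t_contr: float = 0.0               # controller activation time [ms]
    l_CE_ref: float | None = None      # strain reference length [mm]

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown controller mode {self.mode!r}")
        for name in ("delta", "tau_reflex", "omega"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def lam_at(self, t: float) -> float:
        return self.lam(t) if isinstance(self.lam, Schedule) else self.lam

    @property
    def max_delay(self) -> float:
        return max(self.delta, self.tau_reflex)


class DelayBuffer:
    """Ring buffer of uniformly sampled history with zero-order hold.

    Samples are recorded once per simulation step of size ``dt``.  A
    lookup at ``t - d`` returns the stored value at the nearest sample not
    later than ``t - d``; before recorded history it returns the initial
    pre-fill value, which replicates the initial state across the whole
    delay span.
    """

    def __init__(self, dt: float, span: float, initial: float, t0: float = 0.0):
        if dt <= 0:
            raise ValueError("dt must be positive")
        if span < 0:
            raise ValueError("span must be non-negative")
        self.dt = dt
        self.t0 = t0
        self._n = max(int(round(span / dt)) + 2, 2)
        self._buf = [float(initial)] * self._n
        self._count = 0  # samples recorded so far (sample k is at t0 + k·dt)

    @property
    def span(self) -> float:
        return (self._n - 2) * self.dt

    def record(self, value: float) -> None:
        self._buf[self._count % self._n] = float(value)
        self._count += 1

    def lookup_abs(self, t_query: float) -> float:
        """Value at absolute time ``t_query`` (nearest-not-later sample)."""
        k = int((t_query - self.t0) / self.dt + 1e-9)
        if self._count == 0 or k < 0:
            k = 0
        k = min(k, self._count - 1) if self._count else 0
        if self._count == 0:
            return self._buf[0]
        if k < self._count - self._n:
            raise ValueError("delay exceeds the buffer span")
        return self._buf[k % self._n]

    def lookup(self, t: float, d: float) -> float:
        """Value of the signal at ``t - d``."""
        if d < 0:
            raise ValueError("delay must be non-negative")
        if d > self.span + self.dt * 0.5:
            raise ValueError(
                f"delay {d} exceeds buffer span {self.span}; "
                "configure the buffer with a larger span"
            )
        return self.lookup_abs(t - d)


def delayed_signal(buffer: DelayBuffer, t: float, d: float) -> float:
    """Delayed proprioceptive signal value at ``t - d`` (exact for
    sample-aligned queries)."""
    return buffer.lookup(t, d)


# ---------------------------------------------------------------------------
# stimulation laws
# ---------------------------------------------------------------------------

def stim_alpha(t: float, cfg: ControllerConfig) -> float:
    """Open-loop stimulation: the schedule value clamped to [0, 1]."""
    return _clamp01(cfg.stim_open(t))


def _lambda_term(t: float, l_CE_delayed: float, v_CE_delayed: float,
                 cfg: ControllerConfig, l_CE_opt: float) -> float:
    err_l = l_CE_delayed - cfg.lam_at(t)
    err_v = v_CE_delayed - cfg.lam_dot
    return (cfg.k_p * err_l + cfg.k_d * err_v) / l_CE_opt


def stim_lambda(t: float, l_CE_delayed: float, v_CE_delayed: float,
                cfg: ControllerConfig, l_CE_opt: float) -> float:
    """Closed-loop PD stimulation on the delayed fibre-length error,
    normalized by the optimal fibre length and clamped to [0, 1]."""
    return _clamp01(_lambda_term(t, l_CE_delayed, v_CE_delayed, cfg, l_CE_opt))


def stim_hybrid(t: float, l_CE_delayed: float, v_CE_delayed: float,
                cfg: ControllerConfig, l_CE_opt: float,
                variant: str = "kistemaker") -> float:
    """Hybrid open- plus closed-loop stimulation.

    ``kistemaker``: the signed lambda term is added to the open-loop term
    and the sum is clamped once — the feedback may inhibit the open-loop
    drive.  ``standard``: each term is clamped to [0, 1] first (the
    lambda addendum can only add stimulation), then the sum is clamped.
    """
    alpha = cfg.stim_open(t)
    lam = _lambda_term(t, l_CE_delayed, v_CE_delayed, cfg, l_CE_opt)
    if variant == "kistemaker":
        return _clamp01(alpha + lam)
    if variant == "standard":
        return _clamp01(_clamp01(alpha) + _clamp01(lam))
    raise ValueError(f"unknown hybrid variant {variant!r}")


def strain_ce(l_CE_delayed: float, l_CE_ref: float) -> float:
    """Engineering strain of the delayed fibre length against the
    reference length."""
    if l_CE_ref <= 0:
        raise ValueError("l_CE_ref must be strictly positive")
    return (l_CE_delayed - l_CE_ref) / l_CE_ref


def stim_reflex(t: float, strain: float, cfg: ControllerConfig) -> float:
    """Bang-bang stretch-reflex stimulation: 1 when the strain exceeds the
    threshold omega and the gate (t > t_contr + tau) is open, else 0.
    Strain exactly at the threshold does not fire."""
    if t <= cfg.t_contr + cfg.tau_reflex:
        return 0.0
    return 1.0 if strain > cfg.omega else 0.0


# ---------------------------------------------------------------------------
# per-muscle runtime controller
# ---------------------------------------------------------------------------

class Controller:
    """Binds a ControllerConfig to a muscle's proprioceptive buffers.

    Holds the only piece of controller state: the frozen strain reference
    length of the reflex, captured at the controller activation time when
    not set explicitly (making the strain zero at gate opening).
    """

    def __init__(self, cfg: ControllerConfig, l_CE_opt: float):
        self.cfg = cfg
        self.l_CE_opt = l_CE_opt
        self._l_ref = cfg.l_CE_ref

    def stim(self, t: float, buf_l: DelayBuffer, buf_v: DelayBuffer) -> float:
        cfg = self.cfg
        if cfg.mode == "none":
            return 0.0
        if cfg.mode == "alpha":
            return stim_alpha(t, cfg)

        if cfg.mode == "reflex":
            if self._l_ref is None and t >= cfg.t_contr:
                self._l_ref = buf_l.lookup_abs(cfg.t_contr)
            if self._l_ref is None:
                return 0.0
            eps = strain_ce(buf_l.lookup(t, cfg.tau_reflex), self._l_ref)
            return stim_reflex(t, eps, cfg)

        l_d = buf_l.lookup(t, cfg.delta)
        v_d = buf_v.lookup(t, cfg.delta)
        if cfg.mode == "lambda":
            return stim_lambda(t, l_d, v_d, cfg, self.l_CE_opt)
        variant = "kistemaker" if cfg.mode == "hybrid_kistemaker" else "standard"
        return stim_hybrid(t, l_d, v_d, cfg, self.l_CE_opt, variant)
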