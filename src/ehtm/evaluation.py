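"""Trajectory comparison and kinematic summary metrics.

Simulated joint trajectories are scored against reference signals with
the mean squared error on a common time base, and summarised by peak
angular velocity, settling time after an EP switch and peak displacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rigs import SimResult

__all__ = ["SignalPair", "mse", "kinematic_metrics"]


@dataclass
class SignalPair:
    """A reference and a test series resampled onto a common base.

    The common base is the reference's sample times restricted to the
    overlap of both series; the test series is linearly interpolated onto
    it.
    """

    t_ref: np.ndarray
    y_ref: np.ndarray
    t_test: np.ndarray
    y_test: np.ndarray

    def common_base(self):
        lo = max(self.t_ref[0], self.t_test[0])
        hi = min(self.t_ref[-1], self.t_test[-1])
        mask = (self.t_ref >= lo) & (self.t_ref <= hi)
        t = self.t_ref[mask]
        if len(t) < 2:
            raise ValueError("signals share fewer than two common samples")
        return t, self.y_ref[mask], np.interp(t, self.t_test, self.y_test)


def mse(pair: SignalPair) -> float:
    """Mean squared pointwise difference on the common time base."""
    _, ref, test = pair.common_base()
    d = ref - test
    return float(np.mean(d * d))


def kinematic_metrics(result: SimResult, switch_time: float | None = None,
                      band: float = 0.02) -> dict[str, float]:
    """Kinematic summary of a run.

    ``peak_velocity``: max |coord rate| (after ``switch_time`` if given).
    ``settling_time``: time from the switch until the coordinate stays
    within ``band`` (fraction of the step amplitude) of its final value;
    0 for a constant run.  ``peak_displacement``: max |coord - coord(0)|.
    """
    t = result.t
    x = result.coord
    v = result.coord_vel

    t0 = switch_time if switch_time is not None else float(t[0])
    sel = t >= t0
    if not np.any(sel):
        raise ValueError("switch_time beyond the end of the run")

    peak_velocity = float(np.max(np.abs(v[sel])))
    peak_displacement = float(np.max(np.abs(x - x[0])))

    xs = x[sel]
    ts = t[sel]
    x_final = float(np.mean(xs[max(len(xs) - max(len(xs) // 20, 1), 0):]))
    amplitude = abs(x_final - float(xs[0]))
    if amplitude < 1e-12:
        settling_time = 0.0
    else:
        tol = band * amplitude
        outside = np.abs(xs - x_final) >= tol
        if not np.any(outside):
            settling_time = 0.0
        else:
            last_out = np.max(np.nonzero(outside)[0])
            if last_out + 1 >= len(ts):
                settling_time = float(ts[-1] - t0)  # never settles in-window
            else:
                settling_time = float(ts[last_out + 1] - t0)
    return {
        "peak_velocity": peak_velocity,
        "settling_time": settling_time,
        "peak_displacement": peak_displacement,
    }
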