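"""Isometric test bench with a stimulation ramp.

A single muscle-tendon unit is clamped at a fixed length and the
stimulation ramps from 0 to 1 over 300-700 ms.  The tendon-side output
force rises smoothly and monotonically (the serial damping element
suppresses the oscillations a purely elastic tendon would show) and
settles at the full isometric capacity for that fibre length.
"""

import numpy as np

from ehtm import default_muscle, simulate_mtu_bench

p, act = default_muscle("generic")
res = simulate_mtu_bench("ramp", p, act, duration=1200.0, dt=0.1)

f = res.muscles["mtu"]["force"]
q = res.muscles["mtu"]["q"]
for t_ms in (0, 300, 500, 700, 900, 1150):
    k = np.searchsorted(res.t, t_ms)
    print(f"t = {t_ms:5d} ms   stim = {res.muscles['mtu']['stim'][k]:.2f}   "
          f"q = {q[k]:.3f}   force = {f[k]:.4f} kN")
onset = np.searchsorted(res.t, 320.0)
print(f"monotone rise after onset: {bool(np.min(np.diff(f[onset:])) > -1e-6)}")
print(f"settled force {f[-1]:.3f} kN out of F_max = {p.F_max} kN "
      f"(fibre off-optimum and tendon stretch take the rest)")
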