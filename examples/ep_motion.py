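"""Equilibrium-point motion on the antagonistic elbow rig.

Optimises minimum-effort stimulation vectors for two elbow postures
(~65 and ~100 degrees), then performs the step movement between them
twice: once purely open-loop (alpha) and once with the hybrid controller
that adds delayed muscle-length feedback.  The feedback both inhibits the
antagonist and boosts the agonist during the transient, so the hybrid
movement is several times faster at the same equilibrium points.

Takes a couple of minutes: each optimisation runs ~100 forward
simulations of the rig.
"""

import math

import numpy as np

from ehtm import EPProblem, find_ep, generate_motion, make_rig, simulate_rig
from ehtm.fixtures import ELBOW_GAINS

rig = make_rig("elbow_pair")
print("optimising equilibrium points (min effort) ...")
ep_flex = find_ep(EPProblem(phi_target=math.radians(100.0), seed=1), rig)
ep_ext = find_ep(EPProblem(phi_target=math.radians(65.0), seed=1), rig)
for name, ep in (("flexed", ep_flex), ("extended", ep_ext)):
    print(f"  {name}: stim = {tuple(round(s, 4) for s in ep.stim_opt)}, "
          f"phi = {math.degrees(ep.phi):.1f} deg, "
          f"lambda = {tuple(round(l, 1) for l in ep.lam)} mm")

seq, switches = [ep_flex, ep_ext, ep_flex], [800.0, 1600.0]
peaks = {}
for variant, gains in (("alpha", {}), ("hybrid_kistemaker", ELBOW_GAINS)):
    cfgs = generate_motion(seq, switches, variant, **gains)
    res = simulate_rig(rig.with_controllers(cfgs), 2400.0, 0.25)
    peak = float(np.max(np.abs(res.coord_vel[res.t >= 1600.0])))
    peaks[variant] = peak
    print(f"{variant:18s} second-step peak |phi_dot| = {peak * 1e3:.2f} rad/s, "
          f"final angle = {math.degrees(res.coord[-1]):.1f} deg")
print(f"hybrid / alpha peak-velocity ratio: "
      f"{peaks['hybrid_kistemaker'] / peaks['alpha']:.2f}")
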