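"""Evaluate the four element force laws at their anchor points.

Builds the generic fixture muscle (F_max = 1 kN, l_CE_opt = 45 mm,
l_SEE_0 = 45 mm, non-specific defaults) and prints the characteristic
values of the force-length, parallel-elastic and serial-elastic curves.
"""

from ehtm import MuscleState, default_muscle, f_isom, f_pee, f_sde, f_see

p, _ = default_muscle("generic")

print(f"CE force-length peak at l_CE_opt:        {f_isom(p.l_CE_opt, p):.3f}")
print(f"CE force at 0.7 l_CE_opt (ascending):    {f_isom(0.7 * p.l_CE_opt, p):.3f}")
print(f"CE force at 1.3 l_CE_opt (descending):   {f_isom(1.3 * p.l_CE_opt, p):.3f}")
print(f"PEE force at its rest length (0.95):     {f_pee(0.95 * p.l_CE_opt, p):.3f} kN")
print(f"PEE force at 1.45 l_CE_opt:              {f_pee(1.45 * p.l_CE_opt, p):.3f} kN"
      f"  (= F_PEE x F_max by construction)")
print(f"SEE force at slack length:               {f_see(p.l_SEE_0, p):.3f} kN")
see_at_nll = f_see(p.l_SEE_0 * 1.0425, p)
print(f"SEE force at transition strain 4.25 %:   {see_at_nll:.3f} kN"
      f"  (= 0.4 x F_max = {0.4 * p.F_max:.3f})")
state = MuscleState(l_MTU=p.l_CE_opt + 1.02 * p.l_SEE_0, l_CE=p.l_CE_opt,
                    v_CE=0.0, v_MTU=0.1, q=0.5)
print(f"SDE force, taut tendon lengthening at 0.1 mm/ms: "
      f"{f_sde(state, 0.5 * p.F_max, p):.4f} kN")

# The first two lines say the bell is exactly 1 at the optimum and lower on
# both limbs; the SEE line reproduces the 0.4 F_max transition-force rule.
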