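"""Four-element Hill-type muscle-tendon unit (MTU) mechanics.

The MTU is a one-dimensional element made of two groups in series: the
muscle belly, a contractile element (CE) in parallel with a parallel
elastic element (PEE), and the tendon, a serial elastic element (SEE) in
parallel with a serial damping element (SDE).  The internal force
equilibrium

    F_CE + F_PEE = F_SEE + F_SDE

is resolved for the fibre contraction velocity ``v_CE`` at every instant;
the tendon-side sum ``F_SEE + F_SDE`` is the force transmitted to the
skeleton.

The shipped default parameter set uses the kg-mm-ms-kN unit system, in
which forces come out in kN, lengths in mm, times in ms and velocities in
mm/ms.  The formulas themselves are unit-agnostic: any self-consistent
system works.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy.optimize import brentq

__all__ = [
    "MuscleParams",
    "MuscleState",
    "f_isom",
    "f_pee",
    "f_see",
    "f_sde",
    "contraction_velocity",
    "mtu_force",
    "static_fibre_length",
    "pee_energy",
    "see_energy",
    "element_curves",
]

# normalized root-finding tolerance for the brentq fallback
_V_TOL = 1e-10


@dataclass(frozen=True)
class MuscleParams:
    """Mechanical constants of one muscle-tendon unit.

    The three muscle-specific values (``F_max``, ``l_CE_opt``,
    ``l_SEE_0``) must always be supplied; everything else defaults to the
    non-specific parameter set in the kg-mm-ms-kN unit system.  The force
    at the SEE nonlinear-linear transition ``dF_SEE_0`` defaults to
    ``0.4 * F_max``.
    """

    F_max: float            # maximum isometric force [kN]
    l_CE_opt: float         # optimal fibre length [mm]
    l_SEE_0: float          # tendon slack length [mm]
    # CE force-length relation (exponential bell, two limbs)
    dW_des: float = 0.45    # width of descending limb [-]
    dW_asc: float = 0.45    # width of ascending limb [-]
    nu_CE_des: float = 1.5  # exponent of descending limb [-]
    nu_CE_asc: float = 3.0  # exponent of ascending limb [-]
    # CE force-velocity relation (Hill hyperbola + eccentric branch)
    A_rel_0: float = 0.2    # normalized Hill constant [-]
    B_rel_0: float = 0.002  # normalized Hill constant [1/ms]
    F_ecc: float = 1.5      # eccentric force ceiling / F_max·q·F_isom [-]
    S_ecc: float = 2.0      # eccentric/concentric slope ratio at v=0 [-]
    # PEE
    L_PEE_0: float = 0.95   # PEE rest length / l_CE_opt [-]
    nu_PEE: float = 2.5     # PEE exponent [-]
    F_PEE: float = 2.0      # PEE force scale [-]
    # SEE
    dU_SEE_nll: float = 0.0425  # strain at nonlinear-linear transition [-]
    dU_SEE_l: float = 0.017     # linear strain parameter [-]
    dF_SEE_0: float | None = None  # force at the transition [kN]; 0.4·F_max
    # SDE
    D_SDE: float = 0.3      # damping scale [-]
    R_SDE: float = 0.01     # minimum damping ratio [-]

    def __post_init__(self) -> None:
        if self.dF_SEE_0 is None:
            object.__setattr__(self, "dF_SEE_0", 0.4 * self.F_max)
        for name in ("F_max", "l_CE_opt", "l_SEE_0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in (
            "dW_des", "dW_asc", "nu_CE_des", "nu_CE_asc", "A_rel_0",
            "B_rel_0", "S_ecc", "L_PEE_0", "nu_PEE", "F_PEE",
            "dU_SEE_nll", "dU_SEE_l", "dF_SEE_0", "D_SDE",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.F_ecc <= 1:
            raise ValueError("F_ecc must exceed 1")
        if not 0 <= self.R_SDE <= 1:
            raise ValueError("R_SDE must lie in [0, 1]")

    # -- derived constants -------------------------------------------------

    @property
    def K_PEE(self) -> float:
        """PEE stiffness scale so that F_PEE·F_max is reached at
        l_CE = l_CE_opt·(1 + dW_des)."""
        span = self.l_CE_opt * (self.dW_des + 1.0 - self.L_PEE_0)
        return self.F_PEE * self.F_max / span ** self.nu_PEE

    @property
    def nu_SEE(self) -> float:
        """Exponent of the SEE toe region; chosen so force and slope are
        continuous at the nonlinear-linear transition."""
        return self.dU_SEE_nll / self.dU_SEE_l

    @property
    def K_SEE_nl(self) -> float:
        return self.dF_SEE_0 / (self.dU_SEE_nll * self.l_SEE_0) ** self.nu_SEE

    @property
    def K_SEE_l(self) -> float:
        return self.dF_SEE_0 / (self.dU_SEE_l * self.l_SEE_0)

    @property
    def d_SE_max(self) -> float:
        """Maximum SDE damping coefficient [kN/(mm/ms)]."""
        return (
            self.D_SDE * self.F_max * self.A_rel_0
            / (self.l_CE_opt * self.B_rel_0)
        )

    def with_scale(self, factor: float) -> "MuscleParams":
        """Geometrically similar muscle with all lengths scaled."""
        return replace(
            self,
            l_CE_opt=self.l_CE_opt * factor,
            l_SEE_0=self.l_SEE_0 * factor,
        )


@dataclass
class MuscleState:
    """Instantaneous state of one MTU."""

    t: float = 0.0          # time [ms]
    l_MTU: float = 0.0      # total muscle-tendon length [mm]
    l_CE: float = 0.0       # fibre length [mm]
    v_CE: float = 0.0       # fibre velocity [mm/ms]
    v_MTU: float = 0.0      # MTU lengthening rate [mm/ms]
    q: float = 0.0          # activation [-]
    gamma: float = 0.0      # free-calcium state [-]

    @property
    def l_SEE(self) -> float:
        return self.l_MTU - self.l_CE

    def l_CE_rel(self, p: MuscleParams) -> float:
        return self.l_CE / p.l_CE_opt


# ---------------------------------------------------------------------------
# element force laws
# ---------------------------------------------------------------------------

def f_isom(l_CE: float, p: MuscleParams) -> float:
    """Normalized isometric force-length relation of the CE.

    Exponential bell with separate ascending (l_CE < l_CE_opt) and
    descending limbs; exactly 1 at the optimal fibre length.
    """
    if l_CE <= 0:
        raise ValueError("l_CE must be strictly positive")
    x = l_CE / p.l_CE_opt - 1.0
    if x < 0:
        return math.exp(-abs(x / p.dW_asc) ** p.nu_CE_asc)
    return math.exp(-abs(x / p.dW_des) ** p.nu_CE_des)


def f_pee(l_CE: float, p: MuscleParams) -> float:
    """Parallel elastic element force [kN]; power law above its rest
    length ``L_PEE_0 * l_CE_opt``, zero below."""
    if l_CE <= 0:
        raise ValueError("l_CE must be strictly positive")
    slack = p.L_PEE_0 * p.l_CE_opt
    if l_CE <= slack:
        return 0.0
    return p.K_PEE * (l_CE - slack) ** p.nu_PEE


def f_see(l_SEE: float, p: MuscleParams) -> float:
    """Serial elastic element (tendon) force [kN].

    Zero below the slack length; a power-law toe region up to strain
    ``dU_SEE_nll`` where the force is exactly ``dF_SEE_0``; linear beyond,
    with continuous force and slope at the transition.
    """
    if l_SEE < 0:
        raise ValueError("l_SEE must be non-negative")
    dl = l_SEE - p.l_SEE_0
    if dl <= 0:
        return 0.0
    dl_nll = p.dU_SEE_nll * p.l_SEE_0
    if dl < dl_nll:
        return p.K_SEE_nl * dl ** p.nu_SEE
    return p.dF_SEE_0 + p.K_SEE_l * (dl - dl_nll)


def _sde_coeff(f_ce: float, f_pee_val: float, l_SEE: float, p: MuscleParams) -> float:
    """Force-dependent SDE damping coefficient, gated on tendon slack."""
    if l_SEE <= p.l_SEE_0:
        return 0.0
    rel = max((f_ce + f_pee_val) / p.F_max, 0.0)
    return p.d_SE_max * ((1.0 - p.R_SDE) * rel + p.R_SDE)


def f_sde(state: MuscleState, f_ce: float, p: MuscleParams) -> float:
    """Serial damping element force [kN]: viscous in the tendon
    lengthening rate ``v_MTU - v_CE``, with a coefficient interpolated
    between ``R_SDE`` and 1 (scaled by ``D_SDE``) depending on the muscle
    force; exactly zero while the tendon is at or below its rest length.
    """
    coeff = _sde_coeff(f_ce, f_pee(state.l_CE, p), state.l_SEE, p)
    return coeff * (state.v_MTU - state.v_CE)


# ---------------------------------------------------------------------------
# CE force-velocity relation and contraction dynamics
# ---------------------------------------------------------------------------

def _a_rel(l_CE: float, q: float, p: MuscleParams) -> float:
    L = 1.0 if l_CE < p.l_CE_opt else f_isom(l_CE, p)
    return p.A_rel_0 * L * (1.0 + 3.0 * q) / 4.0


def _b_rel(q: float, p: MuscleParams) -> float:
    return p.B_rel_0 * (3.0 + 4.0 * q) / 7.0


def _ecc_branch(fisom: float, q: float, A: float, B: float, p: MuscleParams):
    """Eccentric branch parameters (A_e, B_e) giving a hyperbola through
    (v=0, q·F_isom·F_max) with asymptote F_ecc·q·F_isom·F_max and slope
    S_ecc times the concentric slope at v = 0."""
    qf = max(q * fisom, 1e-12)
    A_e = -p.F_ecc * qf
    B_e = B * (1.0 - p.F_ecc) / (p.S_ecc * (1.0 + A / qf))
    return A_e, B_e


def _f_ce_of_v(v: float, l_CE: float, q: float, p: MuscleParams) -> float:
    """CE force as a function of contraction velocity (both branches)."""
    fisom = f_isom(l_CE, p)
    A = _a_rel(l_CE, q, p)
    B = _b_rel(q, p)
    if v > 0:
        A, B = _ecc_branch(fisom, q, A, B, p)
    u = 1.0 - v / (B * p.l_CE_opt)
    return p.F_max * ((q * fisom + A) / u - A)


def _solve_branch(A: float, B: float, q: float, fisom: float, f_pee_val: float,
                  f_see_val: float, d: float, v_MTU: float, p: MuscleParams):
    """Closed-form roots of the force balance on one Hill branch.

    Substituting u = 1 - v/(B·l_CE_opt) into
    F_CE(v) + F_PEE - F_SEE - D(F_CE)·(v_MTU - v) = 0 with the
    force-dependent damping coefficient yields a quadratic in u.
    Returns candidate velocities.
    """
    Bl = B * p.l_CE_opt
    R = p.R_SDE
    qf = q * fisom
    P = (1.0 - R) * (qf + A)
    Q = (1.0 - R) * (f_pee_val / p.F_max - A) + R
    w = v_MTU - Bl
    c2 = -d * Q * Bl
    c1 = (f_pee_val - f_see_val - p.F_max * A) - d * (P * Bl + Q * w)
    c0 = p.F_max * (qf + A) - d * P * w
    roots = []
    if abs(c2) < 1e-14 * max(1.0, abs(c1)):
        if c1 != 0.0:
            roots.append(-c0 / c1)
    else:
        disc = c1 * c1 - 4.0 * c2 * c0
        if disc >= 0:
            sq = math.sqrt(disc)
            roots.extend([(-c1 + sq) / (2 * c2), (-c1 - sq) / (2 * c2)])
    return [Bl * (1.0 - u) for u in roots if u > 0]


def contraction_velocity(state: MuscleState, q: float, p: MuscleParams) -> float:
    """Fibre velocity solving the internal force balance
    ``F_CE + F_PEE = F_SEE + F_SDE`` at the given state and activation.

    The concentric and eccentric Hill branches join continuously at
    v_CE = 0; the branch is selected from the sign of the isometric force
    surplus.  Closed-form branch roots are used where admissible, with a
    bracketed scalar root-find as fallback.
    """
    return _solve_v_ce(state.l_CE, state.l_MTU, state.v_MTU, q, p)


def _solve_v_ce(l_CE: float, l_MTU: float, v_MTU: float, q: float,
                p: MuscleParams) -> float:
    l_CE = max(l_CE, 1e-9 * p.l_CE_opt)
    fisom = f_isom(l_CE, p)
    fp = f_pee(l_CE, p)
    l_SEE = l_MTU - l_CE
    fs = f_see(max(l_SEE, 0.0), p)
    d = 0.0 if l_SEE <= p.l_SEE_0 else p.d_SE_max

    A = _a_rel(l_CE, q, p)
    B = _b_rel(q, p)

    # isometric residual decides the branch: surplus CE force -> shortening
    f_ce0 = q * fisom * p.F_max
    g0 = f_ce0 + fp - fs - _sde_coeff(f_ce0, fp, max(l_SEE, 0.0), p) * v_MTU
    if g0 > 0:
        branch_A, branch_B, want_neg = A, B, True
    else:
        A_e, B_e = _ecc_branch(fisom, q, A, B, p)
        branch_A, branch_B, want_neg = A_e, B_e, False

    cands = _solve_branch(branch_A, branch_B, q, fisom, fp, fs, d, v_MTU, p)
    v_scale = p.B_rel_0 * p.l_CE_opt
    tol = 1e-9 * v_scale
    for v in sorted(cands, key=abs):
        if (want_neg and v <= tol) or (not want_neg and v >= -tol):
            # verify the residual before accepting the closed form
            res = _balance_residual(v, l_CE, l_MTU, v_MTU, q, p)
            if abs(res) < 1e-8 * p.F_max:
                return v

    return _bracketed_solve(l_CE, l_MTU, v_MTU, q, p, v_scale)


def _balance_residual(v: float, l_CE: float, l_MTU: float, v_MTU: float,
                      q: float, p: MuscleParams) -> float:
    f_ce = _f_ce_of_v(v, l_CE, q, p)
    fp = f_pee(l_CE, p)
    fs = f_see(max(l_MTU - l_CE, 0.0), p)
    coeff = _sde_coeff(f_ce, fp, max(l_MTU - l_CE, 0.0), p)
    return f_ce + fp - fs - coeff * (v_MTU - v)


def _bracketed_solve(l_CE, l_MTU, v_MTU, q, p, v_scale) -> float:
    g = lambda v: _balance_residual(v, l_CE, l_MTU, v_MTU, q, p)
    # g is increasing in v: CE force grows from the concentric toward the
    # eccentric branch and the damping term grows with v
    lo, hi = -40.0 * v_scale, 40.0 * v_scale
    glo = g(lo)
    if glo > 0.0:
        # surplus belly force even at fast shortening: happens with a
        # slack tendon and an engaged PEE (the Hill hyperbola cannot pull
        # negative enough).  Clamp at the fast-shortening floor so rigs
        # stay integrable through such transients.
        return lo
    ghi = g(hi)
    grow = 0
    while ghi < 0.0 and grow < 40:
        hi *= 2.0
        ghi = g(hi)
        grow += 1
    if ghi < 0.0:
        raise ArithmeticError(
            "no admissible contraction-velocity root: "
            f"l_CE={l_CE!r} l_MTU={l_MTU!r} v_MTU={v_MTU!r} q={q!r}"
        )
    return brentq(g, lo, hi, xtol=_V_TOL * max(1.0, v_scale), rtol=1e-14)


def mtu_force(state: MuscleState, p: MuscleParams) -> float:
    """Tendon-side output force ``F_SEE + F_SDE`` transmitted to the
    skeleton.  Equals ``F_CE + F_PEE`` whenever ``state.v_CE`` came from
    :func:`contraction_velocity`."""
    fs = f_see(max(state.l_SEE, 0.0), p)
    f_ce = _f_ce_of_v(state.v_CE, max(state.l_CE, 1e-9 * p.l_CE_opt), state.q, p)
    coeff = _sde_coeff(f_ce, f_pee(state.l_CE, p), max(state.l_SEE, 0.0), p)
    return fs + coeff * (state.v_MTU - state.v_CE)


# ---------------------------------------------------------------------------
# statics, energies, curve export
# ---------------------------------------------------------------------------

def static_fibre_length(l_MTU: float, q: float, p: MuscleParams) -> float:
    """Fibre length at static equilibrium
    ``q·F_isom·F_max + F_PEE = F_SEE`` for a fixed MTU length."""
    if l_MTU <= 0:
        raise ValueError("l_MTU must be positive")

    def g(l_CE: float) -> float:
        return (q * f_isom(l_CE, p) * p.F_max + f_pee(l_CE, p)
                - f_see(max(l_MTU - l_CE, 0.0), p))

    lo = 1e-6 * p.l_CE_opt
    hi = l_MTU
    if g(lo) > 0:  # tendon slack even at minimal fibre length
        return l_MTU - p.l_SEE_0 if l_MTU > p.l_SEE_0 else l_MTU
    return brentq(g, lo, hi, xtol=1e-12 * p.l_CE_opt, rtol=1e-15)


def pee_energy(l_CE: float, p: MuscleParams) -> float:
    """Elastic energy stored in the PEE [kN·mm]."""
    slack = p.L_PEE_0 * p.l_CE_opt
    if l_CE <= slack:
        return 0.0
    n = p.nu_PEE
    return p.K_PEE * (l_CE - slack) ** (n + 1.0) / (n + 1.0)


def see_energy(l_SEE: float, p: MuscleParams) -> float:
    """Elastic energy stored in the SEE [kN·mm]."""
    dl = l_SEE - p.l_SEE_0
    if dl <= 0:
        return 0.0
    dl_nll = p.dU_SEE_nll * p.l_SEE_0
    n = p.nu_SEE
    if dl <= dl_nll:
        return p.K_SEE_nl * dl ** (n + 1.0) / (n + 1.0)
    toe = p.K_SEE_nl * dl_nll ** (n + 1.0) / (n + 1.0)
    x = dl - dl_nll
    return toe + p.dF_SEE_0 * x + 0.5 * p.K_SEE_l * x * x


def element_curves(p: MuscleParams, n: int = 200):
    """Two-column samples of the element curves for plotting/regression.

    Returns a dict of (x, y) column pairs: CE force-length over
    [0.4, 1.8]·l_CE_opt, PEE force over the same range, SEE force over
    strain [0, 2·dU_SEE_nll].
    """
    import numpy as np

    l = np.linspace(0.4 * p.l_CE_opt, 1.8 * p.l_CE_opt, n)
    strain = np.linspace(0.0, 2.0 * p.dU_SEE_nll, n)
    return {
        "ce_force_length": (l, np.array([f_isom(x, p) for x in l])),
        "pee_force_length": (l, np.array([f_pee(x, p) for x in l])),
        "see_force_strain": (
            strain,
            np.array([f_see(p.l_SEE_0 * (1.0 + s), p) for s in strain]),
        ),
    }
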