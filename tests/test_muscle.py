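"""Element force laws and contraction dynamics of the four-element MTU."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ehtm import (
    MuscleParams,
    MuscleState,
    contraction_velocity,
    default_muscle,
    f_isom,
    f_pee,
    f_sde,
    f_see,
    mtu_force,
)
from ehtm.muscle import _f_ce_of_v, _solve_v_ce, pee_energy, see_energy


@pytest.fixture(scope="module")
def p():
    return default_muscle("generic")[0]


class TestForceLength:
    def test_maximum_at_optimal_length(self, p):
        assert f_isom(p.l_CE_opt, p) == 1.0
        grid = np.linspace(0.4, 1.8, 141) * p.l_CE_opt
        vals = [f_isom(l, p) for l in grid]
        assert max(vals) <= 1.0
        assert np.argmax(vals) == np.argmin(np.abs(grid - p.l_CE_opt))

    def test_extreme_stretch_matches_closed_form(self, p):
        # independent evaluation of the descending-limb exponential
        expected = math.exp(-((2.5 - 1.0) / p.dW_des) ** p.nu_CE_des)
        assert f_isom(2.5 * p.l_CE_opt, p) == pytest.approx(expected, rel=1e-12)
        assert expected < 0.01

    def test_limbs_are_asymmetric(self, p):
        # nu_asc=3.0 vs nu_des=1.5 make equal offsets give unequal force
        # (offsets of exactly dW are the one crossing point of the limbs,
        # where both give 1/e — probe inside that)
        lo = f_isom(0.70 * p.l_CE_opt, p)
        hi = f_isom(1.30 * p.l_CE_opt, p)
        assert lo != pytest.approx(hi, rel=1e-3)
        assert lo == pytest.approx(math.exp(-(0.30 / p.dW_asc) ** 3.0), rel=1e-12)
        assert hi == pytest.approx(math.exp(-(0.30 / p.dW_des) ** 1.5), rel=1e-12)
        # at exactly dW both limbs meet at 1/e
        assert f_isom(0.55 * p.l_CE_opt, p) == pytest.approx(
            f_isom(1.45 * p.l_CE_opt, p), rel=1e-12)

    def test_domain_error(self, p):
        with pytest.raises(ValueError):
            f_isom(0.0, p)
        with pytest.raises(ValueError):
            f_isom(-1.0, p)


class TestPEE:
    @pytest.mark.parametrize("rel", [0.5, 0.9, 0.95])
    def test_zero_at_or_below_slack(self, p, rel):
        assert f_pee(rel * p.l_CE_opt, p) == 0.0

    def test_power_law_above_slack(self, p):
        # anchor: F_PEE * F_max at l_CE_opt * (1 + dW_des)
        anchor = f_pee(p.l_CE_opt * (1.0 + p.dW_des), p)
        assert anchor == pytest.approx(p.F_PEE * p.F_max, rel=1e-12)
        a, b = f_pee(1.1 * p.l_CE_opt, p), f_pee(1.3 * p.l_CE_opt, p)
        assert 0.0 < a < b
        # exponent check against direct evaluation
        ratio = b / a
        expected = ((1.3 - p.L_PEE_0) / (1.1 - p.L_PEE_0)) ** p.nu_PEE
        assert ratio == pytest.approx(expected, rel=1e-12)


class TestSEE:
    def test_slack_and_transition_anchor(self, p):
        assert f_see(p.l_SEE_0, p) == 0.0
        assert f_see(0.5 * p.l_SEE_0, p) == 0.0
        at_nll = f_see(p.l_SEE_0 * (1.0 + p.dU_SEE_nll), p)
        assert at_nll == pytest.approx(0.4 * p.F_max, rel=1e-12)

    def test_slope_continuity_at_transition(self, p):
        lt = p.l_SEE_0 * (1.0 + p.dU_SEE_nll)
        h = 1e-7 * p.l_SEE_0
        below = (f_see(lt, p) - f_see(lt - h, p)) / h
        above = (f_see(lt + h, p) - f_see(lt, p)) / h
        assert below == pytest.approx(above, rel=1e-5)

    def test_linear_beyond_transition(self, p):
        lt = p.l_SEE_0 * (1.0 + p.dU_SEE_nll)
        f1 = f_see(lt + 1.0, p)
        f2 = f_see(lt + 2.0, p)
        f3 = f_see(lt + 3.0, p)
        assert f3 - f2 == pytest.approx(f2 - f1, rel=1e-12)

    def test_negative_length_rejected(self, p):
        with pytest.raises(ValueError):
            f_see(-1.0, p)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.0, 0.12), st.floats(0.0, 0.12))
    def test_monotone_in_strain(self, p, s1, s2):
        lo, hi = sorted((s1, s2))
        assert f_see(p.l_SEE_0 * (1 + lo), p) <= f_see(p.l_SEE_0 * (1 + hi), p)


class TestSDE:
    def test_zero_when_tendon_slack_or_at_rest(self, p):
        slack = MuscleState(l_MTU=p.l_CE_opt + 0.9 * p.l_SEE_0,
                            l_CE=p.l_CE_opt, v_CE=-0.1, v_MTU=0.5, q=1.0)
        assert f_sde(slack, 0.5 * p.F_max, p) == 0.0
        taut_static = MuscleState(l_MTU=p.l_CE_opt + 1.02 * p.l_SEE_0,
                                  l_CE=p.l_CE_opt, v_CE=0.0, v_MTU=0.0, q=1.0)
        assert f_sde(taut_static, 0.5 * p.F_max, p) == 0.0

    def test_linear_in_tendon_velocity(self, p):
        s1 = MuscleState(l_MTU=p.l_CE_opt + 1.02 * p.l_SEE_0,
                         l_CE=p.l_CE_opt, v_CE=0.0, v_MTU=0.2, q=0.5)
        s2 = MuscleState(l_MTU=s1.l_MTU, l_CE=s1.l_CE, v_CE=0.0, v_MTU=0.4, q=0.5)
        f1 = f_sde(s1, 0.3 * p.F_max, p)
        f2 = f_sde(s2, 0.3 * p.F_max, p)
        assert f1 > 0
        assert f2 == pytest.approx(2.0 * f1, rel=1e-12)


class TestContractionDynamics:
    def test_isometric_equilibrium_gives_zero_velocity(self, p):
        # prepare a state where the static balance holds exactly
        from scipy.optimize import brentq

        q = 0.7
        l_mtu = p.l_CE_opt + p.l_SEE_0 * 1.03
        g = lambda l: (q * f_isom(l, p) * p.F_max + f_pee(l, p)
                       - f_see(l_mtu - l, p))
        l_eq = brentq(g, 0.2 * p.l_CE_opt, l_mtu - 1e-9, xtol=1e-13)
        state = MuscleState(l_MTU=l_mtu, l_CE=l_eq, v_MTU=0.0)
        assert contraction_velocity(state, q, p) == pytest.approx(0.0, abs=1e-12)

    def test_quick_release_matches_concentric_root(self, p):
        # tendon force forced to zero, full activation, optimal length:
        # independent closed form u = (qF+A)/(A - F_PEE/F_max)
        q, l = 1.0, p.l_CE_opt
        A = p.A_rel_0 * (1 + 3 * q) / 4.0
        B = p.B_rel_0 * (3 + 4 * q) / 7.0
        u = (q * 1.0 + A) / (A - f_pee(l, p) / p.F_max)
        v_expected = B * p.l_CE_opt * (1.0 - u)
        state = MuscleState(l_MTU=l + p.l_SEE_0, l_CE=l, v_MTU=0.0)
        v = contraction_velocity(state, q, p)
        assert v == pytest.approx(v_expected, rel=1e-9)
        assert v < 0

    def test_eccentric_branch_force_below_ceiling(self, p):
        # imposed tendon force 1.2x the isometric capacity -> lengthening,
        # with CE force strictly under the eccentric asymptote
        q, l = 0.8, p.l_CE_opt
        target = 1.2 * q * f_isom(l, p) * p.F_max
        from scipy.optimize import brentq

        l_see = brentq(lambda s: f_see(s, p) - target,
                       p.l_SEE_0, 1.2 * p.l_SEE_0)
        state = MuscleState(l_MTU=l + l_see, l_CE=l, v_MTU=0.0)
        v = contraction_velocity(state, q, p)
        assert v > 0
        f_ce = _f_ce_of_v(v, l, q, p)
        assert f_ce < p.F_ecc * q * f_isom(l, p) * p.F_max

    def test_force_velocity_continuity_at_zero(self, p):
        q, l = 0.6, 1.05 * p.l_CE_opt
        eps = 1e-12  # small enough that slope * eps stays below the bound
        f_minus = _f_ce_of_v(-eps, l, q, p)
        f_plus = _f_ce_of_v(eps, l, q, p)
        f_zero = _f_ce_of_v(0.0, l, q, p)
        assert abs(f_minus - f_zero) / p.F_max < 1e-9
        assert abs(f_plus - f_zero) / p.F_max < 1e-9

    def test_eccentric_slope_ratio(self, p):
        # d(F_CE)/dv just above zero is S_ecc times the concentric slope
        q, l = 0.6, 1.05 * p.l_CE_opt
        h = 1e-7
        con = (_f_ce_of_v(0.0, l, q, p) - _f_ce_of_v(-h, l, q, p)) / h
        ecc = (_f_ce_of_v(h, l, q, p) - _f_ce_of_v(0.0, l, q, p)) / h
        assert ecc / con == pytest.approx(p.S_ecc, rel=1e-4)

    def test_internal_equilibrium_defines_output_force(self, p):
        # F_SEE + F_SDE == F_CE + F_PEE at the solved velocity
        for q, rel_mtu in [(0.2, 1.01), (0.9, 1.04), (0.5, 1.02)]:
            l_mtu = p.l_CE_opt + p.l_SEE_0 * rel_mtu
            l_ce = 0.97 * p.l_CE_opt
            for v_mtu in (-0.05, 0.0, 0.08):
                v = _solve_v_ce(l_ce, l_mtu, v_mtu, q, p)
                state = MuscleState(l_MTU=l_mtu, l_CE=l_ce, v_CE=v,
                                    v_MTU=v_mtu, q=q)
                tendon = mtu_force(state, p)
                belly = _f_ce_of_v(v, l_ce, q, p) + f_pee(l_ce, p)
                assert abs(tendon - belly) < 1e-8 * p.F_max

    def test_slack_everything_gives_zero_output(self, p):
        state = MuscleState(l_MTU=0.9 * (p.l_CE_opt + p.l_SEE_0),
                            l_CE=0.92 * p.l_CE_opt, v_CE=0.0, v_MTU=0.0, q=0.005)
        assert f_see(max(state.l_SEE, 0.0), p) == 0.0
        assert f_sde(state, 0.0, p) == 0.0

    @settings(derandomize=True, max_examples=40)
    @given(
        st.floats(0.01, 1.0),
        st.floats(0.7, 1.25),
        st.floats(1.001, 1.06),
        st.floats(-0.2, 0.2),
    )
    def test_solver_always_satisfies_balance(self, p, q, rel_ce, rel_see, v_mtu):
        # taut tendon: the balance always has a root and the solver must
        # satisfy it to numerical precision
        l_ce = rel_ce * p.l_CE_opt
        l_mtu = l_ce + rel_see * p.l_SEE_0
        v = _solve_v_ce(l_ce, l_mtu, v_mtu, q, p)
        from ehtm.muscle import _balance_residual

        assert abs(_balance_residual(v, l_ce, l_mtu, v_mtu, q, p)) < 1e-7 * p.F_max

    def test_slack_tendon_with_engaged_pee_clamps_shortening(self, p):
        # no admissible root exists (hyperbola asymptote above -F_PEE):
        # the solver returns a fast-shortening clamp instead of raising
        l_ce = 1.3 * p.l_CE_opt
        l_mtu = l_ce + 0.95 * p.l_SEE_0
        v = _solve_v_ce(l_ce, l_mtu, 0.0, 0.01, p)
        assert v < 0
        assert math.isfinite(v)


class TestParams:
    def test_default_transition_force_rule(self):
        p = MuscleParams(F_max=3.3, l_CE_opt=50.0, l_SEE_0=80.0)
        assert p.dF_SEE_0 == pytest.approx(0.4 * 3.3)

    def test_validation(self):
        with pytest.raises(ValueError):
            MuscleParams(F_max=-1.0, l_CE_opt=45.0, l_SEE_0=45.0)
        with pytest.raises(ValueError):
            MuscleParams(F_max=1.0, l_CE_opt=45.0, l_SEE_0=45.0, F_ecc=0.9)
        with pytest.raises(ValueError):
            MuscleParams(F_max=1.0, l_CE_opt=45.0, l_SEE_0=45.0, R_SDE=1.5)

    def test_nonspecific_defaults(self, p):
        assert (p.dW_des, p.dW_asc) == (0.45, 0.45)
        assert (p.nu_CE_des, p.nu_CE_asc) == (1.5, 3.0)
        assert (p.A_rel_0, p.B_rel_0) == (0.2, 0.002)
        assert (p.F_ecc, p.S_ecc) == (1.5, 2.0)
        assert (p.L_PEE_0, p.nu_PEE, p.F_PEE) == (0.95, 2.5, 2.0)
        assert (p.dU_SEE_nll, p.dU_SEE_l) == (0.0425, 0.017)
        assert (p.D_SDE, p.R_SDE) == (0.3, 0.01)


class TestEnergies:
    def test_energy_is_integral_of_force(self, p):
        # numeric integral of the element force matches the closed form
        for fn_e, fn_f, lo, hi in [
            (pee_energy, f_pee, p.L_PEE_0 * p.l_CE_opt, 1.3 * p.l_CE_opt),
            (see_energy, f_see, p.l_SEE_0, 1.06 * p.l_SEE_0),
        ]:
            grid = np.linspace(lo, hi, 4001)
            numeric = np.trapezoid([fn_f(x, p) for x in grid], grid)
            assert fn_e(hi, p) - fn_e(lo, p) == pytest.approx(numeric, rel=1e-5)
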