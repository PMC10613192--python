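"""Rig kinematics, bench protocols, forward dynamics and their physical
invariants (static oracle, energy dissipation, step-size convergence,
reflex-threshold monotonicity)."""

import math

import numpy as np
import pytest

from ehtm import (
    ActivationParams,
    ControllerConfig,
    Schedule,
    ViaPointRouting,
    default_muscle,
    macro_element_kinematics,
    make_rig,
    simulate_mtu_bench,
    simulate_reflex_drop,
    simulate_rig,
)
from ehtm.ep import simulate_with_stim
from ehtm.fixtures import FixtureSpec
from ehtm.muscle import f_isom, f_pee, f_see
from ehtm.rigs import energy_series


class TestMacroElementKinematics:
    def test_straight_two_point_path(self):
        poly = ViaPointRouting((("ground", (0.0, 0.0)), ("ground", (0.0, 70.0))))
        L, rate = macro_element_kinematics(poly, 0.3, 0.1)
        assert L == pytest.approx(70.0)
        assert rate == pytest.approx(0.0, abs=1e-9)

    def test_bent_path_sums_segments(self):
        poly = ViaPointRouting((
            ("ground", (0.0, 30.0)),
            ("ground", (0.0, 0.0)),
            ("ground", (40.0, 0.0)),
        ))
        L, _ = macro_element_kinematics(poly, 0.0)
        assert L == pytest.approx(70.0)

    def test_rotation_about_via_point_preserves_lengths(self):
        # distal segment attached to the body frame, via-point at the
        # joint origin: rotation changes no segment length
        poly = ViaPointRouting((
            ("ground", (0.0, 30.0)),
            ("ground", (0.0, 0.0)),
            ("body", (40.0, 0.0)),
        ))
        lengths = [macro_element_kinematics(poly, phi)[0]
                   for phi in np.linspace(-1.0, 1.0, 11)]
        assert np.ptp(lengths) < 1e-9
        assert lengths[0] == pytest.approx(70.0)

    def test_coincident_points_rejected(self):
        poly = ViaPointRouting((("ground", (0.0, 0.0)), ("ground", (0.0, 0.0))))
        with pytest.raises(ValueError):
            poly.length(0.0)

    def test_lengthening_rate_matches_finite_difference(self):
        poly = ViaPointRouting((("ground", (0.0, 80.0)), ("body", (28.0, 0.0))))
        phi, w = 1.1, 0.02
        _, rate = macro_element_kinematics(poly, phi, w)
        h = 1e-6
        dl = (poly.length(phi + h) - poly.length(phi - h)) / (2 * h)
        assert rate == pytest.approx(dl * w, rel=1e-6)


class TestBench:
    def test_passive_isometric_settles_to_elastic_equilibrium(self):
        p, act = default_muscle("generic")
        res = simulate_mtu_bench("isometric", p, act, 400.0, 0.1)
        f_end = res.muscles["mtu"]["force"][-1]
        l_end = res.muscles["mtu"]["l_CE"][-1]
        # force balances the tendon at the settled fibre length
        assert f_end == pytest.approx(f_see(res.meta["l_mtu"] - l_end, p), rel=1e-6)
        assert abs(res.muscles["mtu"]["v_CE"][-1]) < 1e-9

    def test_isometric_ramp_force_rises_monotonically(self):
        p, act = default_muscle("generic")
        res = simulate_mtu_bench("ramp", p, act, 1100.0, 0.1)
        f = res.muscles["mtu"]["force"]
        onset = np.searchsorted(res.t, 320.0)
        # allow solver-level ripple only
        drops = np.diff(f[onset:])
        assert drops.min() > -1e-6 * p.F_max
        assert f[-1] > 10 * f[onset]

    def test_quick_release_velocity_matches_hill_closed_form(self):
        p, act = default_muscle("generic")
        res = simulate_mtu_bench("quick_release", p, act, 800.0, 0.05,
                                 release_time=600.0)
        k = np.searchsorted(res.t, 600.0)
        l_ce = res.muscles["mtu"]["l_CE"][k]
        q = res.muscles["mtu"]["q"][k]
        v = res.muscles["mtu"]["v_CE"][k]
        # independent concentric closed form at zero tendon force
        F = f_isom(l_ce, p)
        L = 1.0 if l_ce < p.l_CE_opt else F
        A = p.A_rel_0 * L * (1 + 3 * q) / 4.0
        B = p.B_rel_0 * (3 + 4 * q) / 7.0
        u = (q * F + A) / (A - f_pee(l_ce, p) / p.F_max)
        v_expected = B * p.l_CE_opt * (1.0 - u)
        assert v == pytest.approx(v_expected, rel=5e-3)
        assert v < 0

    def test_static_oracle_over_random_states(self):
        # steady state by time integration vs independent bisection of
        # the static force balance, 100 seeded random (l_MTU, q) pairs
        p, _ = default_muscle("generic")
        act = ActivationParams(mode="direct")
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(100):
            q = float(rng.uniform(0.02, 1.0))
            l_mtu = p.l_CE_opt * float(rng.uniform(0.85, 1.15)) + p.l_SEE_0
            res = simulate_mtu_bench(
                "isometric", p, act, 300.0, 0.1, l_mtu=l_mtu,
                stim_schedule=Schedule.constant(q),
            )
            l_sim = res.muscles["mtu"]["l_CE"][-1]
            # brute-force bisection, independent of the integrator
            g = lambda l: (q * f_isom(l, p) * p.F_max + f_pee(l, p)
                           - f_see(max(l_mtu - l, 0.0), p))
            lo, hi = 0.3 * p.l_CE_opt, l_mtu - 1e-9
            for _ in range(200):
                mid = 0.5 * (lo + hi)
                if g(mid) > 0:
                    hi = mid
                else:
                    lo = mid
            l_ref = 0.5 * (lo + hi)
            worst = max(worst, abs(l_sim - l_ref) / l_ref)
        assert worst < 1e-3  # < 0.1 %

    def test_unknown_protocol_rejected(self):
        p, act = default_muscle("generic")
        with pytest.raises(ValueError):
            simulate_mtu_bench("twitch", p, act, 100.0, 0.1)


class TestJointDynamics:
    def test_no_muscles_no_gravity_stays_put(self):
        import dataclasses

        rig = dataclasses.replace(make_rig("pendulum"), g=0.0, rest_angle=0.4)
        res = simulate_rig(rig, 300.0, 0.25)
        assert np.ptp(res.coord) == 0.0
        assert np.all(res.coord_vel == 0.0)

    def test_pendulum_period_matches_closed_form(self):
        rig = make_rig("pendulum")  # 0.15 rad initial offset
        res = simulate_rig(rig, 4000.0, 0.25)
        sign = np.signbit(res.coord_vel)
        crossings = res.t[1:][np.diff(sign.astype(int)) != 0]
        period = 2.0 * np.mean(np.diff(crossings))
        expected = 2 * math.pi * math.sqrt(
            rig.inertia / (rig.mass * rig.g * rig.com_dist))
        assert period == pytest.approx(expected, rel=0.01)

    def test_symmetric_costimulation_equilibrium(self):
        # equal stimulation of the mirror pair: phi = 0 is an equilibrium
        # and a small offset decays back toward it
        rig = make_rig("symmetric_pair")
        res = simulate_with_stim(rig, [0.3, 0.3], 800.0, 0.25)
        assert np.max(np.abs(res.coord)) == 0.0
        rig_off = make_rig(FixtureSpec("symmetric_pair",
                                       overrides={"rest_angle": 0.05}))
        res = simulate_with_stim(rig_off, [0.3, 0.3], 2000.0, 0.25)
        assert abs(res.coord[-1]) < 0.01
        assert abs(res.coord_vel[-1]) < 1e-5

    def test_passive_energy_dissipates(self):
        rig = make_rig("elbow_pair")
        res = simulate_rig(rig, 1500.0, 0.25)
        E = energy_series(rig, res)
        # non-increasing up to the tiny work of the basic activity q0
        assert np.all(np.diff(E) < 5e-6)
        assert E[-1] < E[0]

    def test_terminal_angle_converges_when_halving_dt(self):
        rig = make_rig("elbow_pair")
        finals = []
        for dt in (0.25, 0.125):
            res = simulate_with_stim(rig, [0.15, 0.05], 900.0, dt)
            finals.append(res.coord[-1])
        assert abs(finals[1] - finals[0]) / abs(finals[1]) < 5e-3

    def test_output_force_stays_physical(self):
        rig = make_rig("elbow_pair")
        res = simulate_with_stim(rig, [0.4, 0.3], 800.0, 0.25)
        for name, m in zip(("flexor", "extensor"), rig.muscles):
            force = res.muscles[name]["force"]
            assert force.min() > -1e-6 * m.params.F_max
            cap = (m.params.F_ecc * m.params.F_max
                   + f_pee(res.muscles[name]["l_CE"].max(), m.params)
                   + 0.5 * m.params.F_max)
            assert force.max() < cap


@pytest.fixture(scope="module")
def sweep():
    rig = make_rig("drop_mass")
    omegas = [0.01, 0.03, 0.05, 0.07, 0.09]
    return omegas, simulate_reflex_drop(rig, omegas, 400.0, 0.1)


class TestReflexDrop:
    def test_peak_displacement_monotone_in_threshold(self, sweep):
        omegas, runs = sweep
        peaks = [r.meta["peak_displacement"] for r in runs]
        assert all(a <= b + 1e-12 for a, b in zip(peaks, peaks[1:]))
        # earliest firing -> smallest drop of the sweep
        assert peaks[0] == min(peaks)

    def test_never_exceeded_threshold_reproduces_passive_run(self, sweep):
        rig = make_rig("drop_mass")
        huge = simulate_reflex_drop(rig, [10.0], 400.0, 0.1)[0]
        assert np.all(huge.muscles["holder1"]["stim"] == 0.0)
        # fully passive comparison: no-controller muscles
        passive_rig = rig.with_controllers(
            [ControllerConfig(mode="none")] * 2)
        passive = simulate_rig(passive_rig, 400.0, 0.1)
        np.testing.assert_allclose(huge.coord, passive.coord, atol=1e-12)

    def test_reflex_fires_and_activation_stays_smooth(self, sweep):
        _, runs = sweep
        run = runs[1]  # omega = 3 %
        stim = run.muscles["holder1"]["stim"]
        q = run.muscles["holder1"]["q"]
        assert set(np.unique(stim)) <= {0.0, 1.0}
        assert stim.max() == 1.0
        # low-pass contract: bounded, continuous activation
        assert q.min() >= 0.005 - 1e-12 and q.max() <= 1.0
        max_rate = 0.0113 * 20.0  # steepest Hatze q-slope x gamma rate
        assert np.max(np.abs(np.diff(q))) < max_rate * run.dt * 5

    def test_mode_validation(self):
        rig = make_rig("elbow_pair")
        with pytest.raises(ValueError):
            simulate_reflex_drop(rig, [0.05], 100.0, 0.1)
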