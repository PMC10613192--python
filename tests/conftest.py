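"""Shared fixtures.

The two optimised equilibrium points on the fixture elbow rig are
expensive (a couple of minutes of derivative-free search), so they are
computed once per session and shared by the EP, motion and acceptance
tests.
"""

from __future__ import annotations

import dataclasses
import math

import pytest

from ehtm import ActivationParams, EPProblem, default_muscle, find_ep, make_rig


@pytest.fixture(scope="session")
def generic_muscle():
    return default_muscle("generic")


@pytest.fixture(scope="session")
def elbow_rig():
    return make_rig("elbow_pair")


@pytest.fixture(scope="session")
def elbow_rig_zajac():
    """Elbow rig with the linear first-order activation mode, used by the
    pure length-feedback servo tests."""
    rig = make_rig("elbow_pair")
    zaj = ActivationParams(mode="zajac")
    return dataclasses.replace(
        rig, muscles=tuple(dataclasses.replace(m, act=zaj) for m in rig.muscles)
    )


@pytest.fixture(scope="session")
def elbow_eps(elbow_rig):
    """Two minimum-effort equilibrium points ~40 degrees apart."""
    ep1 = find_ep(EPProblem(phi_target=math.radians(65.0), seed=1), elbow_rig)
    ep2 = find_ep(EPProblem(phi_target=math.radians(100.0), seed=1), elbow_rig)
    return ep1, ep2
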