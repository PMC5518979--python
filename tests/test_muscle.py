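"""Muscle path geometry, moment arms, and Hill-type force generation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitstress.model import BipedModel, HingeJoint, Segment, model_poses
from gaitstress.muscle import (
    MuscleTendonUnit,
    activation_update,
    force_length,
    force_velocity,
    moment_arm,
    mtu_force,
    mtu_length,
    passive_force_length,
)


def _rig(waypoints, q0=0.0, ranges=(-1.5, 1.5)):
    base = Segment("base", 1.0, (0, 0), 0.0, 0.2, (0, 0), (0.2, 0))
    lever = Segment("lever", 1.0, (0, -0.5), 1.0 / 12, 1.0, (0, 0), (0, -1))
    model = BipedModel(
        segments=[base, lever],
        joints=[HingeJoint("j", "base", "lever", (0, 0), (0, 0), *ranges,
                           q0=q0)],
        muscles=[MuscleTendonUnit("m", waypoints)],
        anchored_root=True,
    )
    return model


class TestPathGeometry:
    def test_two_point_length(self):
        m = _rig([("base", (0.0, 0.0)), ("lever", (0.0, -0.3))])
        L = mtu_length(m.muscles[0], model_poses(m))
        assert L == pytest.approx(0.3)

    def test_collinear_midpoint_changes_nothing(self):
        m3 = _rig([("base", (0.0, 0.0)), ("lever", (0.0, -0.15)),
                   ("lever", (0.0, -0.3))])
        L = mtu_length(m3.muscles[0], model_poses(m3))
        assert L == pytest.approx(0.3)

    def test_rigid_translation_invariance(self):
        m = _rig([("base", (-0.1, 0.05)), ("lever", (-0.07, -0.4))])
        L0 = mtu_length(m.muscles[0], model_poses(m))
        m.root_start = (5.0, -2.0, 0.0)
        L1 = mtu_length(m.muscles[0], model_poses(m))
        assert L1 == pytest.approx(L0, abs=1e-12)


class TestMomentArm:
    @pytest.mark.parametrize("r", [0.05, 0.1, 0.2])
    def test_tangent_line_gives_radius(self, r):
        # a straight path passing at perpendicular distance r from the joint
        m = _rig([("base", (-1.0, r)), ("lever", (1.0, r))])
        arm = moment_arm(m.muscles[0], "j", m)
        assert abs(arm) == pytest.approx(r, abs=1e-4)

    def test_path_through_joint_centre_zero(self):
        m = _rig([("base", (-0.5, 0.0)), ("lever", (0.0, 0.0)),
                  ("lever", (0.0, -0.5))])
        # straight to the hinge point then down the lever: d L / d q = 0 at q=0
        arm = moment_arm(m.muscles[0], "j", m)
        assert arm == pytest.approx(0.0, abs=1e-6)

    def test_reversed_path_same_magnitude(self):
        wp = [("base", (-0.8, 0.1)), ("lever", (0.4, 0.1))]
        a1 = moment_arm(_rig(wp).muscles[0], "j", _rig(wp))
        m2 = _rig(list(reversed(wp)))
        a2 = moment_arm(m2.muscles[0], "j", m2)
        assert abs(a1) == pytest.approx(abs(a2), rel=1e-9)

    def test_non_crossing_muscle_rejected(self):
        m = _rig([("base", (0, 0)), ("base", (1, 0))])
        m.muscles[0].path = [("base", np.zeros(2)), ("base", np.ones(2))]
        with pytest.raises(ValueError):
            moment_arm(m.muscles[0], "j", m)

    def test_matches_virtual_work_torque(self):
        """Generalized muscle torque in the engine equals tension x moment arm."""
        from gaitstress.dynamics import Engine, SimConfig

        m = _rig([("base", (-0.3, 0.2)), ("lever", (-0.25, -0.6))])
        m.muscles[0].f_max = 100.0
        m.muscles[0].fibre_length = 0.2
        m.muscles[0].tendon_slack_length = 0.0
        m.gravity = 0.0
        e = Engine(m, SimConfig(duration=1.0))
        e.activation[:] = 1.0
        fk = e._fk(e.q, e.qd)
        F, T, Qj = e._forces(fk, e.qd)
        jp = e._jacobian(fk)
        q_muscle = np.einsum("lda,la->d", jp, F) + e.jw.T @ T
        tension = e._tension[0]
        arm = moment_arm(m.muscles[0], "j", m)
        assert tension > 0
        assert q_muscle[0] == pytest.approx(tension * arm, rel=1e-6)


class TestForceGeneration:
    def _muscle(self):
        return MuscleTendonUnit(
            "m", [("a", (0, 0)), ("b", (0, 0))],
            f_max=1000.0, fibre_length=0.1, tendon_slack_length=0.2,
        )

    def test_curve_normalisation(self):
        assert force_length(1.0) == 1.0
        assert force_velocity(0.0) == 1.0

    @given(st.floats(-2, 3), st.floats(-3, 3))
    @settings(max_examples=50, deadline=None)
    def test_curves_bounded_nonnegative(self, ln, vn):
        assert 0.0 <= force_length(ln) <= 1.0
        assert 0.0 <= force_velocity(vn) <= 1.5
        assert 0.0 <= passive_force_length(ln) <= 1.5

    def test_slack_muscle_zero_force(self):
        mu = self._muscle()
        assert mtu_force(mu, 0.0, 0.19, 0.0) == 0.0
        assert mtu_force(mu, 1.0, 0.15, 0.0) == 0.0

    def test_isometric_optimal_gives_fmax(self):
        mu = self._muscle()
        f = mtu_force(mu, 1.0, mu.tendon_slack_length + mu.fibre_length, 0.0)
        assert f == pytest.approx(mu.f_max, rel=1e-9)

    def test_max_shortening_velocity_zero_active_force(self):
        mu = self._muscle()
        L = mu.tendon_slack_length + mu.fibre_length
        v = -10.0 * mu.fibre_length  # full shortening speed
        assert mtu_force(mu, 1.0, L, v) == pytest.approx(0.0, abs=1e-9)

    def test_force_never_negative(self):
        mu = self._muscle()
        for L in np.linspace(0.0, 0.5, 11):
            for v in (-2.0, 0.0, 2.0):
                assert mtu_force(mu, 0.5, L, v) >= 0.0

    def test_nonfinite_state_rejected(self):
        with pytest.raises(ValueError):
            mtu_force(self._muscle(), 1.0, np.nan, 0.0)

    def test_fmax_from_mass_and_specific_tension(self):
        mu = MuscleTendonUnit("m", [("a", (0, 0)), ("b", (0, 0))],
                              mass=1.06, fibre_length=0.1)
        # PCSA = 1.06 / (1060 * 0.1) = 0.01 m^2 -> 3 kN at 0.3 MPa
        assert mu.max_isometric_force() == pytest.approx(3000.0)

    def test_engine_vectorised_force_matches_scalar(self, toy_model):
        from gaitstress.dynamics import Engine
        from gaitstress.fixtures import toy_sim_config

        e = Engine(toy_model, toy_sim_config(1.0))
        rng = np.random.default_rng(3)
        act = rng.uniform(0, 1, len(e.muscle_names))
        lengths = e.mu_slack + e.mu_lopt * rng.uniform(0.6, 1.4, len(act))
        vels = rng.normal(0, 0.1, len(act))
        vec = e._mtu_forces(act, lengths, vels)
        for i, mu in enumerate(toy_model.muscles):
            assert vec[i] == pytest.approx(
                mtu_force(mu, act[i], lengths[i], vels[i]), rel=1e-9, abs=1e-9
            )


class TestActivationDynamics:
    def test_fixed_point(self):
        assert activation_update(0.4, 0.4, 0.01, 0.05) == pytest.approx(0.4)

    def test_step_response_one_time_constant(self):
        a = activation_update(1.0, 0.0, 0.05, 0.05)
        assert a == pytest.approx(1.0 - np.exp(-1.0), rel=1e-9)

    def test_vanishing_dt(self):
        assert activation_update(1.0, 0.2, 1e-9, 0.05) == pytest.approx(0.2, abs=1e-6)

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(1e-4, 0.1))
    @settings(max_examples=50, deadline=None)
    def test_stays_in_bounds(self, e, a, dt):
        assert 0.0 <= activation_update(e, a, dt) <= 1.0
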