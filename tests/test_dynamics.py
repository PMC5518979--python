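"""Forward dynamics engine: closed-form oracles, conservation, load recovery."""

import copy

import numpy as np
import pytest

from gaitstress.dynamics import (
    Engine,
    SimConfig,
    contact_force,
    split_segment_for_load,
)
from gaitstress.fixtures import (
    make_cantilever,
    make_double_pendulum,
    make_drop_test,
    make_pendulum,
    make_toy_biped,
    toy_sim_config,
)
from gaitstress.geometry import regular_polygon
from gaitstress.model import BoneMonitor, ContactSphere, CrossSectionSpec


def _monitored_cantilever(orientation, length=1.0, mass=2.0, cut=0.5):
    m = make_cantilever(length=length, mass=mass, orientation=orientation)
    m, weld = split_segment_for_load(m, "bar", cut)
    m.sections["bone"] = CrossSectionSpec("bone", regular_polygon(64, 0.02), 1.0)
    m.monitors.append(BoneMonitor("bar", weld, ["bone"]))
    return m


class TestContactLaw:
    def test_sphere_above_ground_no_force(self):
        s = ContactSphere("c", "x", (0, 0), 0.1, 1e6, 1e3)
        f = contact_force(s, np.array([0.0, 0.2]), np.zeros(2))
        assert np.allclose(f, 0.0)

    def test_spring_law_normal_force(self):
        s = ContactSphere("c", "x", (0, 0), 0.1, 1e6, 0.0)
        f = contact_force(s, np.array([0.0, 0.1 - 1e-3]), np.zeros(2))
        assert f[1] == pytest.approx(1000.0)

    def test_fast_separation_clamped_to_zero(self):
        # penetrated but retracting so fast the spring-damper sum is tensile
        s = ContactSphere("c", "x", (0, 0), 0.1, 1e4, 1e4)
        f = contact_force(s, np.array([0.0, 0.1 - 1e-3]), np.array([0.0, 1.0]))
        assert f[1] == 0.0

    def test_friction_opposes_slip_and_is_bounded(self):
        s = ContactSphere("c", "x", (0, 0), 0.1, 1e6, 0.0, friction_mu=0.8)
        f = contact_force(s, np.array([0.0, 0.1 - 1e-3]), np.array([0.5, 0.0]))
        assert f[0] < 0.0
        assert abs(f[0]) <= 0.8 * f[1] + 1e-9

    def test_drop_test_settles_to_static_penetration(self):
        m = make_drop_test(mass=1.0, radius=0.1)
        k = m.contacts[0].stiffness
        e = Engine(m, SimConfig(timestep=1e-4, duration=2.0))
        for _ in range(20000):
            e.step()
        delta = m.contacts[0].radius - e.q[1]
        assert delta == pytest.approx(1.0 * 9.81 / k, rel=1e-3)
        assert abs(e.qd[1]) < 1e-6


class TestClosedFormDynamics:
    def test_free_fall_velocity(self):
        m = make_drop_test(drop_height=50.0)
        e = Engine(m, SimConfig(timestep=1e-4, duration=1.0))
        for _ in range(10000):
            e.step()
        assert e.qd[1] == pytest.approx(-9.81 * 1.0, rel=1e-6)

    def test_pendulum_period_and_energy_drift(self):
        m = make_pendulum(length=1.0, mass=1.0)
        e = Engine(m, SimConfig(timestep=1e-4, duration=10.0))
        e.q[0] = 0.05  # small amplitude
        e0 = e.total_energy()
        angles = np.empty(100000)
        for i in range(100000):
            e.step()
            angles[i] = e.q[0]
        # rod pendulum: period 2 pi sqrt(I_pivot / (m g d)), d = L/2
        t_expected = 2 * np.pi * np.sqrt((1.0 / 3.0) / (9.81 * 0.5))
        sgn = np.sign(angles)
        up = np.nonzero((sgn[1:] > 0) & (sgn[:-1] <= 0))[0]
        period = np.mean(np.diff(up)) * 1e-4
        assert period == pytest.approx(t_expected, rel=0.01)
        # undamped passive system: energy drift below 0.1% over 10 s
        assert abs(e.total_energy() - e0) / abs(e0) < 1e-3

    def test_double_pendulum_energy_conserved(self):
        m = make_double_pendulum()
        e = Engine(m, SimConfig(timestep=1e-4, duration=10.0))
        e.q[0], e.q[1] = 0.4, -0.2
        e0 = e.total_energy()
        for _ in range(100000):
            e.step()
        assert abs(e.total_energy() - e0) / abs(e0) < 1e-3


class TestSegmentSplitting:
    def test_halves_recombine_exactly(self, toy_model):
        m = copy.deepcopy(toy_model)
        seg = m.segment("trunk")
        m2, _ = split_segment_for_load(m, "trunk", 0.3)
        p, d = m2.segment("trunk_prox"), m2.segment("trunk_dist")
        assert p.mass + d.mass == pytest.approx(seg.mass, rel=1e-12)
        com = (p.mass * p.com_local + d.mass * d.com_local) / seg.mass
        assert np.allclose(com, seg.com_local, atol=1e-12)
        i_tot = (
            p.inertia_zz + p.mass * np.sum((p.com_local - seg.com_local) ** 2)
            + d.inertia_zz + d.mass * np.sum((d.com_local - seg.com_local) ** 2)
        )
        assert i_tot == pytest.approx(seg.inertia_zz, rel=1e-9)

    def test_uniform_bar_midpoint_split(self):
        m = make_cantilever(length=1.0, mass=2.0)
        m2, _ = split_segment_for_load(m, "bar", 0.5)
        for half in ("bar_prox", "bar_dist"):
            s = m2.segment(half)
            assert s.mass == pytest.approx(1.0)
            assert s.inertia_zz == pytest.approx((2.0 / 2) * 1.0**2 / 48.0)

    def test_unknown_segment_rejected(self, toy_model):
        with pytest.raises(KeyError):
            split_segment_for_load(toy_model, "wing")

    def test_split_and_unsplit_trajectories_match(self):
        m1 = make_double_pendulum()
        m2, _ = split_segment_for_load(make_double_pendulum(), "bar2", 0.5)
        coms = []
        for m in (m1, m2):
            e = Engine(m, SimConfig(timestep=1e-4, duration=2.0))
            e.q[0], e.q[1] = 0.5, 0.3
            for _ in range(20000):
                e.step()
            coms.append(e.com()[0])
        assert np.abs(coms[0] - coms[1]).max() < 1e-6


class TestInternalLoads:
    def test_horizontal_cantilever_statics(self):
        # distal half: mass 1 kg, COM 0.25 m beyond the mid-shaft cut
        m = _monitored_cantilever("horizontal")
        e = Engine(m, SimConfig())
        load = e.measure_internal_load("bar")
        assert load.axial_force == pytest.approx(0.0, abs=1e-9)
        assert abs(load.shear_force) == pytest.approx(1.0 * 9.81, rel=1e-6)
        assert abs(load.bending_moment_x) == pytest.approx(
            1.0 * 9.81 * 0.25, rel=1e-6
        )
        assert load.bending_moment_y == 0.0

    def test_vertical_column_pure_axial(self):
        m = _monitored_cantilever("vertical")
        e = Engine(m, SimConfig())
        load = e.measure_internal_load("bar")
        assert load.axial_force == pytest.approx(1.0 * 9.81, rel=1e-6)
        assert load.shear_force == pytest.approx(0.0, abs=1e-9)
        assert load.bending_moment_x == pytest.approx(0.0, abs=1e-9)

    def test_zero_gravity_at_rest_zero_loads(self):
        m = _monitored_cantilever("horizontal")
        m.gravity = 0.0
        load = Engine(m, SimConfig()).measure_internal_load("bar")
        assert load.axial_force == 0.0
        assert load.shear_force == 0.0
        assert load.bending_moment_x == 0.0

    def test_off_centre_cut_moment_arm(self):
        # cut at 25%: distal 75% of a 2 kg bar, COM 0.375 m past the cut
        m = _monitored_cantilever("horizontal", cut=0.25)
        e = Engine(m, SimConfig())
        load = e.measure_internal_load("bar")
        assert abs(load.shear_force) == pytest.approx(1.5 * 9.81, rel=1e-6)
        assert abs(load.bending_moment_x) == pytest.approx(
            1.5 * 9.81 * 0.375, rel=1e-6
        )


class TestEngineContracts:
    def test_hinge_anchor_coincidence(self, toy_model):
        e = Engine(toy_model, toy_sim_config(1.0))
        rng = np.random.default_rng(0)
        for _ in range(5):
            q = e.q.copy()
            q[e.n_base:] += rng.uniform(-0.3, 0.3, e.n_joints)
            fk = e._fk(q, np.zeros_like(q))
            for l in range(1, e.n_links):
                child_anchor = fk["o"][l] + fk["R"][l] @ e.anchor_child[l]
                assert np.abs(child_anchor - fk["W"][l]).max() < 1e-8

    def test_momentum_matches_external_impulse(self):
        # ballistic phase: momentum change equals gravity impulse exactly
        m = make_drop_test(drop_height=10.0)
        e = Engine(m, SimConfig(timestep=1e-4, duration=1.0))
        p0 = 1.0 * e.qd[1]
        for _ in range(5000):
            e.step()
        p1 = 1.0 * e.qd[1]
        assert p1 - p0 == pytest.approx(-1.0 * 9.81 * 0.5, rel=1e-9)

    def test_contact_normal_force_never_tensile(self):
        m = make_drop_test(mass=1.0, radius=0.1, drop_height=0.3)
        e = Engine(m, SimConfig(timestep=1e-4, duration=1.5, record_every=5))
        traj = e.run()
        assert traj.contact_force[:, :, 1].min() >= 0.0

    def test_same_config_reproducible_bitwise(self, toy_model):
        cfg = toy_sim_config(0.5)
        t1 = Engine(toy_model, cfg).run(None, np.inf)
        t2 = Engine(toy_model, cfg).run(None, np.inf)
        assert np.array_equal(t1.q, t2.q)
        assert np.array_equal(t1.stress_max_filtered, t2.stress_max_filtered)

    def test_zero_stress_limit_fails_immediately(self, toy_model):
        traj = Engine(toy_model, toy_sim_config(1.0)).run(None, stress_limit=0.0)
        assert traj.termination.cause == "stress_fail"
        assert traj.termination.time == 0.0

    def test_infinite_limit_matches_unconstrained(self, toy_model):
        cfg = toy_sim_config(0.5)
        t_inf = Engine(toy_model, cfg).run(None, stress_limit=np.inf)
        t_big = Engine(toy_model, cfg).run(None, stress_limit=1e30)
        assert np.array_equal(t_inf.q, t_big.q)
        assert np.array_equal(t_inf.com, t_big.com)

    def test_standing_model_stays_put_initially(self, toy_model):
        traj = Engine(toy_model, toy_sim_config(0.5)).run(None, np.inf)
        assert abs(traj.com[0, 0] - traj.com[len(traj.time) // 4, 0]) < 0.05

    def test_fall_detection_reports_fell(self, toy_model):
        traj = Engine(toy_model, toy_sim_config(4.0)).run(None, np.inf)
        assert traj.termination.cause in ("fell", "completed")
        if traj.termination.cause == "fell":
            assert traj.hip_height[-1] < 0.55 * traj.hip_height[0]
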