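"""Model construction rules: mass regression, inertia, allocation, tuning."""

import numpy as np
import pytest

from gaitstress.model import (
    BipedModel,
    HingeJoint,
    Segment,
    assign_limb_mass_fractions,
    assign_muscle_masses,
    compute_planar_inertia,
    estimate_mass_from_hull,
    model_poses,
    tune_fibre_tendon_lengths,
    validate_model,
)
from gaitstress.muscle import MuscleTendonUnit

TREX_TOTAL_MASS = 7206.7  # kg, volumetric estimate for the full-scale model


class TestHullMassRegression:
    def test_power_law_evaluation(self):
        assert estimate_mass_from_hull(0.5, {"a": 1000.0, "b": 1.0}) == 500.0

    def test_zero_volume_zero_mass(self):
        assert estimate_mass_from_hull(0.0, {"a": 500.0, "b": 0.9}) == 0.0

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            estimate_mass_from_hull(-1.0, {"a": 1.0, "b": 1.0})

    def test_segment_volumes_recover_full_scale_total(self):
        # per-segment hull volumes scaled so that a calibrated power law
        # reproduces the full-scale total body mass
        regression = {"a": 1000.0, "b": 0.95}
        fractions = np.array([0.65, 0.08, 0.08, 0.04, 0.04, 0.015, 0.015,
                              0.01, 0.01, 0.015, 0.015, 0.01, 0.01, 0.005,
                              0.005])
        assert fractions.sum() == pytest.approx(1.0)
        target_masses = fractions * TREX_TOTAL_MASS
        volumes = (target_masses / regression["a"]) ** (1.0 / regression["b"])
        total = sum(estimate_mass_from_hull(v, regression) for v in volumes)
        assert total == pytest.approx(TREX_TOTAL_MASS, rel=1e-9)


class TestPlanarInertia:
    def test_rectangle_closed_form(self):
        w, h, m = 0.4, 1.2, 7.0
        hull = np.array([[0, 0], [w, 0], [w, h], [0, h]])
        izz, com = compute_planar_inertia(hull, m)
        assert izz == pytest.approx(m * (w**2 + h**2) / 12.0, rel=1e-9)
        assert np.allclose(com, [w / 2, h / 2])

    def test_unit_square_12kg(self):
        hull = np.array([[0, 0], [1, 0], [1, 1], [0, 1]])
        izz, _ = compute_planar_inertia(hull, 12.0)
        assert izz == pytest.approx(2.0, rel=1e-9)

    def test_linear_in_mass(self):
        hull = np.array([[0, 0], [2, 0], [1.1, 1.7]])
        i1, _ = compute_planar_inertia(hull, 3.0)
        i2, _ = compute_planar_inertia(hull, 6.0)
        assert i2 == pytest.approx(2 * i1, rel=1e-12)

    def test_degenerate_polygon_rejected(self):
        flat = np.array([[0, 0], [1, 0], [2, 0]])
        with pytest.raises(ValueError):
            compute_planar_inertia(flat, 1.0)


class TestMassAllocation:
    def test_fractions_conserve_total(self):
        masses = assign_limb_mass_fractions(
            100.0, {"thigh_l": 0.1, "shank_l": 0.05, "thigh_r": 0.1,
                    "shank_r": 0.05}
        )
        assert masses["thigh_l"] == 10.0
        assert masses["shank_r"] == 5.0
        assert masses["trunk"] == 70.0
        assert sum(masses.values()) == pytest.approx(100.0, rel=1e-12)

    def test_full_scale_total_conserved(self):
        f = 0.105
        masses = assign_limb_mass_fractions(TREX_TOTAL_MASS, {"thigh_l": f})
        assert masses["thigh_l"] == pytest.approx(TREX_TOTAL_MASS * f)
        assert sum(masses.values()) == pytest.approx(TREX_TOTAL_MASS, rel=1e-9)

    def test_zero_fractions_put_all_in_trunk(self):
        masses = assign_limb_mass_fractions(50.0, {})
        assert masses == {"trunk": 50.0}

    def test_oversubscribed_fractions_rejected(self):
        with pytest.raises(ValueError):
            assign_limb_mass_fractions(10.0, {"a": 0.7, "b": 0.6})

    def test_muscle_masses_half_body_mass(self):
        muscles = [
            MuscleTendonUnit(f"{a}_{loc}", [("a", (0, 0)), ("b", (0, 0))],
                             f_max=1.0, action=a, location=loc)
            for a in ("extensor", "flexor")
            for loc in ("proximal", "intermediate", "distal")
        ]
        out = assign_muscle_masses(TREX_TOTAL_MASS, 0.5, muscles)
        assert sum(out.values()) == pytest.approx(3603.35, rel=1e-9)

    def test_two_equal_groups(self):
        muscles = [
            MuscleTendonUnit("e", [("a", (0, 0)), ("b", (0, 0))], f_max=1.0,
                             action="extensor", location="proximal"),
            MuscleTendonUnit("f", [("a", (0, 0)), ("b", (0, 0))], f_max=1.0,
                             action="flexor", location="proximal"),
        ]
        out = assign_muscle_masses(
            100.0, 0.5, muscles,
            {("extensor", "proximal"): 0.5, ("flexor", "proximal"): 0.5},
        )
        assert out == {"e": 25.0, "f": 25.0}

    def test_zero_muscle_fraction(self):
        muscles = [
            MuscleTendonUnit("e", [("a", (0, 0)), ("b", (0, 0))], f_max=1.0,
                             action="extensor", location="proximal"),
        ]
        out = assign_muscle_masses(
            100.0, 0.0, muscles, {("extensor", "proximal"): 1.0}
        )
        assert out == {"e": 0.0}

    def test_empty_group_with_mass_rejected(self):
        with pytest.raises(ValueError):
            assign_muscle_masses(100.0, 0.5, [], {("extensor", "proximal"): 1.0})


def _lever_model(arm=0.1, length=1.0, q0=0.0):
    """Anchored base plus one hinged lever with a single-joint muscle."""
    base = Segment("base", 1.0, (0, 0), 0.0, 0.2, (0, 0), (0.2, 0))
    lever = Segment("lever", 1.0, (0, -length / 2), length**2 / 12.0, length,
                    (0, 0), (0, -length))
    muscle = MuscleTendonUnit(
        "m", [("base", (-arm, 0.0)), ("lever", (-arm, -length / 2))]
    )
    return BipedModel(
        name="lever",
        segments=[base, lever],
        joints=[HingeJoint("j", "base", "lever", (0, 0), (0, 0), -1.5, 1.5,
                           q0=q0)],
        muscles=[muscle],
        anchored_root=True,
    )


class TestFibreTendonTuning:
    def test_fibre_is_fraction_of_length_range(self):
        m = _lever_model()
        mu = m.muscles[0]
        lengths = []
        for q in np.linspace(-1.5, 1.5, 64):
            poses = model_poses(m, {"j": q})
            from gaitstress.muscle import path_length

            lengths.append(path_length(mu, poses))
        dl = max(lengths) - min(lengths)
        fibre, slack = tune_fibre_tendon_lengths(mu, m, fibre_fraction=1.0)
        assert fibre == pytest.approx(dl, rel=1e-12)

    def test_zero_fraction_all_tendon(self):
        m = _lever_model()
        fibre, slack = tune_fibre_tendon_lengths(m.muscles[0], m,
                                                 fibre_fraction=0.0)
        from gaitstress.muscle import path_length

        mid = model_poses(m, {"j": 0.0})  # mid-range of the symmetric range
        assert fibre == 0.0
        assert slack == pytest.approx(path_length(m.muscles[0], mid), rel=1e-9)

    def test_scales_with_model_geometry(self):
        f1, _ = tune_fibre_tendon_lengths(_lever_model().muscles[0],
                                          _lever_model())
        big = _lever_model(arm=0.2, length=2.0)
        f2, _ = tune_fibre_tendon_lengths(big.muscles[0], big)
        assert f2 == pytest.approx(2 * f1, rel=1e-9)

    def test_translation_invariant(self):
        m1 = _lever_model()
        f1, s1 = tune_fibre_tendon_lengths(m1.muscles[0], m1)
        m2 = _lever_model()
        m2.root_start = (3.7, -1.2, 0.0)
        f2, s2 = tune_fibre_tendon_lengths(m2.muscles[0], m2)
        assert f1 == pytest.approx(f2, abs=1e-12)
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_muscle_crossing_no_joint_rejected(self):
        m = _lever_model()
        m.muscles[0].path = [("base", np.zeros(2)), ("base", np.ones(2))]
        with pytest.raises(ValueError):
            tune_fibre_tendon_lengths(m.muscles[0], m)


class TestValidateModel:
    def test_fixture_models_valid(self, toy_model, trex_model):
        assert validate_model(toy_model) == []
        assert validate_model(trex_model) == []

    def test_joint_cycle_detected(self):
        m = _lever_model()
        m.joints.append(
            HingeJoint("back", "lever", "base", (0, -1), (0, 0), -1, 1)
        )
        assert any("cycle" in v or "root" in v for v in validate_model(m))

    def test_nonpositive_mass_detected(self):
        m = _lever_model()
        m.segments[1].mass = -2.0
        assert any("mass" in v and "lever" in v for v in validate_model(m))

    def test_validation_does_not_mutate(self):
        m = _lever_model()
        before = m.segments[1].mass
        validate_model(m)
        assert m.segments[1].mass == before
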