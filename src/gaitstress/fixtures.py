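"""Deterministic model generators: validation rigs and biped fixtures.

Everything here is built from documented constants — repeated calls produce
bit-identical models.  The rigs (pendulums, drop test, cantilever) have
closed-form behaviour used to validate the dynamics engine.  The toy biped is
a small, optimisable planar biped; the tyrannosaur-scale fixture applies the
full construction pipeline (limb mass fractions, 50% muscle mass, hollow bone
sections with the published cortical fractions) to simplified box/ellipse
geometry at 7206.7 kg total mass.  The fixture geometry is a labelled
geometric stand-in, not a skeletal reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass
from dataclasses import field as dataclass_field

import numpy as np

from .dynamics import SimConfig, add_bone_monitor
from .model import (
    DEFAULT_LIMB_MASS_FRACTIONS,
    DEFAULT_MUSCLE_ALLOCATION,
    BipedModel,
    ContactSphere,
    CrossSectionSpec,
    FixedJoint,
    HingeJoint,
    Segment,
    assign_limb_mass_fractions,
    assign_muscle_masses,
    compute_planar_inertia,
    tune_fibre_tendon_lengths,
    validate_model,
)
from .geometry import regular_polygon
from .muscle import MuscleTendonUnit

#: Cortical wall thickness as a fraction of mean external radius, per bone.
CORTICAL_FRACTIONS = {
    "femur": 0.38,
    "tibia": 0.35,
    "fibula": 0.96,
    "metatarsus": 0.60,
}


def _rect(w: float, h: float, center=(0.0, 0.0)) -> np.ndarray:
    cx, cy = center
    return np.array(
        [
            [cx - w / 2, cy - h / 2],
            [cx + w / 2, cy - h / 2],
            [cx + w / 2, cy + h / 2],
            [cx - w / 2, cy + h / 2],
        ]
    )


# ---------------------------------------------------------------------------
# physics validation rigs
# ---------------------------------------------------------------------------


def make_pendulum(length: float = 1.0, mass: float = 1.0) -> BipedModel:
    """Uniform rod hinged to an anchored base, hanging along -y at rest."""
    ground = Segment(
        name="ground", mass=1.0, com_local=(0, 0), inertia_zz=0.0, length=0.1,
        proximal_anchor=(0, 0), distal_anchor=(0.1, 0),
    )
    bar = Segment(
        name="bar", mass=mass, com_local=(0, -length / 2),
        inertia_zz=mass * length**2 / 12.0, length=length,
        proximal_anchor=(0, 0), distal_anchor=(0, -length),
    )
    return BipedModel(
        name="pendulum",
        segments=[ground, bar],
        joints=[
            HingeJoint("pivot", "ground", "bar", (0, 0), (0, 0), -20.0, 20.0)
        ],
        anchored_root=True,
    )


def make_double_pendulum(length: float = 1.0, mass: float = 1.0) -> BipedModel:
    m = make_pendulum(length, mass)
    m.name = "double_pendulum"
    bar2 = Segment(
        name="bar2", mass=mass, com_local=(0, -length / 2),
        inertia_zz=mass * length**2 / 12.0, length=length,
        proximal_anchor=(0, 0), distal_anchor=(0, -length),
    )
    m.segments.append(bar2)
    m.joints.append(
        HingeJoint("elbow", "bar", "bar2", (0, -length), (0, 0), -20.0, 20.0)
    )
    return m


def make_drop_test(
    mass: float = 1.0,
    radius: float = 0.1,
    stiffness: float | None = None,
    damping: float | None = None,
    drop_height: float = 0.0,
) -> BipedModel:
    """Free ball with one contact sphere; settles to penetration m g / k."""
    if stiffness is None:
        stiffness = mass * 9.81 / 1e-3  # 1 mm static penetration
    if damping is None:
        damping = float(np.sqrt(stiffness * mass))  # near critical
    ball = Segment(
        name="ball", mass=mass, com_local=(0, 0),
        inertia_zz=0.5 * mass * radius**2, length=radius,
        proximal_anchor=(0, 0), distal_anchor=(0, -radius),
    )
    return BipedModel(
        name="drop_test",
        segments=[ball],
        contacts=[
            ContactSphere("ball_contact", "ball", (0, 0), radius,
                          stiffness, damping, friction_mu=1.0)
        ],
        root_start=(0.0, radius + drop_height, 0.0),
    )


def make_cantilever(
    length: float = 1.0, mass: float = 2.0, orientation: str = "horizontal"
) -> BipedModel:
    """Uniform bar welded to an anchored base (statics oracle for cut loads)."""
    if orientation == "horizontal":
        distal, com = (length, 0.0), (length / 2, 0.0)
    elif orientation == "vertical":
        distal, com = (0.0, -length), (0.0, -length / 2)
    else:
        raise ValueError("orientation must be horizontal or vertical")
    ground = Segment(
        name="ground", mass=1.0, com_local=(0, 0), inertia_zz=0.0, length=0.1,
        proximal_anchor=(0, 0), distal_anchor=(0.1, 0),
    )
    bar = Segment(
        name="bar", mass=mass, com_local=com,
        inertia_zz=mass * length**2 / 12.0, length=length,
        proximal_anchor=(0, 0), distal_anchor=distal,
    )
    return BipedModel(
        name=f"cantilever_{orientation}",
        segments=[ground, bar],
        fixed_joints=[FixedJoint("weld", "ground", "bar", (0, 0), (0, 0))],
        anchored_root=True,
    )


# ---------------------------------------------------------------------------
# bipeds
# ---------------------------------------------------------------------------


def _leg_segments(side: str, L: float, masses: dict[str, float], width: float):
    """thigh/shank/metatarsal/pes chain for one side; frames hang along -y."""
    lt, ls, lm = 0.4 * L, 0.4 * L, 0.2 * L
    lp = 0.18 * L
    segs = []
    for base, seg_len in (("thigh", lt), ("shank", ls), ("metatarsal", lm)):
        name = f"{base}_{side}"
        hull = _rect(width, seg_len, (0, -seg_len / 2))
        inertia, com = compute_planar_inertia(hull, masses[base])
        segs.append(
            Segment(
                name=name, mass=masses[base], com_local=com, inertia_zz=inertia,
                length=seg_len, proximal_anchor=(0, 0), distal_anchor=(0, -seg_len),
                hull=hull,
            )
        )
    hull = _rect(lp + width, width, (lp / 2 - width / 4, 0))
    inertia, com = compute_planar_inertia(hull, masses["pes"])
    segs.append(
        Segment(
            name=f"pes_{side}", mass=masses["pes"], com_local=com,
            inertia_zz=inertia, length=lp,
            proximal_anchor=(0, 0), distal_anchor=(lp, 0), hull=hull,
        )
    )
    return segs, (lt, ls, lm, lp)


def _leg_joints(side: str, lt: float, ls: float, lm: float):
    return [
        HingeJoint(f"hip_{side}", "trunk", f"thigh_{side}",
                   (0, 0), (0, 0), -0.9, 1.1, q0=0.0),
        HingeJoint(f"knee_{side}", f"thigh_{side}", f"shank_{side}",
                   (0, -lt), (0, 0), -2.0, 0.05, q0=0.0),
        HingeJoint(f"ankle_{side}", f"shank_{side}", f"metatarsal_{side}",
                   (0, -ls), (0, 0), -0.9, 0.9, q0=0.0),
        HingeJoint(f"mtp_{side}", f"metatarsal_{side}", f"pes_{side}",
                   (0, -lm), (0, 0), -0.7, 0.7, q0=0.0),
    ]


def _leg_muscles(side: str, L: float, lt: float, ls: float, lm: float,
                 fmax_scale: float | None, muscles_per_limb: int):
    """Six (or eight) muscles: flexor/extensor at hip, knee, ankle (and mtp).

    ``fmax_scale`` of None leaves f_max to be derived from allocated muscle
    mass; otherwise f_max is the given multiple of the scale (body weight).
    """
    arm = 0.09 * L  # way-point offset controlling moment arms
    defs = [
        # name, action, location, fmax multiple, waypoints
        ("hip_ext", "extensor", "proximal", 2.5,
         [("trunk", (-arm, 0.1 * L)), (f"thigh_{side}", (-arm * 0.7, -0.55 * lt))]),
        ("hip_flex", "flexor", "proximal", 1.5,
         [("trunk", (arm, 0.1 * L)), (f"thigh_{side}", (arm * 0.7, -0.55 * lt))]),
        ("knee_ext", "extensor", "intermediate", 2.0,
         [(f"thigh_{side}", (arm * 0.6, -0.5 * lt)),
          (f"thigh_{side}", (arm * 0.6, -lt)),
          (f"shank_{side}", (arm * 0.5, -0.3 * ls))]),
        ("knee_flex", "flexor", "intermediate", 1.0,
         [(f"thigh_{side}", (-arm * 0.6, -0.5 * lt)),
          (f"shank_{side}", (-arm * 0.5, -0.35 * ls))]),
        ("ankle_ext", "extensor", "distal", 1.2,
         [(f"shank_{side}", (-arm * 0.7, -0.45 * ls)),
          (f"metatarsal_{side}", (-arm * 0.8, -0.45 * lm))]),
        ("ankle_flex", "flexor", "distal", 0.5,
         [(f"shank_{side}", (arm * 0.7, -0.45 * ls)),
          (f"metatarsal_{side}", (arm * 0.6, -0.4 * lm))]),
        ("mtp_ext", "extensor", "distal", 0.4,
         [(f"metatarsal_{side}", (-arm * 0.5, -0.5 * lm)),
          (f"pes_{side}", (0.05 * L, -arm * 0.3))]),
        ("mtp_flex", "flexor", "distal", 0.3,
         [(f"metatarsal_{side}", (arm * 0.5, -0.5 * lm)),
          (f"pes_{side}", (0.08 * L, arm * 0.3))]),
    ]
    if muscles_per_limb < 6 or muscles_per_limb % 2:
        raise ValueError("need an even number >= 6 of muscles per limb")
    defs = defs[: muscles_per_limb]
    out = []
    for base, action, location, mult, path in defs:
        out.append(
            MuscleTendonUnit(
                name=f"{base}_{side}",
                path=[(s, np.asarray(p, dtype=float)) for s, p in path],
                f_max=None if fmax_scale is None else mult * fmax_scale,
                action=action,
                location=location,
            )
        )
    return out


def make_biped(
    leg_length: float = 1.0,
    total_mass: float = 80.0,
    muscles_per_limb: int = 6,
    name: str = "toy_biped",
    section_radii: dict[str, float] | None = None,
    fmax_from_mass: bool = False,
    muscle_mass_fraction: float = 0.5,
    limb_fractions: dict[str, float] | None = None,
    static_penetration: float = 0.01,
) -> BipedModel:
    """General planar biped builder used by the toy and tyrannosaur fixtures."""
    L = leg_length
    limb_fractions = dict(DEFAULT_LIMB_MASS_FRACTIONS if limb_fractions is None
                          else limb_fractions)
    per_side = {f"{k}_{s}": v for s in ("l", "r") for k, v in limb_fractions.items()}
    masses = assign_limb_mass_fractions(total_mass, per_side)
    width = 0.08 * L

    segments = []
    trunk_hull = _rect(0.7 * L, 0.62 * L, (0.0, 0.26 * L))
    t_inertia, t_com = compute_planar_inertia(trunk_hull, masses["trunk"])
    segments.append(
        Segment(
            name="trunk", mass=masses["trunk"], com_local=t_com,
            inertia_zz=t_inertia, length=0.7 * L,
            proximal_anchor=(0, 0), distal_anchor=(0, 0.55 * L), hull=trunk_hull,
        )
    )
    joints, muscles, contacts = [], [], []
    g = 9.81
    n_spheres = 4
    k_contact = total_mass * g / (n_spheres * static_penetration)
    c_contact = 0.7 * float(np.sqrt(k_contact * total_mass / n_spheres))
    rc = 0.04 * L
    for side in ("l", "r"):
        side_masses = {k: masses[f"{k}_{side}"] for k in limb_fractions}
        segs, (lt, ls, lm, lp) = _leg_segments(side, L, side_masses, width)
        segments.extend(segs)
        joints.extend(_leg_joints(side, lt, ls, lm))
        muscles.extend(
            _leg_muscles(side, L, lt, ls, lm,
                         None if fmax_from_mass else 2.0 * total_mass * g / 2.0,
                         muscles_per_limb)
        )
        for tag, x in (("heel", 0.02 * L), ("toe", 0.15 * L)):
            contacts.append(
                ContactSphere(f"{tag}_{side}", f"pes_{side}", (x, 0.0), rc,
                              k_contact, c_contact, friction_mu=1.0)
            )

    radii = section_radii or {
        "femur": 0.022 * L * (total_mass / 80.0) ** 0.5,
        "tibia": 0.019 * L * (total_mass / 80.0) ** 0.5,
        "fibula": 0.007 * L * (total_mass / 80.0) ** 0.5,
        "metatarsus": 0.016 * L * (total_mass / 80.0) ** 0.5,
    }
    sections = {
        bone: CrossSectionSpec(bone, regular_polygon(64, r),
                               CORTICAL_FRACTIONS[bone])
        for bone, r in radii.items()
    }

    lt, ls, lm = 0.4 * L, 0.4 * L, 0.2 * L
    hip_y = lt + ls + lm + rc - 0.5 * static_penetration
    model = BipedModel(
        name=name,
        segments=segments,
        joints=joints,
        muscles=muscles,
        contacts=contacts,
        sections=sections,
        root_start=(0.0, hip_y, 0.0),
        hip_joints=["hip_l", "hip_r"],
    )
    # muscle masses allocated over the action x location table
    assign_muscle_masses(total_mass, muscle_mass_fraction, model.muscles,
                         DEFAULT_MUSCLE_ALLOCATION)
    from .model import model_poses
    from .muscle import path_length

    standing = model_poses(model)
    for mu in model.muscles:
        tune_fibre_tendon_lengths(mu, model, fibre_fraction=0.5)
        # fixture choice: slacken tendons so the build pose is force-free and
        # fibres sit at optimal length when standing
        mu.tendon_slack_length = max(
            0.0, path_length(mu, standing) - mu.fibre_length
        )

    # mid-shaft stress monitors on the three major hind limb segments
    for side in ("l", "r"):
        model = add_bone_monitor(model, f"thigh_{side}", ["femur"],
                                 name=f"femur_{side}")
        model = add_bone_monitor(model, f"shank_{side}", ["tibia", "fibula"],
                                 name=f"shank_{side}")
        model = add_bone_monitor(model, f"metatarsal_{side}", ["metatarsus"],
                                 name=f"metatarsus_{side}")
    violations = validate_model(model)
    if violations:
        raise ValueError(f"fixture model invalid: {violations}")
    return model


def make_toy_biped(
    leg_length: float = 1.0, total_mass: float = 80.0, muscles_per_limb: int = 6
) -> BipedModel:
    """Small optimisable biped with explicit (stability-friendly) muscle forces."""
    if muscles_per_limb < 6:
        raise ValueError("muscles_per_limb must be >= 6")
    return make_biped(leg_length, total_mass, muscles_per_limb, name="toy_biped")


def make_trex_like() -> BipedModel:
    """Planar tyrannosaur-scale biped: 7206.7 kg, 50% muscle mass.

    Geometric stand-in with simplified hulls; forelimbs are merged into the
    trunk segment.  Muscle forces derive from the allocated muscle masses via
    specific tension; bone sections use the published cortical fractions.
    """
    return make_biped(
        leg_length=3.2,
        total_mass=7206.7,
        muscles_per_limb=6,
        name="trex_like",
        section_radii={
            "femur": 0.085,
            "tibia": 0.065,
            "fibula": 0.025,
            "metatarsus": 0.050,
        },
        fmax_from_mass=True,
        muscle_mass_fraction=0.5,
        static_penetration=0.02,
    )


def toy_sim_config(duration: float = 5.0, seed: int = 0) -> SimConfig:
    """Integration settings sized for the toy biped's contact stiffness."""
    return SimConfig(timestep=2.5e-4, duration=duration, record_every=8,
                     rng_seed=seed)


@dataclass(frozen=True)
class FixtureSpec:
    """Names a fixture and its scale parameters.

    Builders are fully deterministic, so equal specs always produce
    byte-identical models; the seed field exists for provenance in run
    manifests (no fixture draws random numbers).
    """

    name: str
    params: dict = dataclass_field(default_factory=dict)
    rng_seed: int = 0


def build_fixture(spec: FixtureSpec) -> BipedModel:
    return make_fixture(spec.name, **spec.params)


def write_synthetic_published_xml(path) -> None:
    """Write a SYNTHETIC replica of the published simulator model's structure.

    This is not the published supplementary file: it is a stand-in generated
    from the printed model description (15 body segments — trunk, paired
    thigh/shank/metatarsal/pes, paired arm/forearm/manus — linked by hinge
    joints, 58 hindlimb muscles, foot contact spheres) for exercising the
    importer without the original data.
    """
    segs = ["Trunk"]
    for side in ("Left", "Right"):
        segs += [f"{side}{b}" for b in
                 ("Thigh", "Shank", "Metatarsal", "Pes", "Arm", "Forearm",
                  "Manus")]
    lines = ['<?xml version="1.0" encoding="UTF-8"?>', "<SIMULATION>",
             '  <GLOBAL GravityVector="0 0 -9.81"/>']
    for i, s in enumerate(segs):
        lines.append(
            f'  <BODY ID="{s}" Mass="{100 + i}" '
            f'Position="0 0 {1.0 + 0.1 * i}"/>'
        )
    chains = [("Trunk", "LeftThigh"), ("LeftThigh", "LeftShank"),
              ("LeftShank", "LeftMetatarsal"), ("LeftMetatarsal", "LeftPes"),
              ("Trunk", "RightThigh"), ("RightThigh", "RightShank"),
              ("RightShank", "RightMetatarsal"), ("RightMetatarsal", "RightPes"),
              ("Trunk", "LeftArm"), ("LeftArm", "LeftForearm"),
              ("LeftForearm", "LeftManus"), ("Trunk", "RightArm"),
              ("RightArm", "RightForearm"), ("RightForearm", "RightManus")]
    for i, (a, b) in enumerate(chains):
        lines.append(
            f'  <JOINT ID="joint{i}" Type="Hinge" Body1ID="{a}" Body2ID="{b}"/>'
        )
    for side in ("Left", "Right"):
        for i in range(29):
            lines.append(
                f'  <MUSCLE ID="{side}HindlimbMuscle{i}" Type="MinettiAlexander" '
                f'OriginBodyID="{side}Thigh" InsertionBodyID="{side}Shank"/>'
            )
    for side in ("Left", "Right"):
        for i in range(2):
            lines.append(
                f'  <GEOM ID="{side}Toe{i}" Type="Sphere" BodyID="{side}Pes" '
                f'Radius="0.05"/>'
            )
    lines += ["</SIMULATION>", ""]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


FIXTURES = {
    "pendulum": make_pendulum,
    "double-pendulum": make_double_pendulum,
    "drop": make_drop_test,
    "cantilever": make_cantilever,
    "toy-biped": make_toy_biped,
    "trex-like": make_trex_like,
}


def make_fixture(name: str, **kwargs) -> BipedModel:
    try:
        return FIXTURES[name](**kwargs)
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; options: {sorted(FIXTURES)}")
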