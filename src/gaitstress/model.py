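"""Articulated planar biped model: types, construction rules and validation.

A model is a tree of rigid segments linked by hinge joints (pure
flexion-extension), actuated by polyline muscle-tendon units, and supported by
spring-damper contact spheres.  Conventions: x forward, y up, angles
counterclockwise-positive, each segment frame anchored at its proximal joint,
SI units throughout.  A segment's world orientation equals its parent's
orientation plus the connecting joint angle; joint angle zero therefore means
parallel frames.

Mass properties follow the volumetric workflow used for fossil
reconstructions: total body mass from a power-law regression on convex-hull
volume, limb segment masses as fractions of total mass (running-bird based
defaults, overridable), planar inertia computed from segment hull outlines and
scaled to the assigned masses, and muscle masses allocated by a
flexor/extensor x proximal/intermediate/distal table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import is_simple, polygon_planar_inertia
from .muscle import MuscleTendonUnit


@dataclass(eq=False)
class Segment:
    name: str
    mass: float
    com_local: np.ndarray
    inertia_zz: float
    length: float
    proximal_anchor: np.ndarray
    distal_anchor: np.ndarray
    hull: np.ndarray | None = None
    section_ref: str | None = None

    def __post_init__(self) -> None:
        self.com_local = np.asarray(self.com_local, dtype=float)
        self.proximal_anchor = np.asarray(self.proximal_anchor, dtype=float)
        self.distal_anchor = np.asarray(self.distal_anchor, dtype=float)
        if self.hull is not None:
            self.hull = np.asarray(self.hull, dtype=float)


@dataclass(eq=False)
class HingeJoint:
    name: str
    parent: str
    child: str
    anchor_parent: np.ndarray
    anchor_child: np.ndarray
    range_min: float
    range_max: float
    q0: float = 0.0

    def __post_init__(self) -> None:
        self.anchor_parent = np.asarray(self.anchor_parent, dtype=float)
        self.anchor_child = np.asarray(self.anchor_child, dtype=float)


@dataclass(eq=False)
class FixedJoint:
    """Rigid weld between two segments (used for mid-shaft load recovery)."""

    name: str
    parent: str
    child: str
    anchor_parent: np.ndarray
    anchor_child: np.ndarray
    relative_angle: float = 0.0
    is_load_cut: bool = False
    cut_axis: np.ndarray | None = None  # proximal->distal bone axis, parent seg frame

    def __post_init__(self) -> None:
        self.anchor_parent = np.asarray(self.anchor_parent, dtype=float)
        self.anchor_child = np.asarray(self.anchor_child, dtype=float)
        if self.cut_axis is not None:
            self.cut_axis = np.asarray(self.cut_axis, dtype=float)


@dataclass(eq=False)
class ContactSphere:
    name: str
    segment: str
    center_local: np.ndarray
    radius: float
    stiffness: float
    damping: float = 0.0
    friction_mu: float = 1.0

    def __post_init__(self) -> None:
        self.center_local = np.asarray(self.center_local, dtype=float)


@dataclass(eq=False)
class CrossSectionSpec:
    """External outline of a bone cross-section plus cortical wall fraction."""

    name: str
    outer_outline: np.ndarray
    cortical_fraction: float

    def __post_init__(self) -> None:
        self.outer_outline = np.asarray(self.outer_outline, dtype=float)


@dataclass
class BoneMonitor:
    """Names a mid-shaft load cut and the section(s) carrying the load.

    With several sections (tibia + fibula sharing the shank load) the cut load
    is divided in proportion to each section's stiffness: axial force by area,
    bending moment by second moment of area Ix.
    """

    name: str
    fixed_joint: str
    sections: list[str] = field(default_factory=list)


@dataclass(eq=False)
class BipedModel:
    name: str = "model"
    segments: list[Segment] = field(default_factory=list)
    joints: list[HingeJoint] = field(default_factory=list)
    fixed_joints: list[FixedJoint] = field(default_factory=list)
    muscles: list[MuscleTendonUnit] = field(default_factory=list)
    contacts: list[ContactSphere] = field(default_factory=list)
    sections: dict[str, CrossSectionSpec] = field(default_factory=dict)
    monitors: list[BoneMonitor] = field(default_factory=list)
    gravity: float = 9.81
    anchored_root: bool = False
    root_start: tuple[float, float, float] = (0.0, 0.0, 0.0)
    hip_joints: list[str] = field(default_factory=list)
    joint_limit_stiffness: float | None = None
    joint_limit_damping: float | None = None

    # -- lookups ------------------------------------------------------------
    def segment(self, name: str) -> Segment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(f"unknown segment {name!r}")

    def segment_names(self) -> list[str]:
        return [s.name for s in self.segments]

    def all_joints(self) -> list[HingeJoint | FixedJoint]:
        return list(self.joints) + list(self.fixed_joints)

    def parent_joint_of(self, segment: str):
        for j in self.all_joints():
            if j.child == segment:
                return j
        return None

    def root_segment(self) -> str:
        children = {j.child for j in self.all_joints()}
        roots = [s.name for s in self.segments if s.name not in children]
        if len(roots) != 1:
            raise ValueError(f"model must have exactly one root segment, got {roots}")
        return roots[0]

    def total_mass(self) -> float:
        return float(sum(s.mass for s in self.segments))


# ---------------------------------------------------------------------------
# construction rules
# ---------------------------------------------------------------------------

#: Stand-in limb mass fractions of total body mass (per side), patterned on
#: running-bird limb proportions; override per model as needed.
DEFAULT_LIMB_MASS_FRACTIONS: dict[str, float] = {
    "thigh": 0.105,
    "shank": 0.050,
    "metatarsal": 0.016,
    "pes": 0.009,
}

#: Stand-in muscle-mass allocation over action x joint location; fractions of
#: total muscle mass, summing to 1.  Extensor groups are the larger, as in
#: cursorial bipeds.
DEFAULT_MUSCLE_ALLOCATION: dict[tuple[str, str], float] = {
    ("extensor", "proximal"): 0.30,
    ("flexor", "proximal"): 0.20,
    ("extensor", "intermediate"): 0.18,
    ("flexor", "intermediate"): 0.10,
    ("extensor", "distal"): 0.15,
    ("flexor", "distal"): 0.07,
}


def estimate_mass_from_hull(hull_volume: float, regression: dict[str, float]) -> float:
    """Power-law body mass estimate m = a * V**b from convex-hull volume (m^3)."""
    a, b = regression["a"], regression["b"]
    if hull_volume < 0:
        raise ValueError("hull volume must be nonnegative")
    if a <= 0:
        raise ValueError("regression coefficient a must be positive")
    return a * hull_volume**b


def compute_planar_inertia(hull, mass: float) -> tuple[float, np.ndarray]:
    """Out-of-plane inertia and COM of a segment from its hull outline.

    The uniform-density polygon inertia is scaled so the hull carries exactly
    ``mass``; the COM is the polygon centroid.
    """
    return polygon_planar_inertia(hull, mass)


def assign_limb_mass_fractions(
    total_mass: float,
    fractions: dict[str, float],
    trunk: str = "trunk",
) -> dict[str, float]:
    """Per-segment masses from fractions of total mass; remainder to the trunk."""
    if any(f < 0 for f in fractions.values()):
        raise ValueError("mass fractions must be nonnegative")
    s = sum(fractions.values())
    if s > 1.0 + 1e-12:
        raise ValueError(f"limb mass fractions sum to {s} > 1")
    masses = {name: f * total_mass for name, f in fractions.items()}
    masses[trunk] = total_mass - sum(masses.values())
    return masses


def assign_muscle_masses(
    total_mass: float,
    muscle_fraction: float,
    muscles: list[MuscleTendonUnit],
    allocation: dict[tuple[str, str], float] | None = None,
) -> dict[str, float]:
    """Allocate total muscle mass over action x location groups.

    Each (action, location) group receives ``muscle_fraction * total_mass *
    allocation[group]``, shared equally among the group's muscles.  Muscles are
    grouped by their ``action``/``location`` tags.
    """
    if not 0.0 <= muscle_fraction <= 1.0:
        raise ValueError("muscle_fraction must be in [0, 1]")
    allocation = dict(DEFAULT_MUSCLE_ALLOCATION if allocation is None else allocation)
    tot = sum(allocation.values())
    if abs(tot - 1.0) > 1e-9:
        raise ValueError(f"allocation fractions sum to {tot}, expected 1")
    groups: dict[tuple[str, str], list[MuscleTendonUnit]] = {}
    for m in muscles:
        groups.setdefault((m.action, m.location), []).append(m)
    out: dict[str, float] = {}
    for key, frac in allocation.items():
        members = groups.get(key, [])
        if not members:
            if frac > 0:
                raise ValueError(f"no muscles in group {key} with fraction {frac}")
            continue
        each = muscle_fraction * total_mass * frac / len(members)
        for m in members:
            out[m.name] = each
    for m in muscles:
        if m.name in out:
            m.mass = out[m.name]
    return out


# ---------------------------------------------------------------------------
# model-level kinematics (build-pose sweeps; the dynamics engine has its own)
# ---------------------------------------------------------------------------


def model_poses(
    model: BipedModel,
    joint_angles: dict[str, float] | None = None,
    root_pose: tuple[float, float, float] | None = None,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """World pose (rotation matrix, origin) of every segment frame.

    Hinge angles default to each joint's ``q0``; fixed joints use their stored
    relative angle.
    """
    joint_angles = joint_angles or {}
    root = model.root_segment()
    if root_pose is None:
        root_pose = model.root_start
    x0, y0, th0 = root_pose
    c, s = np.cos(th0), np.sin(th0)
    poses: dict[str, tuple[np.ndarray, np.ndarray]] = {
        root: (np.array([[c, -s], [s, c]]), np.array([x0, y0]))
    }
    thetas = {root: th0}
    pending = [j for j in model.all_joints()]
    while pending:
        progressed = False
        rest = []
        for j in pending:
            if j.parent in poses:
                rp, tp = poses[j.parent]
                if isinstance(j, HingeJoint):
                    q = joint_angles.get(j.name, j.q0)
                else:
                    q = j.relative_angle
                th = thetas[j.parent] + q
                cc, ss = np.cos(th), np.sin(th)
                rc = np.array([[cc, -ss], [ss, cc]])
                w = tp + rp @ j.anchor_parent
                poses[j.child] = (rc, w - rc @ j.anchor_child)
                thetas[j.child] = th
                progressed = True
            else:
                rest.append(j)
        if not progressed:
            raise ValueError("joint graph is not a tree rooted at the root segment")
        pending = rest
    return poses


def joints_crossed_by(model: BipedModel, muscle: MuscleTendonUnit) -> list[HingeJoint]:
    """Hinge joints lying on the tree path between consecutive muscle way-points."""
    parent_of = {j.child: j for j in model.all_joints()}

    def path_to_root(seg: str) -> list[str]:
        out = [seg]
        while seg in parent_of:
            seg = parent_of[seg].parent
            out.append(seg)
        return out

    crossed: list[HingeJoint] = []
    for (seg_a, _), (seg_b, _) in zip(muscle.path[:-1], muscle.path[1:]):
        if seg_a == seg_b:
            continue
        pa, pb = path_to_root(seg_a), path_to_root(seg_b)
        common = next(s for s in pa if s in set(pb))
        chain = pa[: pa.index(common)] + pb[: pb.index(common)]
        for seg in chain:
            j = parent_of.get(seg)
            if isinstance(j, HingeJoint) and j not in crossed:
                crossed.append(j)
    return crossed


def tune_fibre_tendon_lengths(
    muscle: MuscleTendonUnit,
    model: BipedModel,
    fibre_fraction: float = 0.5,
    samples_per_joint: int = 64,
) -> tuple[float, float]:
    """Set fibre and tendon-slack lengths from the MTU length range over joint motion.

    All joints the muscle crosses are swept over their permitted ranges on a
    dense grid; the optimal fibre length is ``fibre_fraction`` times the MTU
    length change, and the tendon slack length is the mid-range MTU length
    minus the fibre length (floored at zero).  This tunes each actuator to
    operate over the effective part of its length-tension curve, making the
    model robust to moment-arm errors.
    """
    from .muscle import path_length

    crossed = joints_crossed_by(model, muscle)
    if not crossed:
        raise ValueError(f"muscle {muscle.name!r} crosses no hinge joint")
    if len(crossed) > 2:  # keep the sweep grid tractable for multi-joint paths
        samples_per_joint = min(samples_per_joint, 8)
    grids = [
        np.linspace(j.range_min, j.range_max, samples_per_joint) for j in crossed
    ]
    base = {j.name: j.q0 for j in model.joints}
    lengths = np.empty([samples_per_joint] * len(crossed))
    for idx in np.ndindex(lengths.shape):
        angles = dict(base)
        for j, grid, i in zip(crossed, grids, idx):
            angles[j.name] = grid[i]
        poses = model_poses(model, angles)
        lengths[idx] = path_length(muscle, poses)
    dl = float(lengths.max() - lengths.min())
    if dl <= 0:
        raise ValueError(f"muscle {muscle.name!r} length does not vary with posture")
    mid = dict(base)
    for j in crossed:
        mid[j.name] = 0.5 * (j.range_min + j.range_max)
    l_mid = path_length(muscle, model_poses(model, mid))
    fibre = fibre_fraction * dl
    slack = max(0.0, l_mid - fibre)
    muscle.fibre_length = fibre
    muscle.tendon_slack_length = slack
    return fibre, slack


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate_model(model: BipedModel) -> list[str]:
    """Collect invariant violations; an empty list means the model is valid."""
    v: list[str] = []
    names = model.segment_names()
    if len(set(names)) != len(names):
        v.append("duplicate segment names")
    for s in model.segments:
        if not np.isfinite(s.mass) or s.mass <= 0:
            v.append(f"segment {s.name!r}: mass must be positive")
        if s.inertia_zz < 0:
            v.append(f"segment {s.name!r}: inertia_zz must be nonnegative")
        if s.hull is not None:
            if not is_simple(s.hull):
                v.append(f"segment {s.name!r}: hull is self-intersecting")
            else:
                lo = s.hull.min(axis=0) - 1e-9
                hi = s.hull.max(axis=0) + 1e-9
                for tag, p in (
                    ("proximal", s.proximal_anchor),
                    ("distal", s.distal_anchor),
                ):
                    if np.any(p < lo) or np.any(p > hi):
                        v.append(
                            f"segment {s.name!r}: {tag} anchor outside hull bounds"
                        )
        if s.section_ref is not None and s.section_ref not in model.sections:
            v.append(f"segment {s.name!r}: unknown section {s.section_ref!r}")
    seen_children: set[str] = set()
    for j in model.all_joints():
        if j.parent == j.child:
            v.append(f"joint {j.name!r}: parent equals child")
        for end, seg in (("parent", j.parent), ("child", j.child)):
            if seg not in names:
                v.append(f"joint {j.name!r}: unknown {end} segment {seg!r}")
        if j.child in seen_children:
            v.append(f"segment {j.child!r} has multiple parent joints")
        seen_children.add(j.child)
        if isinstance(j, HingeJoint) and not j.range_min < j.range_max:
            v.append(f"joint {j.name!r}: range_min must be below range_max")
    # tree / cycle check
    try:
        root = model.root_segment()
        parent_of = {j.child: j.parent for j in model.all_joints()}
        for s in names:
            seen = {s}
            cur = s
            while cur in parent_of:
                cur = parent_of[cur]
                if cur in seen:
                    v.append(f"joint cycle through segment {cur!r}")
                    break
                seen.add(cur)
            else:
                if cur != root:
                    v.append(f"segment {s!r} not connected to root {root!r}")
    except ValueError as e:
        v.append(str(e))
    for c in model.contacts:
        if c.segment not in names:
            v.append(f"contact {c.name!r}: unknown segment {c.segment!r}")
        if c.radius <= 0:
            v.append(f"contact {c.name!r}: radius must be positive")
        if c.stiffness <= 0:
            v.append(f"contact {c.name!r}: stiffness must be positive")
        if c.damping < 0 or c.friction_mu < 0:
            v.append(f"contact {c.name!r}: damping and friction must be nonnegative")
    for m in model.muscles:
        if len(m.path) < 2:
            v.append(f"muscle {m.name!r}: path needs at least two way-points")
        if len({seg for seg, _ in m.path}) < 2:
            v.append(f"muscle {m.name!r}: path must span at least two segments")
        for seg, _ in m.path:
            if seg not in names:
                v.append(f"muscle {m.name!r}: unknown segment {seg!r}")
    for sec in model.sections.values():
        if not 0.0 < sec.cortical_fraction <= 1.0:
            v.append(f"section {sec.name!r}: cortical_fraction outside (0, 1]")
        if not is_simple(sec.outer_outline):
            v.append(f"section {sec.name!r}: outline self-intersecting")
    fj_names = {j.name for j in model.fixed_joints}
    for mon in model.monitors:
        if mon.fixed_joint not in fj_names:
            v.append(f"monitor {mon.name!r}: unknown fixed joint {mon.fixed_joint!r}")
        for sec in mon.sections:
            if sec not in model.sections:
                v.append(f"monitor {mon.name!r}: unknown section {sec!r}")
    return v
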