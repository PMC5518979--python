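"""Planar forward dynamics of the articulated model with bone-load recovery.

The engine works in generalized (reduced) coordinates over the joint tree:
three root coordinates (x, y, theta; omitted when the root is anchored to the
world) plus one angle per hinge.  Hinge anchor coincidence therefore holds
exactly at every step.  Fixed joints — including the mid-shaft welds created
by :func:`split_segment_for_load` — are compiled into composite links whose
mass properties recombine exactly to the originals, and the load transmitted
across each weld is recovered at run time by a recursive Newton-Euler pass
over the full dynamic solution (inertial, gravitational, muscle and contact
forces all included).

Equations of motion are assembled from COM Jacobians,

    M(q) qdd = Q_applied + J^T m (g - a_bias),

and integrated with a fixed-step semi-implicit (symplectic) Euler scheme,
which keeps the stiff spring-damper ground contacts stable and the energy of
passive systems bounded.

Ground contact: spheres act as one-sided stiff damped springs (never tensile,
so the foot lifts freely) with regularised Coulomb friction.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .geometry import cross2, perp, rot
from .model import BipedModel, BoneMonitor, FixedJoint, HingeJoint, Segment
from .muscle import VMAX_FIBRE_LENGTHS
from .stress import StreamingLowpass, hollow_section_from_outline


class EngineError(RuntimeError):
    pass


class SolverDivergence(EngineError):
    pass


@dataclass
class SimConfig:
    timestep: float = 1e-4
    duration: float = 10.0
    record_every: int = 10
    integrator: str = "semi_implicit_euler"
    ground_height: float = 0.0
    friction_vreg: float = 0.02
    fall_fraction: float = 0.5
    stress_cutoff_hz: float = 5.0
    stress_filter_order: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.timestep <= 0 or self.duration <= 0:
            raise ValueError("timestep and duration must be positive")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")


@dataclass(eq=False)
class BodyState:
    """Per-link world kinematics at one instant."""

    position: np.ndarray  # (L, 2) link frame origins
    orientation: np.ndarray  # (L,)
    com: np.ndarray  # (L, 2)
    linear_velocity: np.ndarray  # (L, 2) COM velocities
    angular_velocity: np.ndarray  # (L,)


@dataclass
class InternalLoad:
    """Load transmitted across a mid-shaft cut, in the bone frame.

    ``axial_force`` is tension-positive along the proximal->distal bone axis.
    In a planar model the dynamically generated bending moment is the
    out-of-plane (mediolateral-axis) component, mapped to the section x-axis;
    ``bending_moment_y`` is zero by construction.
    """

    axial_force: float
    shear_force: float
    bending_moment_x: float
    bending_moment_y: float = 0.0


@dataclass
class Termination:
    cause: str  # completed | fell | stress_fail | diverged
    time: float
    detail: str = ""


@dataclass(eq=False)
class Trajectory:
    time: np.ndarray
    q: np.ndarray
    qd: np.ndarray
    com: np.ndarray
    com_velocity: np.ndarray
    hip_height: np.ndarray
    contact_names: list[str]
    contact_force: np.ndarray  # (T, nC, 2)
    contact_flag: np.ndarray  # (T, nC) bool
    muscle_names: list[str]
    activation: np.ndarray
    muscle_force: np.ndarray
    monitor_names: list[str]
    load_axial: np.ndarray  # (T, nMon)
    load_shear: np.ndarray
    load_moment: np.ndarray
    stress_max_raw: np.ndarray
    stress_min_raw: np.ndarray
    stress_max_filtered: np.ndarray
    stress_min_filtered: np.ndarray
    termination: Termination
    sample_rate: float = 0.0

    @property
    def distance(self) -> float:
        return float(self.com[-1, 0] - self.com[0, 0])

    def to_frame(self):
        import pandas as pd

        cols = {
            "time_s": self.time,
            "com_x_m": self.com[:, 0],
            "com_y_m": self.com[:, 1],
            "com_vx_m_s": self.com_velocity[:, 0],
            "com_vy_m_s": self.com_velocity[:, 1],
            "hip_height_m": self.hip_height,
        }
        for i, n in enumerate(self.contact_names):
            cols[f"contact_{n}_fx_N"] = self.contact_force[:, i, 0]
            cols[f"contact_{n}_fy_N"] = self.contact_force[:, i, 1]
            cols[f"contact_{n}_flag"] = self.contact_flag[:, i].astype(int)
        for i, n in enumerate(self.muscle_names):
            cols[f"muscle_{n}_activation"] = self.activation[:, i]
            cols[f"muscle_{n}_force_N"] = self.muscle_force[:, i]
        for i, n in enumerate(self.monitor_names):
            cols[f"bone_{n}_axial_N"] = self.load_axial[:, i]
            cols[f"bone_{n}_shear_N"] = self.load_shear[:, i]
            cols[f"bone_{n}_moment_Nm"] = self.load_moment[:, i]
            cols[f"bone_{n}_stress_max_Pa"] = self.stress_max_raw[:, i]
            cols[f"bone_{n}_stress_min_Pa"] = self.stress_min_raw[:, i]
            cols[f"bone_{n}_stress_max_filt_Pa"] = self.stress_max_filtered[:, i]
            cols[f"bone_{n}_stress_min_filt_Pa"] = self.stress_min_filtered[:, i]
        return pd.DataFrame(cols)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# contact law
# ---------------------------------------------------------------------------


def contact_force_law(delta, delta_dot, vx, stiffness, damping, mu, vreg=0.02):
    """One-sided spring-damper normal force + regularised Coulomb friction.

    Returns (tangential, normal) force components on the body.  The normal
    force is clamped at zero so the contact never pulls the foot down, and is
    zero without penetration.
    """
    delta = np.asarray(delta, dtype=float)
    pen = delta > 0.0
    normal = np.where(pen, np.maximum(0.0, stiffness * delta + damping * delta_dot), 0.0)
    tangential = -mu * normal * np.tanh(np.asarray(vx) / vreg)
    return tangential, normal


def contact_force(sphere, center_world, center_velocity, ground_height=0.0, vreg=0.02):
    """World-frame force on one contact sphere (convenience scalar wrapper)."""
    low_y = center_world[1] - sphere.radius
    delta = ground_height - low_y
    ft, fn = contact_force_law(
        delta,
        -center_velocity[1],
        center_velocity[0],
        sphere.stiffness,
        sphere.damping,
        sphere.friction_mu,
        vreg,
    )
    return np.array([float(ft), float(fn)])


# ---------------------------------------------------------------------------
# segment splitting for mid-shaft load recovery
# ---------------------------------------------------------------------------


def split_segment_for_load(
    model: BipedModel, segment: str, cut_fraction: float = 0.5
) -> tuple[BipedModel, str]:
    """Replace a segment by proximal/distal halves joined by a weld at the cut.

    Mass is divided as if uniformly distributed along the bone axis through
    the segment COM; any excess of the true inertia over the equivalent
    slender-rod inertia is shared between the halves in proportion to mass, so
    the halves recombine exactly (parallel-axis theorem) to the original mass,
    COM and inertia.  Muscle way-points, contacts and child joints on the
    segment are re-homed to the correct half by their position along the axis.
    Returns the new model and the name of the load-cut weld joint.
    """
    if not 0.0 < cut_fraction < 1.0:
        raise ValueError("cut_fraction must be inside (0, 1)")
    m = copy.deepcopy(model)
    seg = m.segment(segment)  # KeyError if unknown
    axis = seg.distal_anchor - seg.proximal_anchor
    length = float(np.hypot(*axis))
    if length <= 0:
        raise ValueError(f"segment {segment!r} has coincident anchors")
    u = axis / length
    cut_point = seg.proximal_anchor + cut_fraction * axis

    # uniform-rod mass split along the axis, centred on the segment COM
    s_cut = float(np.clip((cut_point - seg.com_local) @ u, -0.5 * length, 0.5 * length))
    len_p = s_cut + 0.5 * length
    len_d = 0.5 * length - s_cut
    mp = seg.mass * len_p / length
    md = seg.mass * len_d / length
    com_p = seg.com_local + u * (-0.5 * length + 0.5 * len_p)
    com_d = seg.com_local + u * (0.5 * length - 0.5 * len_d)
    rod_i = seg.mass * length**2 / 12.0
    extra = seg.inertia_zz - rod_i
    ip = mp * len_p**2 / 12.0 + extra * mp / seg.mass
    id_ = md * len_d**2 / 12.0 + extra * md / seg.mass

    prox = Segment(
        name=f"{segment}_prox",
        mass=mp,
        com_local=com_p,
        inertia_zz=ip,
        length=len_p,
        proximal_anchor=seg.proximal_anchor,
        distal_anchor=cut_point,
        hull=seg.hull,
        section_ref=seg.section_ref,
    )
    dist = Segment(
        name=f"{segment}_dist",
        mass=md,
        com_local=com_d,
        inertia_zz=id_,
        length=len_d,
        proximal_anchor=cut_point,
        distal_anchor=seg.distal_anchor,
        hull=None,
        section_ref=seg.section_ref,
    )
    i = m.segments.index(seg)
    m.segments[i : i + 1] = [prox, dist]

    def side_of(point) -> str:
        return dist.name if (np.asarray(point) - cut_point) @ u > 0 else prox.name

    for j in m.all_joints():
        if j.child == segment:
            j.child = prox.name if (j.anchor_child - cut_point) @ u <= 0 else dist.name
        if j.parent == segment:
            j.parent = side_of(j.anchor_parent)
    for mu_ in m.muscles:
        mu_.path = [
            (side_of(p) if s == segment else s, p) for s, p in mu_.path
        ]
    for c in m.contacts:
        if c.segment == segment:
            c.segment = side_of(c.center_local)

    weld = FixedJoint(
        name=f"{segment}_cut",
        parent=prox.name,
        child=dist.name,
        anchor_parent=cut_point,
        anchor_child=cut_point,
        relative_angle=0.0,
        is_load_cut=True,
        cut_axis=u,
    )
    m.fixed_joints.append(weld)
    return m, weld.name


def add_bone_monitor(
    model: BipedModel,
    segment: str,
    sections: list[str],
    name: str | None = None,
    cut_fraction: float = 0.5,
) -> BipedModel:
    """Split a segment at its functional mid-point and register a stress monitor."""
    m, weld = split_segment_for_load(model, segment, cut_fraction)
    m.monitors.append(
        BoneMonitor(name=name or segment, fixed_joint=weld, sections=list(sections))
    )
    return m


# ---------------------------------------------------------------------------
# the engine
# ---------------------------------------------------------------------------


class Engine:
    """Compiled forward-dynamics engine for one model + configuration."""

    def __init__(self, model: BipedModel, config: SimConfig | None = None):
        self.model = model
        self.config = config or SimConfig()
        self._compile()
        self.reset()

    # -- compilation --------------------------------------------------------

    def _compile(self) -> None:
        m = self.model
        root = m.root_segment()
        seg_by_name = {s.name: s for s in m.segments}
        parent_joint = {j.child: j for j in m.all_joints()}

        # link partition over fixed joints; reference = root or hinge child
        ref_of: dict[str, str] = {}
        xform: dict[str, tuple[float, np.ndarray]] = {}  # seg -> (phi, t) in link

        def resolve(seg: str):
            if seg in ref_of:
                return
            j = parent_joint.get(seg)
            if j is None or isinstance(j, HingeJoint):
                ref_of[seg] = seg
                xform[seg] = (0.0, np.zeros(2))
                return
            resolve(j.parent)
            phi_p, t_p = xform[j.parent]
            phi = phi_p + j.relative_angle
            t = t_p + rot(phi_p) @ j.anchor_parent - rot(phi) @ j.anchor_child
            ref_of[seg] = ref_of[j.parent]
            xform[seg] = (phi, t)

        for s in m.segments:
            resolve(s.name)

        # topological link order starting at the root link
        hinges = [j for j in m.joints]
        link_refs = [root] + []
        placed = {root}
        remaining = [j for j in hinges]
        ordered_hinges: list[HingeJoint] = []
        while remaining:
            progressed = False
            rest = []
            for j in remaining:
                if ref_of[j.parent] in placed:
                    ordered_hinges.append(j)
                    link_refs.append(j.child)
                    placed.add(j.child)
                    progressed = True
                else:
                    rest.append(j)
            if not progressed:
                raise EngineError("hinge graph is not a tree rooted at the trunk")
            remaining = rest

        self.link_refs = link_refs
        L = len(link_refs)
        link_index = {ref: i for i, ref in enumerate(link_refs)}
        self.link_of_segment = {s: link_index[ref_of[s]] for s in seg_by_name}

        # composite link mass properties
        self.m_link = np.zeros(L)
        self.i_link = np.zeros(L)
        self.com_link = np.zeros((L, 2))
        members: list[list[str]] = [[] for _ in range(L)]
        for s in m.segments:
            members[self.link_of_segment[s.name]].append(s.name)
        self._seg_xform = xform
        for l in range(L):
            mass = 0.0
            com = np.zeros(2)
            for sname in members[l]:
                s = seg_by_name[sname]
                phi, t = xform[sname]
                c = t + rot(phi) @ s.com_local
                mass += s.mass
                com += s.mass * c
            com /= mass
            inertia = 0.0
            for sname in members[l]:
                s = seg_by_name[sname]
                phi, t = xform[sname]
                c = t + rot(phi) @ s.com_local
                inertia += s.inertia_zz + s.mass * float((c - com) @ (c - com))
            self.m_link[l] = mass
            self.i_link[l] = inertia
            self.com_link[l] = com
        self.members = members

        # hinge joint arrays (joint i connects parent link -> link i+1)
        NJ = len(ordered_hinges)
        self.n_links = L
        self.n_joints = NJ
        self.joint_names = [j.name for j in ordered_hinges]
        self.parent_link = np.zeros(L, dtype=int)
        self.anchor_parent = np.zeros((L, 2))
        self.anchor_child = np.zeros((L, 2))
        self.angle_offset = np.zeros(L)
        self.q0_joints = np.zeros(NJ)
        self.joint_lo = np.zeros(NJ)
        self.joint_hi = np.zeros(NJ)
        for i, j in enumerate(ordered_hinges):
            l = i + 1
            self.parent_link[l] = self.link_of_segment[j.parent]
            phi_p, t_p = xform[j.parent]
            self.anchor_parent[l] = t_p + rot(phi_p) @ j.anchor_parent
            self.anchor_child[l] = j.anchor_child
            self.angle_offset[l] = phi_p
            self.q0_joints[i] = j.q0
            self.joint_lo[i] = j.range_min
            self.joint_hi[i] = j.range_max

        # plain-python copies for the scalar kinematics loop
        self._ap_l = [tuple(map(float, v)) for v in self.anchor_parent]
        self._ac_l = [tuple(map(float, v)) for v in self.anchor_child]
        self._off_l = [float(v) for v in self.angle_offset]
        self._par_l = [int(v) for v in self.parent_link]

        # DOF layout
        self.anchored = m.anchored_root
        self.n_base = 0 if self.anchored else 3
        self.n_dof = self.n_base + NJ
        if self.n_dof == 0:
            self.n_dof = 0  # fully static rig is allowed

        # subtree masks: mask[l, d] True if dof d moves link l
        D = self.n_dof
        self.mask = np.zeros((L, D), dtype=bool)
        if not self.anchored:
            self.mask[:, 0:3] = True
        children: list[list[int]] = [[] for _ in range(L)]
        for l in range(1, L):
            children[self.parent_link[l]].append(l)
        self.children = children
        for l in range(1, L):
            d = self.n_base + l - 1
            stack = [l]
            while stack:
                k = stack.pop()
                self.mask[k, d] = True
                stack.extend(children[k])
        self.maskf = self.mask.astype(float)
        self.jw = self.maskf.copy()
        if not self.anchored:
            self.jw[:, 0:2] = 0.0  # translations carry no angular velocity

        # joint-limit parameters: per-joint stiffness/damping capped by the
        # subtree inertia so the one-sided stops stay stable at the timestep
        g = m.gravity
        total = m.total_mass()
        k_req = (
            m.joint_limit_stiffness
            if m.joint_limit_stiffness is not None
            else 2.0 * total * g
        )
        c_req = (
            m.joint_limit_damping
            if m.joint_limit_damping is not None
            else 0.05 * k_req
        )
        self.k_limit = np.full(NJ, k_req)
        self.c_limit = np.full(NJ, c_req)

        # contacts
        nc = len(m.contacts)
        self.contact_names = [c.name for c in m.contacts]
        self.c_link = np.array(
            [self.link_of_segment[c.segment] for c in m.contacts], dtype=int
        )
        self.c_point = np.zeros((nc, 2))
        for i, c in enumerate(m.contacts):
            phi, t = xform[c.segment]
            self.c_point[i] = t + rot(phi) @ c.center_local
        self.c_radius = np.array([c.radius for c in m.contacts])
        self.c_k = np.array([c.stiffness for c in m.contacts])
        self.c_c = np.array([c.damping for c in m.contacts])
        self.c_mu = np.array([c.friction_mu for c in m.contacts])
        self.c_segment = [c.segment for c in m.contacts]

        # muscles: flat way-point arrays + edge lists
        self.muscle_names = [mu.name for mu in m.muscles]
        nM = len(m.muscles)
        wp_link, wp_point, wp_seg, wp_muscle = [], [], [], []
        e0, e1, e_m = [], [], []
        for mi, mu in enumerate(m.muscles):
            start = len(wp_link)
            for seg, p in mu.path:
                phi, t = xform[seg]
                wp_link.append(self.link_of_segment[seg])
                wp_point.append(t + rot(phi) @ np.asarray(p, dtype=float))
                wp_seg.append(seg)
                wp_muscle.append(mi)
            for k in range(start, len(wp_link) - 1):
                e0.append(k)
                e1.append(k + 1)
                e_m.append(mi)
        self.wp_link = np.array(wp_link, dtype=int)
        self.wp_point = np.array(wp_point).reshape(-1, 2)
        self.wp_seg = wp_seg
        self.wp_muscle = np.array(wp_muscle, dtype=int)
        self.e0 = np.array(e0, dtype=int)
        self.e1 = np.array(e1, dtype=int)
        self.e_m = np.array(e_m, dtype=int)
        self.mu_fmax = np.array([mu.max_isometric_force() for mu in m.muscles])
        self.mu_lopt = np.array([mu.fibre_length for mu in m.muscles])
        self.mu_slack = np.array([mu.tendon_slack_length for mu in m.muscles])
        self.mu_tau = np.array([mu.activation_tau for mu in m.muscles])

        # hip joints for the fall test
        self.hip_links = [
            link_index[j.child]
            for j in ordered_hinges
            if j.name in m.hip_joints
        ]

        # stress monitors
        self.monitor_names = [mon.name for mon in m.monitors]
        self._monitors = []
        fj_by_name = {j.name: j for j in m.fixed_joints}
        for mon in m.monitors:
            fj = fj_by_name[mon.fixed_joint]
            if not fj.is_load_cut:
                raise EngineError(f"monitor {mon.name!r}: joint is not a load cut")
            link = self.link_of_segment[fj.child]
            phi_p, t_p = xform[fj.parent]
            w_local = t_p + rot(phi_p) @ fj.anchor_parent
            axis = rot(phi_p) @ fj.cut_axis
            # distal member set: child side of the weld within the link
            distal = set()
            stack = [fj.child]
            while stack:
                s = stack.pop()
                distal.add(s)
                for j2 in m.fixed_joints:
                    if j2.parent == s and self.link_of_segment[j2.child] == link:
                        stack.append(j2.child)
            md = sum(seg_by_name[s].mass for s in distal)
            com_d = sum(
                seg_by_name[s].mass
                * (xform[s][1] + rot(xform[s][0]) @ seg_by_name[s].com_local)
                for s in distal
            ) / md
            i_d = sum(
                seg_by_name[s].inertia_zz
                + seg_by_name[s].mass
                * float(
                    (
                        xform[s][1]
                        + rot(xform[s][0]) @ seg_by_name[s].com_local
                        - com_d
                    )
                    @ (
                        xform[s][1]
                        + rot(xform[s][0]) @ seg_by_name[s].com_local
                        - com_d
                    )
                )
                for s in distal
            )
            child_links = [
                l
                for l in range(1, L)
                if self.parent_link[l] == link
                and ordered_hinges[l - 1].parent in distal
            ]
            wp_idx = np.array(
                [i for i, s in enumerate(wp_seg) if s in distal], dtype=int
            )
            ct_idx = np.array(
                [i for i, s in enumerate(self.c_segment) if s in distal], dtype=int
            )
            secs = []
            for sec_name in mon.sections:
                spec = m.sections[sec_name]
                secs.append(
                    hollow_section_from_outline(
                        spec.outer_outline, spec.cortical_fraction
                    )
                )
            a_tot = sum(s.area for s in secs)
            i_tot = sum(s.ix for s in secs)
            sec_data = []
            for s in secs:
                d = s.ix * s.iy - s.ixy**2
                kv = (s.iy * s.outer_boundary[:, 1] - s.ixy * s.outer_boundary[:, 0]) / d
                sec_data.append(
                    {
                        "area": s.area,
                        "w_a": s.area / a_tot,
                        "w_i": s.ix / i_tot,
                        "kmax": float(kv.max()),
                        "kmin": float(kv.min()),
                        "section": s,
                    }
                )
            self._monitors.append(
                {
                    "name": mon.name,
                    "link": link,
                    "w_local": w_local,
                    "axis_local": axis / np.hypot(*axis),
                    "mass_d": md,
                    "com_d": com_d,
                    "i_d": i_d,
                    "child_links": child_links,
                    "wp_idx": wp_idx,
                    "ct_idx": ct_idx,
                    "sections": sec_data,
                }
            )

        self.g_vec = np.array([0.0, -m.gravity])

        # stability caps on the joint stops, from subtree inertia at build pose
        if NJ:
            q0 = np.zeros(self.n_dof)
            if not self.anchored:
                q0[0:3] = m.root_start
            q0[self.n_base :] = self.q0_joints
            fk0 = self._fk(q0, np.zeros(self.n_dof))
            dt = self.config.timestep
            for jj in range(NJ):
                l = jj + 1
                sub = np.nonzero(self.mask[:, self.n_base + jj])[0]
                d2 = np.sum((fk0["pcom"][sub] - fk0["W"][l]) ** 2, axis=1)
                i_sub = float(np.sum(self.i_link[sub] + self.m_link[sub] * d2))
                self.k_limit[jj] = min(self.k_limit[jj], 0.05 * i_sub / dt**2)
                self.c_limit[jj] = min(
                    self.c_limit[jj],
                    float(np.sqrt(self.k_limit[jj] * i_sub)),
                    0.25 * i_sub / dt,
                )

    # -- state --------------------------------------------------------------

    def reset(self) -> None:
        q = np.zeros(self.n_dof)
        if not self.anchored:
            q[0:3] = self.model.root_start
        q[self.n_base :] = self.q0_joints
        self.q = q
        self.qd = np.zeros(self.n_dof)
        self.t = 0.0
        self.activation = np.zeros(len(self.muscle_names))

    # -- kinematics ---------------------------------------------------------

    def _fk(self, q, qd):
        L = self.n_links
        nb = self.n_base
        ql, qdl = q.tolist(), qd.tolist()
        th = [0.0] * L
        om = [0.0] * L
        cs = [1.0] * L
        sn = [0.0] * L
        ox = [0.0] * L
        oy = [0.0] * L
        vx = [0.0] * L
        vy = [0.0] * L
        ax = [0.0] * L
        ay = [0.0] * L
        wx = [0.0] * L
        wy = [0.0] * L
        if not self.anchored:
            th[0] = ql[2]
            om[0] = qdl[2]
            ox[0], oy[0] = ql[0], ql[1]
            vx[0], vy[0] = qdl[0], qdl[1]
            cs[0], sn[0] = np.cos(ql[2]), np.sin(ql[2])
        for l in range(1, L):
            p = self._par_l[l]
            cp, sp = cs[p], sn[p]
            apx, apy = self._ap_l[l]
            rx = cp * apx - sp * apy
            ry = sp * apx + cp * apy
            wxl = ox[p] + rx
            wyl = oy[p] + ry
            t = th[p] + self._off_l[l] + ql[nb + l - 1]
            w = om[p] + qdl[nb + l - 1]
            c, s = np.cos(t), np.sin(t)
            acx, acy = self._ac_l[l]
            acx_ = c * acx - s * acy
            acy_ = s * acx + c * acy
            omp = om[p]
            th[l], om[l], cs[l], sn[l] = t, w, c, s
            ox[l] = wxl - acx_
            oy[l] = wyl - acy_
            vx[l] = vx[p] - omp * ry + w * acy_
            vy[l] = vy[p] + omp * rx - w * acx_
            ax[l] = ax[p] - omp * omp * rx + w * w * acx_
            ay[l] = ay[p] - omp * omp * ry + w * w * acy_
            wx[l], wy[l] = wxl, wyl
        theta = np.array(th)
        omega = np.array(om)
        c_arr, s_arr = np.array(cs), np.array(sn)
        o = np.column_stack([ox, oy])
        vo = np.column_stack([vx, vy])
        aob = np.column_stack([ax, ay])
        W = np.column_stack([wx, wy])
        R = np.empty((L, 2, 2))
        R[:, 0, 0] = c_arr
        R[:, 0, 1] = -s_arr
        R[:, 1, 0] = s_arr
        R[:, 1, 1] = c_arr
        rcx = c_arr * self.com_link[:, 0] - s_arr * self.com_link[:, 1]
        rcy = s_arr * self.com_link[:, 0] + c_arr * self.com_link[:, 1]
        rc = np.column_stack([rcx, rcy])
        pcom = o + rc
        vcom = np.column_stack([vo[:, 0] - omega * rcy, vo[:, 1] + omega * rcx])
        acomb = aob - omega[:, None] ** 2 * rc
        return {
            "theta": theta,
            "omega": omega,
            "cos": c_arr,
            "sin": s_arr,
            "o": o,
            "vo": vo,
            "aob": aob,
            "R": R,
            "W": W,
            "pcom": pcom,
            "vcom": vcom,
            "acomb": acomb,
        }

    def _jacobian(self, fk):
        L, D = self.n_links, self.n_dof
        pivots = np.zeros((D, 2))
        if not self.anchored:
            pivots[2] = fk["o"][0]
        for l in range(1, L):
            pivots[self.n_base + l - 1] = fk["W"][l]
        rel = fk["pcom"][:, None, :] - pivots[None, :, :]
        jp = np.empty((L, D, 2))
        jp[:, :, 0] = -rel[:, :, 1] * self.maskf
        jp[:, :, 1] = rel[:, :, 0] * self.maskf
        if not self.anchored:
            jp[:, 0, 0] = 1.0
            jp[:, 0, 1] = 0.0
            jp[:, 1, 0] = 0.0
            jp[:, 1, 1] = 1.0
        return jp

    def body_state(self, q=None, qd=None) -> BodyState:
        fk = self._fk(self.q if q is None else q, self.qd if qd is None else qd)
        return BodyState(
            position=fk["o"],
            orientation=fk["theta"],
            com=fk["pcom"],
            linear_velocity=fk["vcom"],
            angular_velocity=fk["omega"],
        )

    def com(self, fk=None) -> tuple[np.ndarray, np.ndarray]:
        fk = fk or self._fk(self.q, self.qd)
        mt = self.m_link.sum()
        return (
            (self.m_link[:, None] * fk["pcom"]).sum(0) / mt,
            (self.m_link[:, None] * fk["vcom"]).sum(0) / mt,
        )

    def total_energy(self, q=None, qd=None) -> float:
        fk = self._fk(self.q if q is None else q, self.qd if qd is None else qd)
        ke = 0.5 * float(
            np.sum(self.m_link * np.sum(fk["vcom"] ** 2, axis=1))
            + np.sum(self.i_link * fk["omega"] ** 2)
        )
        pe = float(np.sum(self.m_link * self.model.gravity * fk["pcom"][:, 1]))
        return ke + pe

    # -- forces -------------------------------------------------------------

    def _forces(self, fk, qd):
        """Per-link applied force/torque + direct joint torques + per-point records."""
        L = self.n_links
        F = np.zeros((L, 2))
        T = np.zeros(L)
        Qj = np.zeros(self.n_dof)
        cfg = self.config

        # contacts
        c_force = np.zeros((len(self.c_link), 2))
        if len(self.c_link):
            li = self.c_link
            c_l, s_l = fk["cos"][li], fk["sin"][li]
            px = fk["o"][li, 0] + c_l * self.c_point[:, 0] - s_l * self.c_point[:, 1]
            py = fk["o"][li, 1] + s_l * self.c_point[:, 0] + c_l * self.c_point[:, 1]
            low = np.column_stack([px, py - self.c_radius])
            om_l = fk["omega"][li]
            vel = np.column_stack(
                [
                    fk["vo"][li, 0] - om_l * (low[:, 1] - fk["o"][li, 1]),
                    fk["vo"][li, 1] + om_l * (low[:, 0] - fk["o"][li, 0]),
                ]
            )
            delta = cfg.ground_height - low[:, 1]
            ft, fn = contact_force_law(
                delta,
                -vel[:, 1],
                vel[:, 0],
                self.c_k,
                self.c_c,
                self.c_mu,
                cfg.friction_vreg,
            )
            c_force[:, 0] = ft
            c_force[:, 1] = fn
            np.add.at(F, li, c_force)
            np.add.at(T, li, cross2(low - fk["pcom"][li], c_force))
            self._c_points = low
        else:
            self._c_points = np.zeros((0, 2))
        self._c_force = c_force

        # muscles
        nwp = len(self.wp_link)
        wp_force = np.zeros((nwp, 2))
        tension = np.zeros(len(self.muscle_names))
        mtu_len = np.zeros(len(self.muscle_names))
        mtu_vel = np.zeros(len(self.muscle_names))
        if nwp:
            li = self.wp_link
            c_l, s_l = fk["cos"][li], fk["sin"][li]
            px = fk["o"][li, 0] + c_l * self.wp_point[:, 0] - s_l * self.wp_point[:, 1]
            py = fk["o"][li, 1] + s_l * self.wp_point[:, 0] + c_l * self.wp_point[:, 1]
            P = np.column_stack([px, py])
            om_l = fk["omega"][li]
            V = np.column_stack(
                [
                    fk["vo"][li, 0] - om_l * (py - fk["o"][li, 1]),
                    fk["vo"][li, 1] + om_l * (px - fk["o"][li, 0]),
                ]
            )
            dP = P[self.e1] - P[self.e0]
            elen = np.hypot(dP[:, 0], dP[:, 1])
            safe = np.maximum(elen, 1e-12)
            u = dP / safe[:, None]
            np.add.at(mtu_len, self.e_m, elen)
            np.add.at(
                mtu_vel, self.e_m, np.einsum("ea,ea->e", u, V[self.e1] - V[self.e0])
            )
            tension = self._mtu_forces(self.activation, mtu_len, mtu_vel)
            te = tension[self.e_m]
            np.add.at(wp_force, self.e0, te[:, None] * u)
            np.add.at(wp_force, self.e1, -te[:, None] * u)
            np.add.at(F, li, wp_force)
            np.add.at(T, li, cross2(P - fk["pcom"][li], wp_force))
            self._wp_points = P
        else:
            self._wp_points = np.zeros((0, 2))
        self._wp_force = wp_force
        self._tension = tension
        self._mtu_len = mtu_len
        self._mtu_vel = mtu_vel

        # joint limits: one-sided torsional spring-dampers at the range ends
        qj = self.q[self.n_base :]
        qdj = qd[self.n_base :]
        tau = np.zeros(self.n_joints)
        below = qj < self.joint_lo
        above = qj > self.joint_hi
        tau[below] = np.maximum(
            0.0,
            self.k_limit[below] * (self.joint_lo[below] - qj[below])
            - self.c_limit[below] * qdj[below],
        )
        tau[above] = np.minimum(
            0.0,
            self.k_limit[above] * (self.joint_hi[above] - qj[above])
            - self.c_limit[above] * qdj[above],
        )
        Qj[self.n_base :] += tau
        self._tau_limit = tau
        return F, T, Qj

    def _mtu_forces(self, act, length, velocity):
        """Vectorised Hill-type force over all muscles (see muscle module)."""
        lopt = self.mu_lopt
        lf = length - self.mu_slack
        ln = np.where(lopt > 0, lf / np.maximum(lopt, 1e-12), 0.0)
        vn = velocity / (VMAX_FIBRE_LENGTHS * np.maximum(lopt, 1e-12))
        fl = np.maximum(0.0, 1.0 - ((ln - 1.0) / 0.5) ** 2)
        fv = np.where(
            vn < 0.0,
            np.clip((1.0 + vn) / (1.0 - vn / 0.25), 0.0, None),
            np.minimum(1.0 + 0.5 * vn / (vn + 0.25 / 3.0), 1.5),
        )
        fp = np.minimum((np.maximum(0.0, ln - 1.0) / 0.6) ** 2, 1.5)
        f = self.mu_fmax * (act * fl * fv + fp)
        return np.where(lf > 0.0, np.maximum(f, 0.0), 0.0)

    # -- dynamics -----------------------------------------------------------

    def _accel(self, fk, F, T, Qj):
        if self.n_dof == 0:
            return np.zeros(0)
        jp = self._jacobian(fk)
        mw = self.m_link
        M = np.einsum("lda,l,lea->de", jp, mw, jp) + np.einsum(
            "ld,l,le->de", self.jw, self.i_link, self.jw
        )
        eff = F + mw[:, None] * (self.g_vec[None, :] - fk["acomb"])
        Q = np.einsum("lda,la->d", jp, eff) + self.jw.T @ T + Qj
        try:
            qdd = np.linalg.solve(M, Q)
        except np.linalg.LinAlgError as e:  # pragma: no cover - degenerate models
            raise SolverDivergence(f"singular mass matrix: {e}") from e
        self._jp = jp
        return qdd

    def step(self, excitation: np.ndarray | None = None) -> np.ndarray:
        """Advance one timestep; returns the generalized accelerations used."""
        dt = self.config.timestep
        if excitation is not None and len(self.activation):
            self.activation = np.clip(
                excitation
                + (self.activation - np.clip(excitation, 0.0, 1.0))
                * np.exp(-dt / self.mu_tau),
                0.0,
                1.0,
            )
        fk = self._fk(self.q, self.qd)
        F, T, Qj = self._forces(fk, self.qd)
        qdd = self._accel(fk, F, T, Qj)
        if not np.all(np.isfinite(qdd)):
            raise SolverDivergence(f"non-finite accelerations at t={self.t:.4f}s")
        self.qd = self.qd + dt * qdd
        self.q = self.q + dt * self.qd
        self.t += dt
        self._fk_last = fk
        self._qdd_last = qdd
        return qdd

    # -- internal load recovery ---------------------------------------------

    def _hinge_reactions(self, fk, qdd, F):
        """Backward Newton-Euler pass: force on each link at its parent hinge."""
        L = self.n_links
        if self.n_dof:
            a_com = fk["acomb"] + np.einsum("lda,d->la", self._jp, qdd)
        else:
            a_com = np.zeros((L, 2))
        Fp = np.zeros((L, 2))
        for l in range(L - 1, 0, -1):
            Fp[l] = (
                self.m_link[l] * (a_com[l] - self.g_vec)
                - F[l]
                + sum(Fp[c] for c in self.children[l])
            )
        return Fp, a_com

    def internal_loads(self, fk, qdd, F) -> list[InternalLoad]:
        """InternalLoad at every registered mid-shaft cut, current step."""
        if not self._monitors:
            return []
        Fp, a_com = self._hinge_reactions(fk, qdd, F)
        if self.n_dof:
            alpha = self.jw @ qdd
        else:
            alpha = np.zeros(self.n_links)
        out = []
        for mon in self._monitors:
            l = mon["link"]
            Rl, ol = fk["R"][l], fk["o"][l]
            w = ol + Rl @ mon["w_local"]
            u = Rl @ mon["axis_local"]
            pd_w = ol + Rl @ mon["com_d"]
            rrel = pd_w - fk["pcom"][l]
            a_d = (
                a_com[l]
                + alpha[l] * perp(rrel)
                - fk["omega"][l] ** 2 * rrel
            )
            md = mon["mass_d"]
            f_ext = np.zeros(2)
            m_ext = 0.0
            if len(mon["wp_idx"]):
                fw = self._wp_force[mon["wp_idx"]]
                pw = self._wp_points[mon["wp_idx"]]
                f_ext += fw.sum(0)
                m_ext += float(np.sum(cross2(pw - w, fw)))
            if len(mon["ct_idx"]):
                fc = self._c_force[mon["ct_idx"]]
                pc = self._c_points[mon["ct_idx"]]
                f_ext += fc.sum(0)
                m_ext += float(np.sum(cross2(pc - w, fc)))
            f_children = np.zeros(2)
            m_children = 0.0
            for c in mon["child_links"]:
                f_children += Fp[c]
                m_children += float(cross2(fk["W"][c] - w, Fp[c]))
                m_children += self._tau_limit[c - 1]
            f_cut = md * a_d - md * self.g_vec - f_ext + f_children
            m_cut = (
                mon["i_d"] * alpha[l]
                + float(cross2(pd_w - w, md * a_d))
                - float(cross2(pd_w - w, md * self.g_vec))
                - m_ext
                + m_children
            )
            out.append(
                InternalLoad(
                    axial_force=float(-f_cut @ u),
                    shear_force=float(-f_cut @ perp(u)),
                    bending_moment_x=float(m_cut),
                )
            )
        return out

    def measure_internal_load(self, monitor: str | int = 0) -> InternalLoad:
        """Recompute the cut load at the current state (for static rigs too)."""
        if isinstance(monitor, str):
            monitor = self.monitor_names.index(monitor)
        if not self._monitors:
            raise EngineError("model has no load-cut monitors")
        fk = self._fk(self.q, self.qd)
        F, T, Qj = self._forces(fk, self.qd)
        qdd = self._accel(fk, F, T, Qj) if self.n_dof else np.zeros(0)
        return self.internal_loads(fk, qdd, F)[monitor]

    def monitor_stress(self, loads: list[InternalLoad]) -> tuple[np.ndarray, np.ndarray]:
        """Peak boundary stress extremes (max, min) per monitor from cut loads.

        With multiple sections per monitor (tibia + fibula) the axial force is
        shared by area and the bending moment by bending stiffness.
        """
        smax = np.full(len(self._monitors), -np.inf)
        smin = np.full(len(self._monitors), np.inf)
        for i, (mon, load) in enumerate(zip(self._monitors, loads)):
            for sd in mon["sections"]:
                f = load.axial_force * sd["w_a"]
                mx = load.bending_moment_x * sd["w_i"]
                base = f / sd["area"]
                hi = base + max(mx * sd["kmax"], mx * sd["kmin"])
                lo = base + min(mx * sd["kmax"], mx * sd["kmin"])
                smax[i] = max(smax[i], hi)
                smin[i] = min(smin[i], lo)
        return smax, smin

    # -- simulation driver ----------------------------------------------------

    def run(
        self,
        controller=None,
        stress_limit: float = np.inf,
        duration: float | None = None,
    ) -> Trajectory:
        """Run until the duration, a fall, or a filtered-stress failure.

        Deterministic: identical inputs give an identical trajectory, and the
        stress monitor is purely observational — raising the limit to infinity
        reproduces the unconstrained trajectory exactly.
        """
        cfg = self.config
        dt = cfg.timestep
        duration = cfg.duration if duration is None else duration
        n_steps = int(round(duration / dt))
        rec = cfg.record_every
        sample_rate = 1.0 / (dt * rec)
        nmon = len(self._monitors)
        filt_max = StreamingLowpass(
            sample_rate, cfg.stress_cutoff_hz, cfg.stress_filter_order
        )
        filt_min = StreamingLowpass(
            sample_rate, cfg.stress_cutoff_hz, cfg.stress_filter_order
        )

        rows: dict[str, list] = {k: [] for k in (
            "t", "q", "qd", "com", "comv", "hip", "cf", "cflag", "act", "mf",
            "la", "ls", "lm", "sraw_max", "sraw_min", "sfil_max", "sfil_min")}
        standing_hip = None
        termination = Termination("completed", duration)

        def hip_height(fk):
            if not self.hip_links:
                return np.nan
            return float(np.mean([fk["W"][l][1] for l in self.hip_links]))

        i = 0
        while i <= n_steps:
            t = i * dt
            if controller is not None and len(self.activation):
                exc = np.asarray(
                    controller.excitations_at(t, self.muscle_names), dtype=float
                )
                if i == 0:
                    self.activation = np.clip(exc, 0.0, 1.0)
                else:
                    self.activation = np.clip(
                        exc
                        + (self.activation - np.clip(exc, 0.0, 1.0))
                        * np.exp(-dt / self.mu_tau),
                        0.0,
                        1.0,
                    )
            fk = self._fk(self.q, self.qd)
            F, T, Qj = self._forces(fk, self.qd)
            qdd = self._accel(fk, F, T, Qj) if self.n_dof else np.zeros(0)
            if not np.all(np.isfinite(qdd)):
                termination = Termination(
                    "diverged", t, f"non-finite accelerations at t={t:.4f}s"
                )
                break
            record = i % rec == 0
            if record:
                loads = self.internal_loads(fk, qdd, F)
                smax, smin = self.monitor_stress(loads) if nmon else (
                    np.zeros(0), np.zeros(0))
                fmax = filt_max(smax) if nmon else smax
                fmin = filt_min(smin) if nmon else smin
                com, comv = self.com(fk)
                hh = hip_height(fk)
                rows["t"].append(t)
                rows["q"].append(self.q.copy())
                rows["qd"].append(self.qd.copy())
                rows["com"].append(com)
                rows["comv"].append(comv)
                rows["hip"].append(hh)
                rows["cf"].append(self._c_force.copy())
                rows["cflag"].append(self._c_force[:, 1] > 0.0)
                rows["act"].append(self.activation.copy())
                rows["mf"].append(self._tension.copy())
                rows["la"].append([ld.axial_force for ld in loads])
                rows["ls"].append([ld.shear_force for ld in loads])
                rows["lm"].append([ld.bending_moment_x for ld in loads])
                rows["sraw_max"].append(smax)
                rows["sraw_min"].append(smin)
                rows["sfil_max"].append(fmax)
                rows["sfil_min"].append(fmin)
                if standing_hip is None:
                    standing_hip = hh
                # hard fail criteria
                if nmon and np.isfinite(stress_limit):
                    mag = np.maximum(np.abs(fmax), np.abs(fmin))
                    if np.any(mag > stress_limit):
                        b = int(np.argmax(mag))
                        termination = Termination(
                            "stress_fail",
                            t,
                            f"{self.monitor_names[b]} at "
                            f"{mag[b] / 1e6:.1f} MPa > "
                            f"{stress_limit / 1e6:.1f} MPa",
                        )
                        break
                if (
                    self.hip_links
                    and standing_hip is not None
                    and np.isfinite(hh)
                    and hh < cfg.fall_fraction * standing_hip
                ):
                    termination = Termination("fell", t, f"hip height {hh:.3f} m")
                    break
            if i == n_steps:
                break
            self.qd = self.qd + dt * qdd
            self.q = self.q + dt * self.qd
            self.t = (i + 1) * dt
            i += 1

        tarr = np.array(rows["t"])
        return Trajectory(
            time=tarr,
            q=np.array(rows["q"]),
            qd=np.array(rows["qd"]),
            com=np.array(rows["com"]),
            com_velocity=np.array(rows["comv"]),
            hip_height=np.array(rows["hip"]),
            contact_names=self.contact_names,
            contact_force=np.array(rows["cf"]).reshape(len(tarr), -1, 2),
            contact_flag=np.array(rows["cflag"]).reshape(len(tarr), -1),
            muscle_names=self.muscle_names,
            activation=np.array(rows["act"]).reshape(len(tarr), -1),
            muscle_force=np.array(rows["mf"]).reshape(len(tarr), -1),
            monitor_names=self.monitor_names,
            load_axial=np.array(rows["la"]).reshape(len(tarr), -1),
            load_shear=np.array(rows["ls"]).reshape(len(tarr), -1),
            load_moment=np.array(rows["lm"]).reshape(len(tarr), -1),
            stress_max_raw=np.array(rows["sraw_max"]).reshape(len(tarr), -1),
            stress_min_raw=np.array(rows["sraw_min"]).reshape(len(tarr), -1),
            stress_max_filtered=np.array(rows["sfil_max"]).reshape(len(tarr), -1),
            stress_min_filtered=np.array(rows["sfil_min"]).reshape(len(tarr), -1),
            termination=termination,
            sample_rate=sample_rate,
        )


def run_simulation(
    model: BipedModel,
    controller=None,
    config: SimConfig | None = None,
    stress_limit: float = np.inf,
) -> Trajectory:
    """Convenience wrapper: compile and run a model in one call."""
    return Engine(model, config).run(controller, stress_limit)
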