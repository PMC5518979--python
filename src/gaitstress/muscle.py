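"""Hill-type muscle-tendon units routed along polyline paths.

Each actuator is a chain of way-points fixed in segment frames; its length is
the summed straight-line distance between consecutive world-frame way-points.
Force generation is a bounded Hill-type model: active force
``a * f_max * f_L(l) * f_v(v)`` plus passive fibre elasticity, transmitted
through a series tendon that is slack (zero force) whenever the path is
shorter than the tendon slack length.  Fibre kinematics use the stiff-tendon
approximation (fibre length = path length minus tendon slack), the standard
simplification in large gait models; the contract-level behaviour — bounded
nonnegative force, f_L(1) = f_v(0) = 1, zero force at full shortening
velocity — is what the rest of the package relies on.

Maximum isometric force defaults to specific tension times physiological
cross-sectional area, PCSA = mass / (density * optimal fibre length).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Muscle specific tension, N/m^2 (0.3 MPa, vertebrate skeletal muscle).
SPECIFIC_TENSION = 3.0e5
#: Muscle density, kg/m^3.
MUSCLE_DENSITY = 1060.0
#: Maximum shortening velocity in optimal fibre lengths per second.
VMAX_FIBRE_LENGTHS = 10.0


@dataclass(eq=False)
class MuscleTendonUnit:
    name: str
    path: list[tuple[str, np.ndarray]]
    f_max: float | None = None
    fibre_length: float = 0.1
    tendon_slack_length: float = 0.0
    mass: float = 0.0
    action: str = "extensor"  # extensor | flexor
    location: str = "proximal"  # proximal | intermediate | distal
    activation_tau: float = 0.05

    def __post_init__(self) -> None:
        self.path = [(seg, np.asarray(p, dtype=float)) for seg, p in self.path]

    def max_isometric_force(self) -> float:
        if self.f_max is not None:
            return self.f_max
        if self.mass <= 0 or self.fibre_length <= 0:
            raise ValueError(
                f"muscle {self.name!r}: need f_max or mass + fibre_length"
            )
        pcsa = self.mass / (MUSCLE_DENSITY * self.fibre_length)
        return SPECIFIC_TENSION * pcsa


@dataclass
class MuscleState:
    activation: float = 0.0
    mtu_length: float = 0.0
    mtu_velocity: float = 0.0
    force: float = 0.0


def path_length(muscle: MuscleTendonUnit, poses: dict) -> float:
    """MTU length for segment poses given as {segment: (R, t)}."""
    pts = np.array([t + r @ p for (seg, p), (r, t) in
                    ((wp, poses[wp[0]]) for wp in muscle.path)])
    return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))


def mtu_length(muscle: MuscleTendonUnit, poses: dict) -> float:
    """Sum of straight-line distances between consecutive world way-points."""
    return path_length(muscle, poses)


def moment_arm(
    muscle: MuscleTendonUnit,
    joint_name: str,
    model,
    joint_angles: dict[str, float] | None = None,
    step: float = 1e-5,
) -> float:
    """Moment arm about a hinge joint by central finite difference, -dL/dq.

    Positive sign means the muscle generates torque in the joint's positive
    angular direction.
    """
    from .model import joints_crossed_by, model_poses

    crossed = {j.name for j in joints_crossed_by(model, muscle)}
    if joint_name not in crossed:
        raise ValueError(f"muscle {muscle.name!r} does not cross joint {joint_name!r}")
    angles = {j.name: j.q0 for j in model.joints}
    if joint_angles:
        angles.update(joint_angles)
    q = angles[joint_name]
    angles[joint_name] = q + step
    lp = path_length(muscle, model_poses(model, angles))
    angles[joint_name] = q - step
    lm = path_length(muscle, model_poses(model, angles))
    return -(lp - lm) / (2.0 * step)


# ---------------------------------------------------------------------------
# force generation
# ---------------------------------------------------------------------------


def force_length(l_norm: float | np.ndarray) -> float | np.ndarray:
    """Active force-length curve: unimodal parabola, f_L(1) = 1, zero width 0.5."""
    return np.maximum(0.0, 1.0 - ((np.asarray(l_norm) - 1.0) / 0.5) ** 2)


def force_velocity(v_norm: float | np.ndarray) -> float | np.ndarray:
    """Hill hyperbola (shortening negative): f_v(-1) = 0, f_v(0) = 1, cap 1.5."""
    v = np.asarray(v_norm, dtype=float)
    a_h = 0.25
    short = np.clip((1.0 + v) / (1.0 - v / a_h), 0.0, None)
    lengthen = 1.0 + 0.5 * v / (v + 0.25 / 3.0)
    out = np.where(v < 0.0, short, np.minimum(lengthen, 1.5))
    return out if out.ndim else float(out)


def passive_force_length(l_norm: float | np.ndarray) -> float | np.ndarray:
    """Passive fibre elasticity: f_max at 60% stretch, capped at 1.5 f_max."""
    s = np.maximum(0.0, np.asarray(l_norm) - 1.0)
    return np.minimum((s / 0.6) ** 2, 1.5)


def mtu_force(
    muscle: MuscleTendonUnit,
    activation: float,
    length: float,
    velocity: float,
) -> float:
    """Tensile force (N, always >= 0) of the muscle-tendon unit.

    ``length``/``velocity`` are the whole-path MTU values; the series tendon
    carries no force below its slack length.
    """
    if not (np.isfinite(activation) and np.isfinite(length) and np.isfinite(velocity)):
        raise ValueError("non-finite muscle state")
    a = float(np.clip(activation, 0.0, 1.0))
    l_opt = muscle.fibre_length
    l_fibre = length - muscle.tendon_slack_length
    if l_fibre <= 0.0 or l_opt <= 0.0:
        return 0.0
    l_norm = l_fibre / l_opt
    v_norm = velocity / (VMAX_FIBRE_LENGTHS * l_opt)
    fmax = muscle.max_isometric_force()
    f = fmax * (a * force_length(l_norm) * force_velocity(v_norm)
                + passive_force_length(l_norm))
    return max(0.0, float(f))


def activation_update(
    excitation: float, activation: float, dt: float, time_constant: float = 0.05
) -> float:
    """First-order activation lag, integrated exactly over dt; clipped to [0, 1]."""
    e = float(np.clip(excitation, 0.0, 1.0))
    a = e + (activation - e) * np.exp(-dt / time_constant)
    return float(np.clip(a, 0.0, 1.0))
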