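"""Post-hoc gait analytics: duty factor, Froude number, stride metrics,
kinetic/potential energy phase, and walk / grounded-run / aerial-run
classification.

Definitions used throughout:

* duty factor — fraction of a gait cycle a limb's foot produces ground force;
  > 0.5 implies a double-support phase (walking), < 0.5 an aerial phase
  (running) for an ideal biped.
* Froude number — Fr = v^2 / (g h) with h the standing hip height; Fr near 1
  marks the inverted-pendulum ceiling of walking.
* energy phase difference — the lag, as a percentage of the gait cycle folded
  into [0, 50], that maximises the cross-correlation between the mean-removed
  horizontal kinetic energy and gravitational potential energy series.
  Out-of-phase (~50%) transformations mark vaulting walks; in-phase (~0%)
  marks bouncing (running) mechanics, even without an aerial phase
  ("grounded running").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .dynamics import Trajectory

#: Contact detection threshold as a fraction of body weight, to suppress
#: numerical chatter in the spring-damper contact forces.
CONTACT_FORCE_FRACTION = 1e-3


@dataclass(eq=False)
class EnergyTrace:
    time: np.ndarray
    kinetic_horizontal: np.ndarray
    potential: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.kinetic_horizontal + self.potential


@dataclass
class GaitSummary:
    mean_velocity: float
    froude: float
    stride_length: float
    cycle_duration: float
    duty_factor: dict[str, float]
    aerial_phase: bool
    energy_phase_pct: float
    gait_class: str


def limb_contact_flags(
    traj: Trajectory, body_weight: float | None = None
) -> dict[str, np.ndarray]:
    """Per-limb ground-contact booleans, limbs keyed by name suffix (_l/_r).

    A limb is in contact when any of its spheres' normal force exceeds the
    chatter threshold (a small fraction of body weight when supplied).
    """
    if not traj.contact_names:
        raise ValueError("trajectory has no contact spheres")
    thr = 0.0 if body_weight is None else CONTACT_FORCE_FRACTION * body_weight
    limbs: dict[str, list[int]] = {}
    for i, name in enumerate(traj.contact_names):
        side = "right" if name.endswith("_r") or "_r_" in name else "left"
        limbs.setdefault(side, []).append(i)
    return {
        side: np.any(traj.contact_force[:, idx, 1] > thr, axis=1)
        for side, idx in limbs.items()
    }


def touchdown_times(flags: np.ndarray, time: np.ndarray) -> np.ndarray:
    """Times of rising contact edges (foot touchdowns)."""
    f = np.asarray(flags, dtype=bool)
    edges = np.nonzero(f[1:] & ~f[:-1])[0] + 1
    return time[edges]


def duty_factor(flags: np.ndarray, time: np.ndarray,
                cycles: list[tuple[float, float]]) -> float:
    """Fraction of the cycle with foot contact, averaged over complete cycles."""
    if not cycles:
        raise ValueError("need at least one complete gait cycle")
    fracs = []
    for t0, t1 in cycles:
        sel = (time >= t0) & (time < t1)
        if not np.any(sel):
            continue
        fracs.append(float(np.mean(flags[sel])))
    if not fracs:
        raise ValueError("cycles do not overlap the sampled time grid")
    return float(np.mean(fracs))


def froude_number(velocity: float, hip_height: float, g: float = 9.81) -> float:
    """Dimensionless speed v^2 / (g h); 1.0 at the walk-run pendular limit."""
    if hip_height <= 0:
        raise ValueError("hip height must be positive")
    return velocity**2 / (g * hip_height)


def stride_metrics(traj: Trajectory, side: str | None = None,
                   body_weight: float | None = None) -> tuple[float, float]:
    """Mean stride length (m) and gait-cycle duration (s) from footfalls.

    Cycle duration is the mean interval between successive touchdowns of the
    same foot; stride length is the mean forward COM displacement per cycle.
    """
    flags = limb_contact_flags(traj, body_weight)
    side = side or ("left" if "left" in flags else next(iter(flags)))
    tds = touchdown_times(flags[side], traj.time)
    if len(tds) < 2:
        raise ValueError("fewer than two touchdowns of the same foot")
    cycle = float(np.mean(np.diff(tds)))
    xs = np.interp(tds, traj.time, traj.com[:, 0])
    stride = float(np.mean(np.diff(xs)))
    return stride, cycle


def gait_cycles(traj: Trajectory, side: str | None = None,
                body_weight: float | None = None) -> list[tuple[float, float]]:
    flags = limb_contact_flags(traj, body_weight)
    side = side or ("left" if "left" in flags else next(iter(flags)))
    tds = touchdown_times(flags[side], traj.time)
    return list(zip(tds[:-1], tds[1:]))


def energy_trace(traj: Trajectory, total_mass: float, g: float = 9.81) -> EnergyTrace:
    """Horizontal KE (half m v_x^2) and gravitational PE (m g y) of the COM."""
    ke = 0.5 * total_mass * traj.com_velocity[:, 0] ** 2
    pe = total_mass * g * traj.com[:, 1]
    return EnergyTrace(time=traj.time, kinetic_horizontal=ke, potential=pe)


def phase_difference_pct(a: np.ndarray, b: np.ndarray, cycle_samples: float) -> float:
    """Lag maximising the cross-correlation of two series, as % of a cycle.

    Series are mean-removed and amplitude-normalised; the lag search is
    restricted to half a cycle either way, so the result folds into [0, 50].
    Symmetric in its arguments and invariant to amplitude scaling.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a - a.mean()
    b = b - b.mean()
    sa, sb = np.std(a), np.std(b)
    if sa <= 0 or sb <= 0:
        raise ValueError("phase difference undefined for a constant series")
    a, b = a / sa, b / sb
    corr = signal.correlate(a, b, mode="full")
    lags = signal.correlation_lags(len(a), len(b), mode="full")
    half = int(round(cycle_samples / 2.0))
    sel = np.abs(lags) <= max(half, 1)
    i = int(np.argmax(corr[sel]))
    lag = abs(int(lags[sel][i]))
    return 100.0 * lag / cycle_samples


def energy_transformations(
    traj: Trajectory, total_mass: float, cycle_duration: float | None = None,
    g: float = 9.81,
) -> tuple[EnergyTrace, float]:
    """Energy series plus KE/PE phase difference (% of cycle, in [0, 50])."""
    tr = energy_trace(traj, total_mass, g)
    if cycle_duration is None:
        _, cycle_duration = stride_metrics(traj)
    dt = float(np.mean(np.diff(traj.time)))
    if traj.time[-1] - traj.time[0] < 2.0 * cycle_duration:
        raise ValueError("need at least two complete gait cycles")
    pct = phase_difference_pct(
        tr.kinetic_horizontal, tr.potential, cycle_duration / dt
    )
    return tr, pct


def classify_gait(
    duty_factors: dict[str, float] | float,
    aerial_phase: bool,
    energy_phase_pct: float,
    walk_phase_threshold: float = 25.0,
) -> str:
    """walk / grounded run / aerial run from contact and energy criteria.

    An aerial phase marks a true (aerial) run regardless of energetics;
    otherwise out-of-phase KE/PE above the threshold marks a vaulting walk
    and in-phase transformations a grounded run.
    """
    if aerial_phase:
        return "aerial run"
    if energy_phase_pct >= walk_phase_threshold:
        return "walk"
    return "grounded run"


def summarize_gait(
    traj: Trajectory,
    model=None,
    total_mass: float | None = None,
    standing_hip_height: float | None = None,
    walk_phase_threshold: float = 25.0,
) -> GaitSummary:
    """Full gait summary of a simulated trajectory.

    Velocity is the mean forward COM speed; Froude uses the standing hip
    height (first recorded sample unless given); aerial phase is any sampled
    instant within the analysed cycles with no foot in contact.
    """
    if model is not None:
        total_mass = model.total_mass()
        g = model.gravity
    else:
        g = 9.81
    if total_mass is None:
        raise ValueError("need a model or total_mass")
    bw = total_mass * g
    elapsed = float(traj.time[-1] - traj.time[0])
    v = max(0.0, traj.distance) / max(elapsed, 1e-12)
    hip = standing_hip_height
    if hip is None:
        hip = float(traj.hip_height[0])
    flags = limb_contact_flags(traj, bw)
    cycles = gait_cycles(traj, body_weight=bw)
    if not cycles:
        raise ValueError("no complete gait cycle in trajectory")
    duty = {side: duty_factor(f, traj.time, cycles) for side, f in flags.items()}
    t0, t1 = cycles[0][0], cycles[-1][1]
    span = (traj.time >= t0) & (traj.time < t1)
    any_contact = np.zeros(span.sum(), dtype=bool)
    for f in flags.values():
        any_contact |= f[span]
    aerial = bool(np.any(~any_contact))
    stride, cycle = stride_metrics(traj, body_weight=bw)
    try:
        _, phase = energy_transformations(traj, total_mass, cycle, g)
    except ValueError:
        phase = np.nan
    gait = classify_gait(duty, aerial, phase if np.isfinite(phase) else 0.0,
                         walk_phase_threshold)
    return GaitSummary(
        mean_velocity=v,
        froude=froude_number(v, hip, g),
        stride_length=stride,
        cycle_duration=cycle,
        duty_factor=duty,
        aerial_phase=aerial,
        energy_phase_pct=phase,
        gait_class=gait,
    )
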