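import numpy as np
import pytest

from gaitstress.dynamics import Termination, Trajectory
from gaitstress.fixtures import make_toy_biped, make_trex_like


@pytest.fixture(scope="session")
def toy_model():
    return make_toy_biped()


@pytest.fixture(scope="session")
def trex_model():
    return make_trex_like()


def synthetic_trajectory(
    duration: float = 4.0,
    dt: float = 0.002,
    velocity: float = 2.0,
    cycle: float = 1.0,
    duty: float = 0.6,
    hip_height: float = 1.0,
    com_wave_amplitude: float = 0.02,
    com_wave_phase: float = 0.0,
    vx_wave_amplitude: float = 0.0,
) -> Trajectory:
    """Hand-built constant-speed gait trajectory with prescribed footfalls.

    Left footfalls at t = 0, cycle, 2*cycle, ...; the right foot is delayed by
    half a cycle.  COM height and forward velocity can carry sinusoidal waves
    at the cycle frequency for energy-phase tests.
    """
    t = np.arange(0.0, duration + dt / 2, dt)
    n = len(t)
    phase = (t % cycle) / cycle
    left = phase < duty
    right = ((t + 0.5 * cycle) % cycle) / cycle < duty
    cf = np.zeros((n, 2, 2))
    cf[left, 0, 1] = 1000.0
    cf[right, 1, 1] = 1000.0
    w = 2.0 * np.pi / cycle
    com = np.column_stack(
        [velocity * t, hip_height + com_wave_amplitude * np.sin(w * t + com_wave_phase)]
    )
    comv = np.column_stack(
        [velocity + vx_wave_amplitude * np.sin(w * t),
         com_wave_amplitude * w * np.cos(w * t + com_wave_phase)]
    )
    z = np.zeros((n, 0))
    return Trajectory(
        time=t, q=z, qd=z, com=com, com_velocity=comv,
        hip_height=np.full(n, hip_height),
        contact_names=["foot_l", "foot_r"],
        contact_force=cf, contact_flag=cf[:, :, 1] > 0,
        muscle_names=[], activation=z, muscle_force=z,
        monitor_names=[], load_axial=z, load_shear=z, load_moment=z,
        stress_max_raw=z, stress_min_raw=z,
        stress_max_filtered=z, stress_min_filtered=z,
        termination=Termination("completed", duration),
        sample_rate=1.0 / dt,
    )


@pytest.fixture
def synth_traj():
    return synthetic_trajectory
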