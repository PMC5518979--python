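"""Cyclic open-loop muscle activation controllers.

A controller holds, for each controlled muscle, a list of N activation levels
over equal phases of a gait cycle, plus the cycle duration.  With the
left-right symmetry flag set (the default), only left-side muscles are stored
and each right-side muscle replays its left counterpart delayed by half a
cycle — the standard symmetric-gait parameterisation that halves the search
space.  The flattened levels plus a normalised cycle-duration gene form the
optimiser's genome, every gene in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def mirror_name(name: str) -> str | None:
    """Right-side counterpart of a left-side muscle name (``*_l`` -> ``*_r``)."""
    if name.endswith("_l"):
        return name[:-2] + "_r"
    if "_l_" in name:
        return name.replace("_l_", "_r_", 1)
    return None


@dataclass(eq=False)
class CyclicController:
    cycle_duration: float
    levels: dict[str, np.ndarray]  # muscle -> (n_phases,) activation levels
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.cycle_duration <= 0:
            raise ValueError("cycle_duration must be positive")
        self.levels = {k: np.asarray(v, dtype=float) for k, v in self.levels.items()}
        n = {len(v) for v in self.levels.values()}
        if len(n) != 1 or min(n) < 2:
            raise ValueError("all muscles need the same number (>= 2) of phases")
        self.n_phases = n.pop()
        self._index_cache: dict[tuple, tuple] = {}

    # -- evaluation ---------------------------------------------------------

    def activation_level(self, muscle: str, time: float) -> float:
        """Commanded level for one muscle at a time (half-cycle delay on the right)."""
        t = time
        levels = self.levels.get(muscle)
        if levels is None and self.symmetric:
            for left, v in self.levels.items():
                if mirror_name(left) == muscle:
                    levels = v
                    t = time + 0.5 * self.cycle_duration
                    break
        if levels is None:
            return 0.0
        phase = int(self.n_phases * ((t % self.cycle_duration) / self.cycle_duration))
        return float(levels[min(phase, self.n_phases - 1)])

    def excitations_at(self, time: float, muscle_names: list[str]) -> np.ndarray:
        """Excitation vector for the engine's muscle ordering (cached mapping)."""
        key = tuple(muscle_names)
        cached = self._index_cache.get(key)
        if cached is None:
            rows = np.zeros((len(muscle_names), self.n_phases))
            delay = np.zeros(len(muscle_names))
            for i, name in enumerate(muscle_names):
                if name in self.levels:
                    rows[i] = self.levels[name]
                elif self.symmetric:
                    for left, v in self.levels.items():
                        if mirror_name(left) == name:
                            rows[i] = v
                            delay[i] = 0.5 * self.cycle_duration
                            break
            cached = (rows, delay)
            self._index_cache[key] = cached
        rows, delay = cached
        tt = (time + delay) % self.cycle_duration
        ph = np.minimum(
            (self.n_phases * tt / self.cycle_duration).astype(int), self.n_phases - 1
        )
        return rows[np.arange(len(rows)), ph]

    # -- genome mapping -----------------------------------------------------

    def muscle_order(self) -> list[str]:
        return sorted(self.levels)

    def to_genome(self, cycle_bounds: tuple[float, float]) -> np.ndarray:
        lo, hi = cycle_bounds
        g = [np.clip((self.cycle_duration - lo) / (hi - lo), 0.0, 1.0)]
        for name in self.muscle_order():
            g.extend(self.levels[name])
        return np.asarray(g, dtype=float)

    @classmethod
    def from_genome(
        cls,
        genome: np.ndarray,
        muscles: list[str],
        n_phases: int,
        cycle_bounds: tuple[float, float],
        symmetric: bool = True,
    ) -> "CyclicController":
        genome = np.clip(np.asarray(genome, dtype=float), 0.0, 1.0)
        lo, hi = cycle_bounds
        expected = 1 + len(muscles) * n_phases
        if len(genome) != expected:
            raise ValueError(f"genome length {len(genome)}, expected {expected}")
        cycle = lo + genome[0] * (hi - lo)
        levels = {}
        for i, name in enumerate(sorted(muscles)):
            levels[name] = genome[1 + i * n_phases : 1 + (i + 1) * n_phases]
        return cls(cycle_duration=cycle, levels=levels, symmetric=symmetric)

    @classmethod
    def genome_size(cls, n_muscles: int, n_phases: int) -> int:
        return 1 + n_muscles * n_phases


def activations_at(controller: CyclicController, time: float, muscle_names) -> np.ndarray:
    """Per-muscle commanded activation vector at a time (module-level alias)."""
    return controller.excitations_at(time, list(muscle_names))


def zero_controller(muscle_names: list[str], cycle_duration: float = 1.0,
                    n_phases: int = 8, symmetric: bool = True) -> CyclicController:
    left = [n for n in muscle_names if not symmetric or not n.endswith("_r")]
    return CyclicController(
        cycle_duration=cycle_duration,
        levels={n: np.zeros(n_phases) for n in left},
        symmetric=symmetric,
    )
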