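"""Evolutionary gait search under a hard peak-stress limit.

Fitness is the horizontal centre-of-mass distance covered in a fixed simulated
time; a run ends early on a fall or when the filtered peak bone stress exceeds
the limit (the hard fail criterion), so early termination is its own penalty.
The optimiser is a seeded generational genetic algorithm (tournament
selection, blend crossover, gaussian mutation, elitism of one) over the cyclic
controller genome.  ``sweep_stress_limits`` re-optimises across a ladder of
stress limits, seeding each search from the previous best ("gait morphing"),
and collects the velocity / Froude number / stride length / cycle duration
profile across limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .controller import CyclicController, mirror_name
from .dynamics import Engine, SimConfig, Trajectory
from .model import BipedModel


@dataclass
class GAConfig:
    population: int = 16
    generations: int = 10
    mutation_sigma: float = 0.15
    mutation_rate: float = 0.25
    crossover_rate: float = 0.7
    tournament: int = 3
    elitism: int = 1
    seed: int = 0
    n_phases: int = 8
    cycle_bounds: tuple[float, float] = (0.3, 1.5)
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")


@dataclass
class FitnessResult:
    distance: float
    mean_velocity: float
    termination: str
    termination_time: float
    peak_stress: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.distance = max(0.0, float(self.distance))


@dataclass
class OptimizeResult:
    controller: CyclicController
    fitness: FitnessResult
    trajectory: Trajectory
    log: list[dict] = field(default_factory=list)
    evaluations: int = 0


@dataclass
class SweepRow:
    stress_limit: float
    best_velocity: float
    froude: float
    stride_length: float
    cycle_duration: float
    distance: float
    gait_class: str = ""


@dataclass
class SweepResult:
    rows: list[SweepRow]
    seed: int


def evaluate_fitness(
    engine: Engine | BipedModel,
    controller: CyclicController,
    config: SimConfig | None = None,
    stress_limit: float = np.inf,
    return_trajectory: bool = False,
):
    """Simulate one controller and score it by COM distance at termination."""
    if isinstance(engine, BipedModel):
        engine = Engine(engine, config)
    engine.reset()
    traj = engine.run(controller, stress_limit)
    elapsed = max(float(traj.time[-1]), engine.config.timestep)
    dist = max(0.0, traj.distance)
    peaks = {
        name: float(np.max(np.maximum(np.abs(traj.stress_max_filtered[:, i]),
                                      np.abs(traj.stress_min_filtered[:, i]))))
        for i, name in enumerate(traj.monitor_names)
    }
    fr = FitnessResult(
        distance=dist,
        mean_velocity=dist / elapsed,
        termination=traj.termination.cause,
        termination_time=traj.termination.time,
        peak_stress=peaks,
    )
    return (fr, traj) if return_trajectory else fr


def _controlled_muscles(model: BipedModel, symmetric: bool) -> list[str]:
    names = [m.name for m in model.muscles]
    if not symmetric:
        return sorted(names)
    left = [n for n in names if mirror_name(n) in names]
    return sorted(left) if left else sorted(names)


def morph_seed(
    previous: CyclicController,
    ga: GAConfig,
    rng: np.random.Generator,
    scale: float = 0.1,
) -> np.ndarray:
    """Population seeded from a previous best controller plus bounded noise.

    The first individual is the unperturbed parent; the rest are gaussian
    perturbations clipped to [0, 1].  This is the staged re-optimisation used
    when the stress limit (or any other constraint) changes.
    """
    g0 = previous.to_genome(ga.cycle_bounds)
    pop = np.tile(g0, (ga.population, 1))
    if scale > 0:
        noise = rng.normal(0.0, scale, size=pop.shape)
        noise[0] = 0.0
        pop = np.clip(pop + noise, 0.0, 1.0)
    return pop


def ga_maximize(
    score,
    genome_size: int,
    ga: GAConfig,
    init_population: np.ndarray | None = None,
) -> tuple[np.ndarray, float, list[dict], int]:
    """Generational GA on [0, 1]^n genomes; returns (best, fitness, log, evals).

    Tournament selection, blend crossover, gaussian mutation with clipping and
    elitism; fully deterministic for a fixed seed.
    """
    rng = np.random.default_rng(ga.seed)
    if init_population is not None:
        pop = np.clip(np.asarray(init_population, dtype=float), 0.0, 1.0)
        if pop.shape != (ga.population, genome_size):
            raise ValueError("init_population has the wrong shape")
    else:
        pop = rng.uniform(0.0, 1.0, size=(ga.population, genome_size))
    fit = np.array([score(g) for g in pop])
    n_eval = ga.population
    best_i = int(np.argmax(fit))
    best_genome, best_fit = pop[best_i].copy(), float(fit[best_i])
    log = [{"generation": 0, "best": best_fit, "mean": float(fit.mean()),
            "seed": ga.seed}]

    for gen in range(1, ga.generations + 1):
        order = np.argsort(fit)[::-1]
        elite = pop[order[: ga.elitism]].copy()
        children = list(elite)
        while len(children) < ga.population:
            idx = rng.integers(0, ga.population, size=ga.tournament)
            p1 = pop[idx[np.argmax(fit[idx])]]
            idx = rng.integers(0, ga.population, size=ga.tournament)
            p2 = pop[idx[np.argmax(fit[idx])]]
            if rng.random() < ga.crossover_rate:
                w = rng.uniform(0.0, 1.0, size=genome_size)
                child = w * p1 + (1.0 - w) * p2
            else:
                child = p1.copy()
            mutate = rng.random(genome_size) < ga.mutation_rate
            child = np.where(
                mutate, child + rng.normal(0.0, ga.mutation_sigma, genome_size),
                child,
            )
            children.append(np.clip(child, 0.0, 1.0))
        pop = np.array(children[: ga.population])
        fit = np.array([score(g) for g in pop])
        n_eval += ga.population
        gi = int(np.argmax(fit))
        if fit[gi] > best_fit:
            best_fit, best_genome = float(fit[gi]), pop[gi].copy()
        log.append({"generation": gen, "best": best_fit,
                    "mean": float(fit.mean()), "seed": ga.seed})
    return best_genome, best_fit, log, n_eval


def optimize_controller(
    model: BipedModel,
    ga: GAConfig | None = None,
    sim: SimConfig | None = None,
    stress_limit: float = np.inf,
    warm_start: CyclicController | None = None,
) -> OptimizeResult:
    """Generational GA over cyclic controllers maximising distance travelled.

    Deterministic for a fixed seed.  With a warm start the parent individual
    is injected unperturbed and elitism guarantees the returned best is at
    least as fit as the warm start.
    """
    ga = ga or GAConfig()
    rng = np.random.default_rng(ga.seed)
    muscles = _controlled_muscles(model, ga.symmetric)
    gsize = CyclicController.genome_size(len(muscles), ga.n_phases)
    engine = Engine(model, sim)

    def decode(genome: np.ndarray) -> CyclicController:
        return CyclicController.from_genome(
            genome, muscles, ga.n_phases, ga.cycle_bounds, ga.symmetric
        )

    def score(genome: np.ndarray) -> float:
        return evaluate_fitness(engine, decode(genome), stress_limit=stress_limit).distance

    if warm_start is not None:
        init = morph_seed(warm_start, ga, rng)
    else:
        init = rng.uniform(0.0, 1.0, size=(ga.population, gsize))
        init[:, 1:] *= rng.uniform(0.2, 0.6, size=(ga.population, 1))  # start gentle
    best_genome, best_fit, log, n_eval = ga_maximize(score, gsize, ga, init)
    best_controller = decode(best_genome)
    fitness, traj = evaluate_fitness(
        engine, best_controller, stress_limit=stress_limit, return_trajectory=True
    )
    return OptimizeResult(best_controller, fitness, traj, log, n_eval)


def sweep_stress_limits(
    model: BipedModel,
    limits: list[float],
    ga: GAConfig | None = None,
    sim: SimConfig | None = None,
) -> SweepResult:
    """Optimise at each stress limit, morphing from the next higher limit.

    Limits are processed from the most permissive down, each search seeded
    from the previous optimum, mirroring the staged gait-morphing protocol.
    """
    if len(limits) < 2:
        raise ValueError("need at least two stress limits to sweep")
    ga = ga or GAConfig()
    from .metrics import summarize_gait  # local import to avoid a cycle

    rows: list[SweepRow] = []
    warm = None
    for limit in sorted(limits, reverse=True):
        res = optimize_controller(model, ga, sim, stress_limit=limit, warm_start=warm)
        warm = res.controller
        try:
            summary = summarize_gait(res.trajectory, model)
            stride, cycle = summary.stride_length, summary.cycle_duration
            froude, gait = summary.froude, summary.gait_class
        except ValueError:  # too little locomotion for stride statistics
            stride = cycle = froude = np.nan
            gait = "none"
        rows.append(
            SweepRow(
                stress_limit=limit,
                best_velocity=res.fitness.mean_velocity,
                froude=froude,
                stride_length=stride,
                cycle_duration=cycle,
                distance=res.fitness.distance,
                gait_class=gait,
            )
        )
    rows.sort(key=lambda r: r.stress_limit)
    return SweepResult(rows=rows, seed=ga.seed)
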