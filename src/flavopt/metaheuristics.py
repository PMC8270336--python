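"""Real-coded genetic algorithm and particle swarm optimizer over a box.

Both optimizers maximize an arbitrary objective over coded 4-vectors inside
box bounds, are bit-reproducible for a given seed, never return a point
outside the box, and expose the best-so-far trace (monotone non-decreasing).

Randomness: each run splits its seed into independent streams —
GA: (0) initialization, (1) selection + crossover, (2) mutation;
PSO: (0) initialization, (1) velocity draws — via ``numpy`` SeedSequence
spawn keys, so changing one operator's draw count cannot perturb another.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import DesignTable, decode_point
from .errors import InvalidBoundsError
from .rsm import OptimumResult, absolute_error, fit_quadratic, optimize_on_cube

__all__ = [
    "GaConfig",
    "PsoConfig",
    "ga_maximize",
    "pso_maximize",
    "surrogate_optimize",
    "ValidationReport",
]


@dataclass
class GaConfig:
    population: int = 50
    generations: int = 100
    crossover_rate: float = 0.9
    mutation_sd: float = 0.1       # coded units (fraction of half-range)
    mutation_decay: float = 0.95   # per-generation geometric decay of the sd
    tournament_size: int = 3
    elitism: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if not (0.0 <= self.crossover_rate <= 1.0):
            raise ValueError("crossover_rate must lie in [0, 1]")


@dataclass
class PsoConfig:
    swarm: int = 30
    iterations: int = 100
    inertia: float = 0.729          # constriction-style defaults
    c1: float = 1.49445
    c2: float = 1.49445
    v_max: float = 0.5              # fraction of box width
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm < 2:
            raise ValueError("swarm must be >= 2")
        if not (0.0 < self.inertia <= 1.0):
            raise ValueError("inertia must lie in (0, 1]")


def _check_box(bounds):
    lo = np.asarray(bounds[0], dtype=float)
    hi = np.asarray(bounds[1], dtype=float)
    if lo.shape != hi.shape or np.any(lo >= hi):
        raise InvalidBoundsError(f"empty or malformed box: lo={lo}, hi={hi}")
    return lo, hi


def _stream(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def ga_maximize(objective, bounds, config: GaConfig | None = None) -> OptimumResult:
    """Tournament selection, blend (BLX-0.5) crossover, Gaussian mutation,
    elitist survival; returns the best point ever evaluated."""
    config = config or GaConfig()
    lo, hi = _check_box(bounds)
    dim = len(lo)
    span = hi - lo
    rng_init = _stream(config.seed, 0)
    rng_sel = _stream(config.seed, 1)
    rng_mut = _stream(config.seed, 2)

    pop = rng_init.uniform(lo, hi, size=(config.population, dim))
    fit = np.array([objective(x) for x in pop])
    best_idx = int(np.argmax(fit))
    best_x, best_v = pop[best_idx].copy(), float(fit[best_idx])
    history = [best_v]

    for gen in range(config.generations):
        sd = config.mutation_sd * config.mutation_decay**gen
        order = np.argsort(-fit, kind="stable")
        elites = pop[order[: config.elitism]].copy()
        children = []
        while len(children) < config.population - config.elitism:
            idx1 = rng_sel.integers(0, config.population, size=config.tournament_size)
            idx2 = rng_sel.integers(0, config.population, size=config.tournament_size)
            p1 = pop[idx1[np.argmax(fit[idx1])]]
            p2 = pop[idx2[np.argmax(fit[idx2])]]
            if rng_sel.random() < config.crossover_rate:
                # BLX-0.5: sample uniformly in the interval stretched by 50%
                lo_g = np.minimum(p1, p2)
                hi_g = np.maximum(p1, p2)
                d = hi_g - lo_g
                child = rng_sel.uniform(lo_g - 0.5 * d, hi_g + 0.5 * d)
            else:
                child = p1.copy()
            child = child + rng_mut.normal(0.0, sd * span / 2.0)
            children.append(np.clip(child, lo, hi))
        pop = np.vstack([elites, np.array(children)])
        fit = np.array([objective(x) for x in pop])
        gen_best = int(np.argmax(fit))
        if float(fit[gen_best]) > best_v:
            best_x, best_v = pop[gen_best].copy(), float(fit[gen_best])
        history.append(best_v)

    return OptimumResult(
        coded=best_x,
        natural=best_x.copy(),
        predicted=best_v,
        method="GA",
        history=np.asarray(history),
    )


def pso_maximize(objective, bounds, config: PsoConfig | None = None) -> OptimumResult:
    """Inertia-weight PSO with velocity clamping and position clipping."""
    config = config or PsoConfig()
    lo, hi = _check_box(bounds)
    dim = len(lo)
    span = hi - lo
    vmax = config.v_max * span
    rng_init = _stream(config.seed, 0)
    rng_vel = _stream(config.seed, 1)

    x = rng_init.uniform(lo, hi, size=(config.swarm, dim))
    v = rng_init.uniform(-vmax, vmax, size=(config.swarm, dim))
    fit = np.array([objective(p) for p in x])
    pbest_x, pbest_f = x.copy(), fit.copy()
    g = int(np.argmax(fit))
    gbest_x, gbest_f = x[g].copy(), float(fit[g])
    history = [gbest_f]

    for _ in range(config.iterations):
        r1 = rng_vel.random((config.swarm, dim))
        r2 = rng_vel.random((config.swarm, dim))
        v = (
            config.inertia * v
            + config.c1 * r1 * (pbest_x - x)
            + config.c2 * r2 * (gbest_x - x)
        )
        v = np.clip(v, -vmax, vmax)
        x = np.clip(x + v, lo, hi)
        fit = np.array([objective(p) for p in x])
        improved = fit > pbest_f
        pbest_x[improved] = x[improved]
        pbest_f[improved] = fit[improved]
        g = int(np.argmax(pbest_f))
        if float(pbest_f[g]) > gbest_f:
            gbest_x, gbest_f = pbest_x[g].copy(), float(pbest_f[g])
        history.append(gbest_f)

    return OptimumResult(
        coded=gbest_x,
        natural=gbest_x.copy(),
        predicted=gbest_f,
        method="PSO",
        history=np.asarray(history),
    )


@dataclass
class ValidationReport:
    """One optimum-validation row: conditions, prediction and measured check."""

    optimum: OptimumResult
    surrogate: str
    experiment: float | None = None
    error: float | None = None

    def to_dict(self) -> dict:
        payload = self.optimum.to_dict()
        payload["surrogate"] = self.surrogate
        payload["experiment"] = self.experiment
        payload["absolute_error"] = self.error
        return payload


def surrogate_optimize(
    design: DesignTable,
    surrogate: str = "rsm",
    method: str = "ga",
    ga_config: GaConfig | None = None,
    pso_config: PsoConfig | None = None,
    train_kwargs: dict | None = None,
    validate: float | None = None,
    seed: int = 0,
) -> ValidationReport:
    """Fit/train a surrogate on the design, maximize it, report the optimum.

    ``surrogate`` is ``rsm`` (quadratic refit) or ``ann`` (trained network);
    ``method`` is ``ga``, ``pso`` or ``rsm`` (the deterministic cube
    optimizer).  With a ``validate`` measurement the absolute error against
    the prediction is included, mirroring a published validation row.
    """
    if surrogate == "rsm":
        model = fit_quadratic(design)
        objective = model.predict
    elif surrogate == "ann":
        from .ann import train as ann_train

        kwargs = dict(train_kwargs or {})
        kwargs.setdefault("seed", seed)
        ann_model, _ = ann_train(design, **kwargs)

        def objective(coded):
            return float(ann_model.forward(decode_point(coded, design.factors)))

    else:
        raise ValueError(f"unknown surrogate {surrogate!r}")

    bounds = (-np.ones(4), np.ones(4))
    if method == "ga":
        result = ga_maximize(objective, bounds, ga_config or GaConfig(seed=seed))
    elif method == "pso":
        result = pso_maximize(objective, bounds, pso_config or PsoConfig(seed=seed))
    elif method == "rsm":
        if surrogate == "rsm":
            result = optimize_on_cube(model)
        else:
            result = optimize_on_cube(
                fit_quadratic(design), objective=objective
            )
    else:
        raise ValueError(f"unknown method {method!r}")

    result.natural = decode_point(result.coded, design.factors)
    tag = {"ga": "GA", "pso": "PSO", "rsm": "RSM"}[method]
    result.method = tag
    report = ValidationReport(optimum=result, surrogate=surrogate)
    if validate is not None:
        report.experiment = float(validate)
        report.error = absolute_error(result.predicted, validate)
    return report
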