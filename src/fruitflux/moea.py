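"""Self-contained elitist NSGA-II for real-coded multi-objective problems.

Implements constraint-domination, fast non-dominated sorting, crowding
distance, simulated binary crossover (SBX) and polynomial mutation.  A
problem object exposes ``bounds`` (an (n, 2) array of box constraints) and
``evaluate(x) -> (f, g)`` where ``f`` is the objective vector (minimised)
and ``g`` the constraint-violation vector (entries > 0 mean violated by
that amount; an empty vector means unconstrained).

Everything is deterministic given the configured seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "Individual", "MoeaConfig", "ParetoSolution", "MoeaEvaluationError",
    "dominates", "fast_nondominated_sort", "crowding_distance",
    "sbx_crossover", "polynomial_mutation", "nsga2_run",
]


class MoeaEvaluationError(RuntimeError):
    """Objective evaluation raised; carries the offending decision vector."""

    def __init__(self, x, cause):
        super().__init__(f"evaluation failed at x={np.asarray(x).tolist()}: {cause!r}")
        self.x = np.asarray(x, dtype=float)
        self.cause = cause


@dataclass
class Individual:
    """One candidate solution with its evaluation and sorting metadata."""

    x: np.ndarray
    f: Optional[np.ndarray] = None
    g: Optional[np.ndarray] = None
    rank: int = -1
    crowding: float = 0.0

    @property
    def violation(self) -> float:
        if self.g is None or self.g.size == 0:
            return 0.0
        return float(np.sum(np.maximum(self.g, 0.0)))

    @property
    def feasible(self) -> bool:
        return self.violation <= 0.0


@dataclass
class MoeaConfig:
    """NSGA-II settings (the source publication prints none; these are ours)."""

    pop_size: int = 100
    generations: int = 200
    eta_crossover: float = 15.0
    p_crossover: float = 0.9
    eta_mutation: float = 20.0
    p_mutation: Optional[float] = None  # default 1/dimension
    seed: int = 0

    def __post_init__(self):
        if self.pop_size < 4 or self.pop_size % 2:
            raise ValueError("pop_size must be even and >= 4")


@dataclass
class ParetoSolution:
    """A non-dominated solution in natural units, with provenance."""

    x: np.ndarray
    f: np.ndarray
    g: np.ndarray
    seed: int = 0
    repeat: int = 0

    def to_dict(self) -> dict:
        return {
            "x": np.asarray(self.x).tolist(),
            "f": np.asarray(self.f).tolist(),
            "g": np.asarray(self.g).tolist(),
            "seed": int(self.seed),
            "repeat": int(self.repeat),
        }


def dominates(a: Individual, b: Individual) -> bool:
    """Constraint-domination: feasibility first, then Pareto dominance."""
    va, vb = a.violation, b.violation
    if va <= 0.0 < vb:
        return True
    if vb <= 0.0 < va:
        return False
    if va > 0.0 and vb > 0.0:
        return va < vb
    better_somewhere = False
    for fa, fb in zip(a.f, b.f):
        if fa > fb:
            return False
        if fa < fb:
            better_somewhere = True
    return better_somewhere


def fast_nondominated_sort(pop: Sequence[Individual]) -> list[list[Individual]]:
    """Deb's fast non-dominated sort; sets each individual's rank."""
    n = len(pop)
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    domination_count = [0] * n
    fronts: list[list[int]] = [[]]
    for i in range(n):
        for j in range(i + 1, n):
            if dominates(pop[i], pop[j]):
                dominated_by[i].append(j)
                domination_count[j] += 1
            elif dominates(pop[j], pop[i]):
                dominated_by[j].append(i)
                domination_count[i] += 1
        if domination_count[i] == 0:
            pop[i].rank = 0
            fronts[0].append(i)
    k = 0
    while fronts[k]:
        nxt: list[int] = []
        for i in fronts[k]:
            for j in dominated_by[i]:
                domination_count[j] -= 1
                if domination_count[j] == 0:
                    pop[j].rank = k + 1
                    nxt.append(j)
        k += 1
        fronts.append(nxt)
    return [[pop[i] for i in fr] for fr in fronts[:-1]]


def crowding_distance(front: Sequence[Individual]) -> np.ndarray:
    """Crowding distances; boundary individuals on any objective get +inf."""
    n = len(front)
    if n == 0:
        raise ValueError("front must be non-empty")
    dist = np.zeros(n)
    if n <= 2:
        dist[:] = np.inf
        for ind, d in zip(front, dist):
            ind.crowding = float(d)
        return dist
    fmat = np.array([ind.f for ind in front], dtype=float)
    for m in range(fmat.shape[1]):
        order = np.argsort(fmat[:, m], kind="stable")
        fmin, fmax = fmat[order[0], m], fmat[order[-1], m]
        dist[order[0]] = np.inf
        dist[order[-1]] = np.inf
        span = fmax - fmin
        if span <= 0:
            continue
        for k in range(1, n - 1):
            dist[order[k]] += (fmat[order[k + 1], m] - fmat[order[k - 1], m]) / span
    for ind, d in zip(front, dist):
        ind.crowding = float(d)
    return dist


def sbx_crossover(p1: np.ndarray, p2: np.ndarray, eta_c: float, p_c: float,
                  bounds: np.ndarray, rng: np.random.Generator):
    """Simulated binary crossover; children are clipped to the box bounds."""
    c1 = p1.copy()
    c2 = p2.copy()
    if rng.random() > p_c:
        return c1, c2
    for i in range(p1.size):
        if rng.random() > 0.5 or abs(p1[i] - p2[i]) < 1e-14:
            continue
        u = rng.random()
        if u <= 0.5:
            beta = (2.0 * u) ** (1.0 / (eta_c + 1.0))
        else:
            beta = (1.0 / (2.0 * (1.0 - u))) ** (1.0 / (eta_c + 1.0))
        c1[i] = 0.5 * ((1.0 + beta) * p1[i] + (1.0 - beta) * p2[i])
        c2[i] = 0.5 * ((1.0 - beta) * p1[i] + (1.0 + beta) * p2[i])
    np.clip(c1, bounds[:, 0], bounds[:, 1], out=c1)
    np.clip(c2, bounds[:, 0], bounds[:, 1], out=c2)
    return c1, c2


def polynomial_mutation(x: np.ndarray, eta_m: float, p_m: float,
                        bounds: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Bounded polynomial mutation, one variable at a time with probability p_m."""
    y = x.copy()
    for i in range(x.size):
        if rng.random() > p_m:
            continue
        lo, hi = bounds[i]
        span = hi - lo
        if span <= 0:
            continue
        d1 = (y[i] - lo) / span
        d2 = (hi - y[i]) / span
        u = rng.random()
        mut_pow = 1.0 / (eta_m + 1.0)
        if u < 0.5:
            val = 2.0 * u + (1.0 - 2.0 * u) * (1.0 - d1) ** (eta_m + 1.0)
            dq = val ** mut_pow - 1.0
        else:
            val = 2.0 * (1.0 - u) + 2.0 * (u - 0.5) * (1.0 - d2) ** (eta_m + 1.0)
            dq = 1.0 - val ** mut_pow
        y[i] = min(max(y[i] + dq * span, lo), hi)
    return y


def _evaluate(problem, ind: Individual) -> None:
    try:
        f, g = problem.evaluate(ind.x)
    except Exception as exc:  # noqa: BLE001 - re-raised with the offending x
        raise MoeaEvaluationError(ind.x, exc) from exc
    ind.f = np.asarray(f, dtype=float)
    ind.g = np.asarray(g, dtype=float)
    if not np.all(np.isfinite(ind.f)):
        raise MoeaEvaluationError(ind.x, "non-finite objective value")


def _crowded_better(a: Individual, b: Individual) -> bool:
    if a.rank != b.rank:
        return a.rank < b.rank
    return a.crowding > b.crowding


def _sort_and_rank(pop: list[Individual]) -> list[list[Individual]]:
    fronts = fast_nondominated_sort(pop)
    for front in fronts:
        crowding_distance(front)
    return fronts


def nsga2_run(problem, config: MoeaConfig,
              on_generation: Optional[Callable[[int, list[Individual]], None]] = None):
    """Run the (mu + lambda) NSGA-II loop.

    Returns (population, archive) where archive is the rank-0 front of the
    final population.  ``on_generation(gen, population)`` is called after
    each environmental selection (useful for convergence diagnostics).
    """
    rng = np.random.default_rng(config.seed)
    bounds = np.asarray(problem.bounds, dtype=float)
    dim = bounds.shape[0]
    p_m = config.p_mutation if config.p_mutation is not None else 1.0 / dim

    pop = [Individual(rng.uniform(bounds[:, 0], bounds[:, 1]))
           for _ in range(config.pop_size)]
    for ind in pop:
        _evaluate(problem, ind)
    _sort_and_rank(pop)

    for gen in range(config.generations):
        offspring: list[Individual] = []
        while len(offspring) < config.pop_size:
            parents = []
            for _ in range(2):
                i, j = rng.integers(0, config.pop_size, size=2)
                a, b = pop[int(i)], pop[int(j)]
                parents.append(a if _crowded_better(a, b) else b)
            c1, c2 = sbx_crossover(parents[0].x, parents[1].x,
                                   config.eta_crossover, config.p_crossover,
                                   bounds, rng)
            for cx in (c1, c2):
                child = Individual(polynomial_mutation(cx, config.eta_mutation,
                                                       p_m, bounds, rng))
                _evaluate(problem, child)
                offspring.append(child)
        merged = pop + offspring[:config.pop_size]
        fronts = _sort_and_rank(merged)
        new_pop: list[Individual] = []
        for front in fronts:
            if len(new_pop) + len(front) <= config.pop_size:
                new_pop.extend(front)
            else:
                room = config.pop_size - len(new_pop)
                order = sorted(range(len(front)),
                               key=lambda k: front[k].crowding, reverse=True)
                new_pop.extend(front[k] for k in order[:room])
                break
        pop = new_pop
        _sort_and_rank(pop)
        if on_generation is not None:
            on_generation(gen, pop)

    archive = [ind for ind in pop if ind.rank == 0]
    return pop, archive


def nondominated_subset(solutions: Sequence[ParetoSolution]) -> list[ParetoSolution]:
    """Reduce a merged collection of solutions to its non-dominated subset."""
    pop = [Individual(np.asarray(s.x, float), np.asarray(s.f, float),
                      np.asarray(s.g, float)) for s in solutions]
    fronts = fast_nondominated_sort(pop)
    if not fronts:
        return []
    keep = {id(ind) for ind in fronts[0]}
    return [s for s, ind in zip(solutions, pop) if id(ind) in keep]


def archive_to_json(solutions: Sequence[ParetoSolution], path) -> None:
    with open(path, "w") as fh:
        json.dump([s.to_dict() for s in solutions], fh, indent=1)


def archive_from_json(path) -> list[ParetoSolution]:
    with open(path) as fh:
        raw = json.load(fh)
    return [ParetoSolution(np.array(r["x"]), np.array(r["f"]), np.array(r["g"]),
                           r.get("seed", 0), r.get("repeat", 0)) for r in raw]
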