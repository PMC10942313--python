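"""NSGA-II core: domination, non-dominated sorting, crowding distance,
binary tournament selection, elitist environmental selection, and the
generational loop.

All objectives follow the minimization convention.  The loop doubles the
population each iteration via tournament selection + n-point crossover
(probability 0.9 by default) + mutation (probability 1.0 by default),
evaluates the offspring, and truncates the combined 2N pool back to N by
admitting whole Pareto fronts in order and breaking the last front by
descending crowding distance.

Determinism: a single numpy Generator seeded from the run config drives
every stochastic operator in a fixed order (per offspring pair: tournament
for parent a, tournament for parent b, crossover coin, cut points, then
mutation of each child).  Objective values are cached per unique designed
sequence; the cache cannot change results because evaluators are required
to be deterministic functions of the sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import yaml

from .problem import (
    Candidate,
    DesignProblem,
    Population,
    ValidationError,
    population_to_fasta,
    random_population,
)

__all__ = [
    "FrontPartition",
    "RunConfig",
    "RunHistory",
    "dominates",
    "fast_non_dominated_sort",
    "crowding_distance",
    "binary_tournament",
    "environmental_selection",
    "evolve",
]


@dataclass(frozen=True)
class FrontPartition:
    """Successive Pareto fronts as lists of member indices (front 0 first)."""

    fronts: tuple[tuple[int, ...], ...]

    def rank_of(self) -> np.ndarray:
        """Per-member front rank (front 0 = rank 0)."""
        n = sum(len(f) for f in self.fronts)
        ranks = np.empty(n, dtype=int)
        for r, front in enumerate(self.fronts):
            for i in front:
                ranks[i] = r
        return ranks


@dataclass
class RunConfig:
    """Hyperparameters of one NSGA-II run.

    Defaults follow the benchmark protocol: population 100, 50 iterations,
    crossover probability 0.9, mutation probability 1.0, two-point
    crossover, fully randomized initial population.
    """

    population_size: int = 100
    iterations: int = 50
    mutation_rate: float = 0.3
    crossover_probability: float = 0.9
    mutation_probability: float = 1.0
    n_crossover_points: int = 2
    seed: int = 0
    selector_kind: str = "random"
    proposer_kind: str = "uniform"
    objective_names: tuple[str, ...] = ()

    def validate(self, problem: DesignProblem) -> None:
        for name, p in [
            ("mutation_rate", self.mutation_rate),
            ("crossover_probability", self.crossover_probability),
            ("mutation_probability", self.mutation_probability),
        ]:
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {p}")
        if self.population_size < 1:
            raise ValidationError("population_size must be >= 1")
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")
        if not (1 <= self.n_crossover_points < problem.n_designable):
            raise ValidationError(
                f"n_crossover_points must be in [1, {problem.n_designable - 1}], "
                f"got {self.n_crossover_points}"
            )

    def to_dict(self) -> dict:
        return {
            "population_size": self.population_size,
            "iterations": self.iterations,
            "mutation_rate": self.mutation_rate,
            "crossover_probability": self.crossover_probability,
            "mutation_probability": self.mutation_probability,
            "n_crossover_points": self.n_crossover_points,
            "seed": self.seed,
            "selector_kind": self.selector_kind,
            "proposer_kind": self.proposer_kind,
            "objective_names": list(self.objective_names),
        }


@dataclass
class IterationRecord:
    population: Population
    metrics: dict[str, float]
    rng_state: dict


@dataclass
class RunHistory:
    """Per-iteration record of populations, metrics and rng checkpoints."""

    config: RunConfig
    records: list[IterationRecord] = field(default_factory=list)

    @property
    def final_population(self) -> Population:
        return self.records[-1].population

    def metric_series(self, key: str) -> list[float]:
        return [rec.metrics[key] for rec in self.records]

    def save(self, out_dir: str | Path) -> Path:
        """Serialize to a self-describing run directory.

        Layout: ``population_iter_###.fasta`` per iteration, ``metrics.csv``,
        ``config.yaml`` echo and a JSON ``manifest.json`` whose final rng
        state checkpoint allows exact restart.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metric_keys: list[str] = []
        for rec in self.records:
            for k in rec.metrics:
                if k not in metric_keys:
                    metric_keys.append(k)
        lines = ["iteration," + ",".join(metric_keys)]
        for rec in self.records:
            vals = [repr(rec.metrics[k]) if k in rec.metrics else "" for k in metric_keys]
            lines.append(f"{rec.population.iteration}," + ",".join(vals))
            population_to_fasta(
                rec.population,
                str(out / f"population_iter_{rec.population.iteration:03d}.fasta"),
            )
        (out / "metrics.csv").write_text("\n".join(lines) + "\n")
        (out / "config.yaml").write_text(yaml.safe_dump(self.config.to_dict()))
        manifest = {
            "iterations_completed": len(self.records),
            "seed": self.config.seed,
            "rng_state": _jsonable(self.records[-1].rng_state),
            "snapshots": [
                f"population_iter_{rec.population.iteration:03d}.fasta"
                for rec in self.records
            ],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# domination machinery
# ---------------------------------------------------------------------------

def dominates(a: Sequence[float], b: Sequence[float]) -> bool:
    """True iff a <= b componentwise with strict improvement somewhere."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(
            f"objective vectors of unequal length: {a.shape} vs {b.shape}"
        )
    return bool(np.all(a <= b) and np.any(a < b))


def fast_non_dominated_sort(objectives: np.ndarray) -> FrontPartition:
    """Partition points into successive Pareto fronts (Deb et al. procedure).

    Deterministic for a given input ordering: within each front, indices
    appear in ascending order.
    """
    obj = np.asarray(objectives, dtype=float)
    if obj.ndim != 2 or obj.shape[0] == 0:
        raise ValidationError("objective matrix must be 2-D with >= 1 row")
    n = obj.shape[0]
    # pairwise domination via broadcasting
    le = np.all(obj[:, None, :] <= obj[None, :, :], axis=2)
    lt = np.any(obj[:, None, :] < obj[None, :, :], axis=2)
    dom = le & lt  # dom[i, j]: i dominates j

    n_dominators = dom.sum(axis=0)
    fronts: list[tuple[int, ...]] = []
    current = np.flatnonzero(n_dominators == 0)
    assigned = np.zeros(n, dtype=bool)
    counts = n_dominators.copy()
    while current.size:
        fronts.append(tuple(int(i) for i in current))
        assigned[current] = True
        counts = counts - dom[current].sum(axis=0)
        nxt = np.flatnonzero((counts == 0) & ~assigned)
        current = nxt
    return FrontPartition(tuple(fronts))


def crowding_distance(front_objectives: np.ndarray) -> np.ndarray:
    """Crowding distance of each member of one front.

    Boundary members per objective get infinite distance; interior members
    accumulate the normalized gap between their sorted neighbors.  A zero
    objective range contributes 0 (not NaN).  Ties in objective value are
    resolved by stable sort order.
    """
    obj = np.atleast_2d(np.asarray(front_objectives, dtype=float))
    n, m = obj.shape
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for j in range(m):
        order = np.argsort(obj[:, j], kind="stable")
        vals = obj[order, j]
        rng = vals[-1] - vals[0]
        dist[order[0]] = np.inf
        dist[order[-1]] = np.inf
        if rng > 0:
            gaps = (vals[2:] - vals[:-2]) / rng
            interior = order[1:-1]
            finite = np.isfinite(dist[interior])
            dist[interior[finite]] += gaps[finite]
    return dist


def _ranks_and_distances(objectives: np.ndarray) -> tuple[np.ndarray, np.ndarray, FrontPartition]:
    partition = fast_non_dominated_sort(objectives)
    ranks = partition.rank_of()
    distances = np.empty(objectives.shape[0])
    for front in partition.fronts:
        idx = np.asarray(front, dtype=int)
        distances[idx] = crowding_distance(objectives[idx])
    return ranks, distances, partition


def binary_tournament(ranks: np.ndarray, distances: np.ndarray,
                      rng: np.random.Generator) -> int:
    """Pick one parent: two distinct members uniformly, lower rank wins,
    crowding-distance tiebreak, then a fair coin."""
    n = len(ranks)
    if n == 1:
        return 0
    i, j = rng.choice(n, size=2, replace=False)
    i, j = int(i), int(j)
    if ranks[i] != ranks[j]:
        return i if ranks[i] < ranks[j] else j
    if distances[i] != distances[j]:
        return i if distances[i] > distances[j] else j
    return i if rng.random() < 0.5 else j


def environmental_selection(combined: Population, n: int) -> Population:
    """Elitist truncation of a combined pool down to exactly ``n`` members.

    Whole fronts are admitted in order; the last partially fitting front is
    truncated by descending crowding distance (stable ties).
    """
    if len(combined) < n:
        raise ValidationError(
            f"combined population of size {len(combined)} < target {n}"
        )
    obj = combined.objective_matrix()
    partition = fast_non_dominated_sort(obj)
    chosen: list[int] = []
    for front in partition.fronts:
        if len(chosen) + len(front) <= n:
            chosen.extend(front)
        else:
            idx = np.asarray(front, dtype=int)
            dist = crowding_distance(obj[idx])
            # descending distance, stable within ties
            order = np.argsort(-dist, kind="stable")
            need = n - len(chosen)
            chosen.extend(int(idx[k]) for k in order[:need])
            break
        if len(chosen) == n:
            break
    return Population(
        [combined.members[i] for i in chosen],
        iteration=combined.iteration,
    )


# ---------------------------------------------------------------------------
# generational loop
# ---------------------------------------------------------------------------

BatchEvaluator = Callable[[list[str]], np.ndarray]
"""Contract point for objective evaluation: maps a list of designed-residue
strings to an (n, m) matrix of minimization-scale objective values.
Implementations may evaluate candidates concurrently as long as results are
identical to sequential evaluation (evaluators must be pure per-sequence)."""


def _evaluate(population: Population, evaluator: BatchEvaluator,
              cache: dict[str, tuple[float, ...]],
              objective_names: Sequence[str]) -> Population:
    """Evaluate members through the batch contract, caching per sequence."""
    pending = [c.designed_residues for c in population.members
               if c.designed_residues not in cache]
    # preserve first-seen order, drop duplicates
    seen: dict[str, None] = {}
    for s in pending:
        seen.setdefault(s)
    todo = list(seen)
    if todo:
        values = np.asarray(evaluator(todo), dtype=float)
        if values.ndim != 2 or values.shape[0] != len(todo):
            raise ValidationError(
                f"batch evaluator returned shape {values.shape} for {len(todo)} sequences"
            )
        for seq, row in zip(todo, values):
            for j, v in enumerate(row):
                if not np.isfinite(v):
                    name = objective_names[j] if j < len(objective_names) else f"obj{j}"
                    raise ValidationError(
                        f"evaluator returned non-finite value for candidate "
                        f"{seq!r}, objective {name!r}"
                    )
            cache[seq] = tuple(float(v) for v in row)
    members = [c.with_objectives(cache[c.designed_residues])
               for c in population.members]
    return Population(members, iteration=population.iteration)


def evolve(
    problem: DesignProblem,
    config: RunConfig,
    evaluator: BatchEvaluator,
    mutate_fn: Callable[[Candidate, np.random.Generator], Candidate],
    crossover_fn: Callable[[Candidate, Candidate, np.random.Generator],
                           tuple[Candidate, Candidate]],
    metric_fns: dict[str, Callable[[Population], float]] | None = None,
    resume_from: IterationRecord | None = None,
) -> RunHistory:
    """Run the NSGA-II generational loop.

    ``mutate_fn`` and ``crossover_fn`` close over the configured operators
    (see :mod:`modesign.variation`); ``evaluator`` is the batched objective
    contract.  Per-iteration metrics always include mean objective values
    ("mean_obj<i>"); extra ``metric_fns`` are evaluated on each selected
    population.

    ``resume_from`` restarts from a recorded checkpoint: the population and
    rng state are restored exactly, so a resumed run is bit-identical to
    one that never stopped.
    """
    config.validate(problem)
    rng = np.random.default_rng(config.seed)
    cache: dict[str, tuple[float, ...]] = {}
    names = config.objective_names

    if resume_from is None:
        population = random_population(problem, config.population_size, rng)
        start_iter = 1
    else:
        population = resume_from.population
        rng.bit_generator.state = resume_from.rng_state
        start_iter = resume_from.population.iteration + 1
    population = _evaluate(population, evaluator, cache, names)
    history = RunHistory(config=config)
    n = config.population_size

    for it in range(start_iter, config.iterations + 1):
        obj = population.objective_matrix()
        ranks, distances, _ = _ranks_and_distances(obj)
        offspring: list[Candidate] = []
        while len(offspring) < n:
            ia = binary_tournament(ranks, distances, rng)
            ib = binary_tournament(ranks, distances, rng)
            pa, pb = population.members[ia], population.members[ib]
            if rng.random() < config.crossover_probability:
                ca, cb = crossover_fn(pa, pb, rng)
            else:
                ca, cb = pa, pb
            for child in (ca, cb):
                if len(offspring) >= n:
                    break
                if rng.random() < config.mutation_probability:
                    child = mutate_fn(child, rng)
                offspring.append(child)
        combined = Population(population.members + offspring, iteration=it)
        combined = _evaluate(combined, evaluator, cache, names)
        population = environmental_selection(combined, n)
        metrics = _default_metrics(population)
        if metric_fns:
            for key, fn in metric_fns.items():
                metrics[key] = float(fn(population))
        history.records.append(
            IterationRecord(
                population=population,
                metrics=metrics,
                rng_state=rng.bit_generator.state,
            )
        )
    return history


def _default_metrics(population: Population) -> dict[str, float]:
    obj = population.objective_matrix()
    metrics = {f"mean_obj{j}": float(obj[:, j].mean()) for j in range(obj.shape[1])}
    return metrics
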