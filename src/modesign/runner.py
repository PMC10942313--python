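"""Convenience wiring of the generational loop: builds the configured
operators and per-iteration metrics (population-mean native recovery,
front-0 hypervolume) around :func:`modesign.moea.evolve`."""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .analysis import hypervolume_2d, mean_recovery
from .moea import RunConfig, RunHistory, evolve, fast_non_dominated_sort
from .objectives import ObjectiveSpec, make_batch_evaluator
from .problem import DesignProblem, Population
from .variation import make_crossover, make_mutator

__all__ = ["run_design", "front0_hypervolume"]


def front0_hypervolume(population: Population,
                       reference: Sequence[float]) -> float:
    """Hypervolume of the population's non-dominated front w.r.t. a
    reference point (2-objective populations only)."""
    obj = population.objective_matrix()
    front0 = fast_non_dominated_sort(obj).fronts[0]
    return hypervolume_2d(obj[list(front0)], reference)


def run_design(
    problem: DesignProblem,
    config: RunConfig,
    objective_specs: Sequence[ObjectiveSpec],
    ranker=None,
    map_fn: Callable = map,
    hv_reference: Sequence[float] | None = None,
) -> RunHistory:
    """Run one NSGA-II design simulation.

    Builds the mutation operator from ``config.selector_kind`` /
    ``config.proposer_kind`` (a ``ranked`` selector needs ``ranker``), the
    n-point crossover, and the batched objective evaluator; records mean
    native recovery and, for two-objective runs with ``hv_reference`` set,
    the front-0 hypervolume at every iteration.
    """
    config.objective_names = tuple(spec.name for spec in objective_specs)
    mutator = make_mutator(
        problem,
        mu=config.mutation_rate,
        selector_kind=config.selector_kind,
        proposer_kind=config.proposer_kind,
        ranker=ranker,
    )
    crossover = make_crossover(config.n_crossover_points)
    evaluator = make_batch_evaluator(objective_specs, map_fn=map_fn)

    metric_fns: dict[str, Callable[[Population], float]] = {
        "mean_recovery": lambda pop: mean_recovery(pop, problem),
    }
    if hv_reference is not None and len(objective_specs) == 2:
        ref = tuple(float(v) for v in hv_reference)
        metric_fns["hv_front0"] = lambda pop: front0_hypervolume(pop, ref)

    return evolve(
        problem,
        config,
        evaluator,
        mutate_fn=mutator,
        crossover_fn=crossover,
        metric_fns=metric_fns,
    )
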