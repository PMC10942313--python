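"""Crossover and the two-part mutation operator.

The mutation operator is composed of two exchangeable stages:

* a *position selector* decides which designable positions to redesign —
  either independent Bernoulli(mu) draws per position ("random", with an
  empty outcome replaced by one uniformly random position), or a ranked
  scheme that scores the current full sequence with a per-position ranker
  (e.g. a language-model pseudo-likelihood) and redesigns the
  max(1, Binomial(n, mu)) lowest-scoring positions;
* a *residue proposer* supplies replacement residues for exactly the
  selected positions — uniform sampling over the alphabet, or a registered
  plugin (e.g. an inverse-folding model conditioned on the full sequence
  context).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np

from .problem import (
    Alphabet,
    Candidate,
    DesignProblem,
    ValidationError,
    to_full_sequence,
)

__all__ = [
    "PositionSelection",
    "n_point_crossover",
    "select_positions_random",
    "select_positions_ranked",
    "propose_uniform",
    "mutate",
    "make_mutator",
    "make_crossover",
    "register_proposer",
    "register_ranker",
    "get_proposer",
    "get_ranker",
]


@dataclass(frozen=True)
class PositionSelection:
    """A non-empty subset of designed-string indices chosen for redesign."""

    selected: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.selected:
            raise ValidationError("position selection must be non-empty")

    @property
    def k(self) -> int:
        return len(self.selected)


class PositionRanker(Protocol):
    """Scores a full sequence, one finite score per designable position
    (higher = more native-like), in a single pass with no masking."""

    def __call__(self, full_sequence: str) -> Sequence[float]: ...


class ResidueProposer(Protocol):
    """Proposes replacement residues for exactly the selected positions,
    conditioned on the full spliced sequence context."""

    def __call__(self, full_sequence: str, selection: PositionSelection,
                 rng: np.random.Generator) -> str: ...


def n_point_crossover(parent_a: str, parent_b: str, n: int,
                      rng: np.random.Generator) -> tuple[str, str]:
    """n distinct cut points at the L-1 junctions; segments alternate.

    Children are complementary: child_a takes parent_a's first segment,
    child_b takes parent_b's.
    """
    if len(parent_a) != len(parent_b):
        raise ValidationError("parents must have equal length")
    length = len(parent_a)
    if not (1 <= n < length):
        raise ValidationError(
            f"n_crossover_points must satisfy 1 <= n < {length}, got {n}"
        )
    cuts = np.sort(rng.choice(length - 1, size=n, replace=False)) + 1
    child_a, child_b = [], []
    take_a = True
    prev = 0
    for cut in [*cuts.tolist(), length]:
        seg_a, seg_b = parent_a[prev:cut], parent_b[prev:cut]
        if take_a:
            child_a.append(seg_a)
            child_b.append(seg_b)
        else:
            child_a.append(seg_b)
            child_b.append(seg_a)
        take_a = not take_a
        prev = cut
    return "".join(child_a), "".join(child_b)


def select_positions_random(problem: DesignProblem, mu: float,
                            rng: np.random.Generator) -> PositionSelection:
    """Independent Bernoulli(mu) per designable position; an empty outcome
    is replaced by a single uniformly random position."""
    if not (0.0 <= mu <= 1.0):
        raise ValidationError(f"mutation rate must be in [0, 1], got {mu}")
    n = problem.n_designable
    mask = rng.random(n) < mu
    selected = np.flatnonzero(mask)
    if selected.size == 0:
        selected = np.array([rng.integers(0, n)])
    return PositionSelection(tuple(int(i) for i in selected))


def select_positions_ranked(problem: DesignProblem, candidate: Candidate,
                            ranker: PositionRanker, mu: float,
                            rng: np.random.Generator) -> PositionSelection:
    """Score once with no masking, then redesign the k lowest-scoring
    positions with k = max(1, Binomial(n, mu)).

    Ties are broken by stable ascending sort on (score, position index).
    """
    if not (0.0 <= mu <= 1.0):
        raise ValidationError(f"mutation rate must be in [0, 1], got {mu}")
    n = problem.n_designable
    scores = np.asarray(ranker(to_full_sequence(problem, candidate)), dtype=float)
    if scores.shape != (n,):
        raise ValidationError(
            f"ranker returned {scores.shape}, expected ({n},) scores"
        )
    if not np.all(np.isfinite(scores)):
        raise ValidationError("ranker returned non-finite scores")
    k = max(1, int(rng.binomial(n, mu)))
    order = np.argsort(scores, kind="stable")
    return PositionSelection(tuple(int(i) for i in order[:k]))


def propose_uniform(selection: PositionSelection, alphabet: Alphabet,
                    rng: np.random.Generator) -> str:
    """Independent uniform draw per selected position; the current residue
    may be re-drawn (no rejection)."""
    symbols = alphabet.symbols
    draws = rng.integers(0, len(symbols), size=selection.k)
    return "".join(symbols[i] for i in draws)


def mutate(
    problem: DesignProblem,
    candidate: Candidate,
    selector: Callable[[Candidate, np.random.Generator], PositionSelection],
    proposer: Callable[[str, PositionSelection, np.random.Generator], str],
    rng: np.random.Generator,
) -> Candidate:
    """Apply selector then proposer; only selected positions may change."""
    selection = selector(candidate, rng)
    context = to_full_sequence(problem, candidate)
    replacements = proposer(context, selection, rng)
    if len(replacements) != selection.k:
        raise ValidationError(
            f"proposer returned {len(replacements)} residues for "
            f"{selection.k} selected positions"
        )
    designed = list(candidate.designed_residues)
    for idx, res in zip(selection.selected, replacements):
        if res not in problem.alphabet:
            raise ValidationError(f"proposed residue {res!r} not in alphabet")
        designed[idx] = res
    return Candidate("".join(designed), provenance="mutate")


# ---------------------------------------------------------------------------
# plugin registries and operator factories
# ---------------------------------------------------------------------------

_PROPOSERS: dict[str, ResidueProposer] = {}
_RANKERS: dict[str, PositionRanker] = {}


def register_proposer(name: str, proposer: ResidueProposer) -> None:
    """Register a named residue proposer (e.g. an inverse-folding plugin)."""
    if not callable(proposer):
        raise ValidationError(f"proposer {name!r} is not callable")
    _PROPOSERS[name] = proposer


def register_ranker(name: str, ranker: PositionRanker) -> None:
    """Register a named per-position ranker (e.g. a language-model scorer)."""
    if not callable(ranker):
        raise ValidationError(f"ranker {name!r} is not callable")
    _RANKERS[name] = ranker


def get_proposer(name: str) -> ResidueProposer:
    if name not in _PROPOSERS:
        raise ValidationError(f"no proposer registered under {name!r}")
    return _PROPOSERS[name]


def get_ranker(name: str) -> PositionRanker:
    if name not in _RANKERS:
        raise ValidationError(f"no ranker registered under {name!r}")
    return _RANKERS[name]


def make_mutator(
    problem: DesignProblem,
    mu: float,
    selector_kind: str = "random",
    proposer_kind: str = "uniform",
    ranker: PositionRanker | None = None,
) -> Callable[[Candidate, np.random.Generator], Candidate]:
    """Build the composed mutation operator used by the generational loop.

    ``selector_kind``: ``random`` or ``ranked`` (the latter requires a
    ranker, either passed directly or registered as ``plugin:<name>``).
    ``proposer_kind``: ``uniform`` or ``plugin:<name>``.
    """
    if selector_kind == "random":
        def selector(candidate, rng):
            return select_positions_random(problem, mu, rng)
    elif selector_kind == "ranked" or selector_kind.startswith("ranked:"):
        the_ranker = ranker
        if the_ranker is None:
            if ":" not in selector_kind:
                raise ValidationError(
                    "ranked selector requires a ranker (pass one or use 'ranked:<name>')"
                )
            the_ranker = get_ranker(selector_kind.split(":", 1)[1])

        def selector(candidate, rng):
            return select_positions_ranked(problem, candidate, the_ranker, mu, rng)
    else:
        raise ValidationError(f"unknown selector kind {selector_kind!r}")

    if proposer_kind == "uniform":
        def proposer(context, selection, rng):
            return propose_uniform(selection, problem.alphabet, rng)
    elif proposer_kind.startswith("plugin:"):
        proposer = get_proposer(proposer_kind.split(":", 1)[1])
    else:
        raise ValidationError(f"unknown proposer kind {proposer_kind!r}")

    def mutator(candidate: Candidate, rng: np.random.Generator) -> Candidate:
        return mutate(problem, candidate, selector, proposer, rng)

    return mutator


def make_crossover(n_points: int):
    """Bind the cut-point count into a candidate-level crossover operator."""

    def crossover(parent_a: Candidate, parent_b: Candidate,
                  rng: np.random.Generator) -> tuple[Candidate, Candidate]:
        ca, cb = n_point_crossover(
            parent_a.designed_residues, parent_b.designed_residues, n_points, rng
        )
        return (
            Candidate(ca, provenance="crossover"),
            Candidate(cb, provenance="crossover"),
        )

    return crossover
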