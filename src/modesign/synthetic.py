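"""Enumerable toy design problems and fixture data.

The toy two-state problem emulates the central tension of multistate
design: two conformational states with per-position residue preferences
(surrogate PSSMs), a configurable fraction of *conflicting* positions where
the states' modal residues differ, and small procedurally built backbone
structures.  At the default scale (L=6, A=4: 4096 sequences) the true
Pareto front can be enumerated exhaustively, giving ground truth for the
optimizer with no model weights, database downloads or structure files.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import biotite.structure as struc

from .moea import fast_non_dominated_sort
from .multistate import StateStructure
from .objectives import ObjectiveSpec, StatePSSM, surrogate_composite
from .problem import Alphabet, DesignProblem, ValidationError, make_problem

__all__ = [
    "ToyTwoStateProblem",
    "make_toy_problem",
    "enumerate_pareto_front",
    "make_toy_structures",
    "make_reference_sequence_sets",
]

ENUMERATION_LIMIT = 10 ** 6


@dataclass(frozen=True)
class ToyTwoStateProblem:
    """A two-state design problem with exhaustively enumerable sequence space."""

    problem: DesignProblem
    pssms: tuple[StatePSSM, StatePSSM]
    structures: tuple[StateStructure, StateStructure]
    conflict_positions: tuple[int, ...]  # 0-based designed-string indices
    seed: int

    @property
    def n_sequences(self) -> int:
        return len(self.problem.alphabet) ** self.problem.n_designable

    def objective_specs(self) -> list[ObjectiveSpec]:
        """Two minimization objectives: negated saturating surrogate
        composite per state (range [-1, 0], -1 = state's modal sequence)."""
        return [
            ObjectiveSpec(
                name=f"neg_composite_{pssm.state}",
                state=pssm.state,
                evaluator=(lambda c, p=pssm: -surrogate_composite(c, p)),
            )
            for pssm in self.pssms
        ]

    def consensus_sequence(self) -> str:
        """Modal sequence of the average of the two state PSSMs — the
        compromise sequence used as the toy wild type."""
        mean = (self.pssms[0].probabilities + self.pssms[1].probabilities) / 2.0
        return "".join(self.problem.alphabet.symbols[i] for i in mean.argmax(axis=1))

    def ranker(self):
        """PSSM-backed per-position ranker: score of the current residue is
        its mean log-probability under the two states (higher = more
        native-like), from a single pass over the sequence."""
        problem = self.problem
        log_p = np.log(
            (self.pssms[0].probabilities + self.pssms[1].probabilities) / 2.0
        )
        index = {ch: i for i, ch in enumerate(problem.alphabet.symbols)}

        def rank(full_sequence: str) -> np.ndarray:
            scores = np.empty(problem.n_designable)
            for j, pos in enumerate(problem.designable_positions):
                scores[j] = log_p[j, index[full_sequence[pos - 1]]]
            return scores

        return rank


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def make_toy_problem(L: int = 6, A: int = 4, conflict_fraction: float = 0.5,
                     sharpness: float = 4.0, seed: int = 0,
                     pseudo_count: float = 1e-4) -> ToyTwoStateProblem:
    """Build a deterministic toy two-state problem.

    ``conflict_fraction`` of the L positions (rounded to the nearest count)
    get differing modal residues in the two states; the rest share a mode.
    ``sharpness`` scales random logits before the softmax that produces the
    PSSMs, controlling how peaked the per-position preferences are.
    """
    if L < 2:
        raise ValidationError(f"L must be >= 2, got {L}")
    if not (2 <= A <= 20):
        raise ValidationError(f"A must be in [2, 20], got {A}")
    if not (0.0 <= conflict_fraction <= 1.0):
        raise ValidationError(f"conflict_fraction must be in [0, 1], got {conflict_fraction}")
    if sharpness <= 0:
        raise ValidationError(f"sharpness must be positive, got {sharpness}")

    rng = np.random.default_rng(seed)
    alphabet = Alphabet("ACDEFGHIKLMNPQRSTVWY"[:A])
    n_conflict = int(round(conflict_fraction * L))
    conflict_positions = tuple(sorted(rng.choice(L, size=n_conflict, replace=False).tolist()))

    probs_a = np.empty((L, A))
    probs_b = np.empty((L, A))
    for j in range(L):
        logits = sharpness * rng.normal(size=A)
        base = _softmax(logits)
        mode = int(base.argmax())
        if j in conflict_positions:
            # state B prefers a different residue: swap the modal logit with
            # a uniformly chosen other residue's logit
            other = int(rng.integers(0, A - 1))
            if other >= mode:
                other += 1
            logits_b = logits.copy()
            logits_b[mode], logits_b[other] = logits_b[other], logits_b[mode]
            # sharpen both so the conflicting modes create real tension
            probs_a[j] = base
            probs_b[j] = _softmax(logits_b)
        else:
            probs_a[j] = base
            probs_b[j] = base
    # pseudo-count smoothing keeps log-likelihoods finite for any sequence
    for probs in (probs_a, probs_b):
        probs += pseudo_count
        probs /= probs.sum(axis=1, keepdims=True)

    pssm_a = StatePSSM("alpha", alphabet.symbols, probs_a, pseudo_count)
    pssm_b = StatePSSM("beta", alphabet.symbols, probs_b, pseudo_count)

    # toy wild type = the two-state consensus (compromise) sequence
    mean = (probs_a + probs_b) / 2.0
    reference = "".join(alphabet.symbols[i] for i in mean.argmax(axis=1))
    problem = make_problem(
        reference_sequence=reference,
        designable_positions=range(1, L + 1),
        alphabet=alphabet,
        state_names=("alpha", "beta"),
    )
    struct_a, struct_b = make_toy_structures(max(L, 3), seed=seed)
    return ToyTwoStateProblem(
        problem=problem,
        pssms=(pssm_a, pssm_b),
        structures=(struct_a, struct_b),
        conflict_positions=conflict_positions,
        seed=seed,
    )


def enumerate_pareto_front(toy: ToyTwoStateProblem
                           ) -> tuple[list[str], np.ndarray]:
    """Exhaustively evaluate every sequence on both state objectives and
    return the exact non-dominated set (sequences, objective matrix)."""
    if toy.n_sequences > ENUMERATION_LIMIT:
        raise ValidationError(
            f"enumeration of {toy.n_sequences} sequences exceeds the "
            f"{ENUMERATION_LIMIT} limit"
        )
    symbols = toy.problem.alphabet.symbols
    L = toy.problem.n_designable
    seqs = ["".join(t) for t in itertools.product(symbols, repeat=L)]
    # vectorized surrogate evaluation
    idx = np.array([[symbols.index(ch) for ch in s] for s in seqs])
    cols = np.arange(L)
    obj = np.empty((len(seqs), 2))
    for k, pssm in enumerate(toy.pssms):
        logp = np.log(pssm.probabilities)[cols, idx].mean(axis=1)
        best = np.log(pssm.probabilities.max(axis=1)).mean()
        obj[:, k] = -np.exp(logp - best)
    front0 = fast_non_dominated_sort(obj).fronts[0]
    return [seqs[i] for i in front0], obj[list(front0)]


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------

def make_toy_structures(n_residues: int, geometry: str | None = None,
                        seed: int = 0) -> tuple[StateStructure, StateStructure]:
    """Procedurally built single-chain backbone traces (N, CA, C, O per
    residue) with valid PDB fields.

    If ``geometry`` is None, returns a (helix-like, strand-like) pair —
    the two toy conformational states; otherwise both structures use the
    requested geometry.  Consecutive CA-CA distances are 3.8 +/- 0.1 A.
    """
    if n_residues < 3:
        raise ValidationError(f"need >= 3 residues, got {n_residues}")
    if geometry is None:
        return (
            _build_trace(n_residues, "helix-like", seed, "alpha"),
            _build_trace(n_residues, "strand-like", seed + 1, "beta"),
        )
    return (
        _build_trace(n_residues, geometry, seed, "alpha"),
        _build_trace(n_residues, geometry, seed + 1, "beta"),
    )


def _build_trace(n_residues: int, geometry: str, seed: int,
                 state: str) -> StateStructure:
    rng = np.random.default_rng(seed)
    if geometry == "helix-like":
        # ideal alpha-helix CA parameters: radius 2.3 A, 100 deg/residue,
        # rise 1.5 A -> CA-CA ~3.8 A
        t = np.deg2rad(100.0) * np.arange(n_residues)
        ca = np.stack([2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n_residues)],
                      axis=1)
    elif geometry == "strand-like":
        # extended zigzag: 3.3 A rise with 0.95 A lateral alternation
        # -> CA-CA ~3.8 A
        i = np.arange(n_residues)
        ca = np.stack([3.3 * i, 0.95 * (-1.0) ** i, np.zeros(n_residues)], axis=1)
    else:
        raise ValidationError(
            f"geometry must be 'helix-like' or 'strand-like', got {geometry!r}"
        )
    ca = ca + rng.normal(scale=0.02, size=ca.shape)  # tiny deterministic jitter

    atoms = []
    offsets = {"N": np.array([-0.5, 0.9, 0.0]), "CA": np.zeros(3),
               "C": np.array([0.6, -0.8, 0.3]), "O": np.array([1.2, -1.4, 0.2])}
    for i in range(n_residues):
        for name, off in offsets.items():
            atom = struc.Atom(
                coord=ca[i] + off,
                chain_id="A",
                res_id=i + 1,
                res_name="ALA",
                atom_name=name,
                element=name[0],
                hetero=False,
            )
            atoms.append(atom)
    array = struc.array(atoms)
    return StateStructure(state=state, atoms=array)


# ---------------------------------------------------------------------------
# reference sequence sets
# ---------------------------------------------------------------------------

def make_reference_sequence_sets(
    problem: DesignProblem,
    n_like: int = 50,
    n_unlike: int = 50,
    divergence_like: float = 0.1,
    divergence_unlike: float = 0.7,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Two synthetic reference sets standing in for annotated sequence
    databases: one mutated from the reference at low per-position
    divergence ("like"), one at high divergence ("unlike"); deterministic
    given the seed."""
    for name, d in [("divergence_like", divergence_like),
                    ("divergence_unlike", divergence_unlike)]:
        if not (0.0 <= d < 1.0):
            raise ValidationError(f"{name} must be in [0, 1), got {d}")
    rng = np.random.default_rng(seed)
    reference = problem.reference_designed
    symbols = problem.alphabet.symbols

    def mutate_set(n: int, divergence: float) -> list[str]:
        out = []
        for _ in range(n):
            seq = list(reference)
            mask = rng.random(len(seq)) < divergence
            for j in np.flatnonzero(mask):
                choices = [s for s in symbols if s != seq[j]]
                seq[j] = choices[rng.integers(0, len(choices))]
            out.append("".join(seq))
        return out

    return mutate_set(n_like, divergence_like), mutate_set(n_unlike, divergence_unlike)
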