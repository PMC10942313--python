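"""Design-task data model: alphabet, problem definition, candidates, populations.

A design problem fixes a full-length reference (wild-type) sequence, an
ordered set of 1-based designable positions, the residue alphabet, and the
names of the conformational states under consideration.  Candidates carry
only the designed residues (one character per designable position); the
full-length sequence is obtained by splicing them into the reference
context.  All external interfaces speak 1-based residue numbering, matching
PDB convention.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class ValidationError(ValueError):
    """Raised when a problem/candidate definition violates an invariant."""


@dataclass(frozen=True)
class Alphabet:
    """An ordered residue alphabet; defaults to the 20 standard amino acids."""

    symbols: str = STANDARD_AMINO_ACIDS

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValidationError("alphabet must be non-empty")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValidationError("alphabet symbols must be unique")
        if self.symbols != self.symbols.upper():
            raise ValidationError("alphabet symbols must be uppercase")

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, residue: str) -> bool:
        return residue in self.symbols

    def index(self, residue: str) -> int:
        return self.symbols.index(residue)


@dataclass(frozen=True)
class DesignProblem:
    """Immutable definition of one design task.

    Parameters
    ----------
    reference_sequence:
        Full-length amino-acid string (the wild type).
    designable_positions:
        Unique, sorted 1-based indices into ``reference_sequence``.
    alphabet:
        The residue alphabet candidates draw from.
    state_names:
        Identifiers of the conformational states of the system.
    """

    reference_sequence: str
    designable_positions: tuple[int, ...]
    alphabet: Alphabet = field(default_factory=Alphabet)
    state_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n = len(self.reference_sequence)
        if n == 0:
            raise ValidationError("reference sequence must be non-empty")
        positions = self.designable_positions
        if not positions:
            raise ValidationError("at least one designable position required")
        if list(positions) != sorted(set(positions)):
            raise ValidationError("designable positions must be unique and sorted")
        for p in positions:
            if not (1 <= p <= n):
                raise ValidationError(f"position {p} out of range [1, {n}]")
            residue = self.reference_sequence[p - 1]
            if residue not in self.alphabet:
                raise ValidationError(
                    f"reference residue {residue!r} at designable position {p} "
                    "is not in the alphabet"
                )

    @property
    def n_designable(self) -> int:
        return len(self.designable_positions)

    @property
    def reference_designed(self) -> str:
        """Reference residues restricted to the designable positions."""
        return "".join(self.reference_sequence[p - 1] for p in self.designable_positions)


@dataclass(frozen=True)
class Candidate:
    """A designed sequence over the designable positions.

    Equality and hashing are on ``designed_residues`` only: objective values
    are derived state, so identical sequences dedupe/caches consistently.
    """

    designed_residues: str
    objectives: tuple[float, ...] | None = None
    provenance: str | None = None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Candidate):
            return NotImplemented
        return self.designed_residues == other.designed_residues

    def __hash__(self) -> int:
        return hash(self.designed_residues)

    def with_objectives(self, values: Sequence[float]) -> "Candidate":
        values = tuple(float(v) for v in values)
        if not all(np.isfinite(values)):
            raise ValidationError(
                f"non-finite objective value for candidate {self.designed_residues!r}"
            )
        return Candidate(self.designed_residues, values, self.provenance)


@dataclass
class Population:
    """An ordered collection of candidates at one iteration."""

    members: list[Candidate]
    iteration: int = 0

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def objective_matrix(self) -> np.ndarray:
        """Stack member objective vectors into an (n, m) array."""
        rows = []
        for i, cand in enumerate(self.members):
            if cand.objectives is None:
                raise ValidationError(f"member {i} has no evaluated objectives")
            rows.append(cand.objectives)
        return np.asarray(rows, dtype=float)


def make_problem(
    reference_sequence: str,
    designable_positions: Iterable[int],
    alphabet: Alphabet | str | None = None,
    state_names: Iterable[str] = (),
) -> DesignProblem:
    """Validate and construct a :class:`DesignProblem`.

    Noncanonical residues outside the designable positions are passed
    through verbatim; inside designable positions they are rejected.
    """
    if alphabet is None:
        alphabet = Alphabet()
    elif isinstance(alphabet, str):
        alphabet = Alphabet(alphabet)
    return DesignProblem(
        reference_sequence=str(reference_sequence),
        designable_positions=tuple(int(p) for p in designable_positions),
        alphabet=alphabet,
        state_names=tuple(state_names),
    )


def make_candidate(problem: DesignProblem, designed_residues: str,
                   provenance: str | None = None) -> Candidate:
    """Construct a candidate, validating length and alphabet membership."""
    if len(designed_residues) != problem.n_designable:
        raise ValidationError(
            f"candidate length {len(designed_residues)} != "
            f"{problem.n_designable} designable positions"
        )
    for i, ch in enumerate(designed_residues):
        if ch not in problem.alphabet:
            raise ValidationError(
                f"residue {ch!r} at designed index {i} not in alphabet"
            )
    return Candidate(designed_residues, provenance=provenance)


def random_population(problem: DesignProblem, size: int,
                      rng: np.random.Generator) -> Population:
    """Fully randomized initial population: each designable position drawn
    independently and uniformly from the alphabet."""
    if size < 1:
        raise ValidationError(f"population size must be >= 1, got {size}")
    symbols = np.array(list(problem.alphabet.symbols))
    draws = rng.integers(0, len(symbols), size=(size, problem.n_designable))
    members = [
        Candidate("".join(symbols[row]), provenance="init")
        for row in draws
    ]
    return Population(members, iteration=0)


def to_full_sequence(problem: DesignProblem, candidate: Candidate) -> str:
    """Splice designed residues into the reference context."""
    if len(candidate.designed_residues) != problem.n_designable:
        raise ValidationError(
            f"candidate length {len(candidate.designed_residues)} != "
            f"{problem.n_designable} designable positions"
        )
    seq = list(problem.reference_sequence)
    for pos, res in zip(problem.designable_positions, candidate.designed_residues):
        seq[pos - 1] = res
    return "".join(seq)


def extract_designed(problem: DesignProblem, full_sequence: str) -> str:
    """Inverse of :func:`to_full_sequence`: pull out the designable residues."""
    return "".join(full_sequence[p - 1] for p in problem.designable_positions)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def population_to_fasta(population: Population, handle_or_path) -> None:
    """Write one FASTA record per candidate.

    Headers carry iteration, provenance and objective values as ``key=value``
    pairs, e.g. ``cand_0003 iter=12 provenance=mutate obj0=-0.8 obj1=-0.6``.
    Objective values are on the minimization scale, exactly as evaluated.
    """
    records = []
    for i, cand in enumerate(population.members):
        parts = [f"iter={population.iteration}"]
        if cand.provenance:
            parts.append(f"provenance={cand.provenance}")
        if cand.objectives is not None:
            parts.extend(
                f"obj{j}={v!r}" for j, v in enumerate(cand.objectives)
            )
        rec = SeqRecord(
            Seq(cand.designed_residues),
            id=f"cand_{i:04d}",
            description=" ".join(parts),
        )
        records.append(rec)
    SeqIO.write(records, handle_or_path, "fasta")


def population_from_fasta(handle_or_path) -> Population:
    """Read a population written by :func:`population_to_fasta`."""
    members = []
    iteration = 0
    for rec in SeqIO.parse(handle_or_path, "fasta"):
        fields: dict[str, str] = {}
        for token in rec.description.split()[1:]:
            if "=" not in token:
                raise ValidationError(
                    f"malformed FASTA header token {token!r} in record {rec.id}"
                )
            key, _, value = token.partition("=")
            fields[key] = value
        iteration = int(fields.get("iter", 0))
        obj_keys = sorted(
            (k for k in fields if k.startswith("obj")),
            key=lambda k: int(k[3:]),
        )
        objectives = (
            tuple(float(fields[k]) for k in obj_keys) if obj_keys else None
        )
        members.append(
            Candidate(
                str(rec.seq),
                objectives=objectives,
                provenance=fields.get("provenance"),
            )
        )
    return Population(members, iteration=iteration)


def population_to_csv(population: Population, handle_or_path,
                      objective_names: Sequence[str] | None = None) -> None:
    """Flat CSV export: sequence plus one column per objective."""
    own = isinstance(handle_or_path, (str,)) or hasattr(handle_or_path, "__fspath__")
    handle = open(handle_or_path, "w", newline="") if own else handle_or_path
    try:
        n_obj = 0
        for cand in population.members:
            if cand.objectives is not None:
                n_obj = len(cand.objectives)
                break
        if objective_names is None:
            objective_names = [f"obj{j}" for j in range(n_obj)]
        writer = csv.writer(handle)
        writer.writerow(["sequence", *objective_names])
        for cand in population.members:
            objs = list(cand.objectives) if cand.objectives is not None else []
            writer.writerow([cand.designed_residues, *[repr(v) for v in objs]])
    finally:
        if own:
            handle.close()
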