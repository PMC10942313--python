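"""Objective specification and scorers.

All objectives are framed as minimization: maximization-style scores (the
folding-propensity composite, log-likelihoods) enter the optimizer negated,
never affinely rescaled, so reported values keep their natural units up to
sign.

Three families live here:

* the structure-confidence composite score (mean pLDDT x pTM x TM-score to
  the template, bounded [0, 1]) together with the geometric primitives it
  needs — Kabsch superposition and a fixed-correspondence TM-score;
* desk-scale surrogate scorers built on per-state position-specific scoring
  matrices (PSSMs), used so the whole pipeline is exercisable without any
  neural-network weights;
* plugin contracts for the three neural scorers (inverse-folding state
  log-likelihood, language-model per-position scores, structure-prediction
  composite), registered by name and validated at registration time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .problem import Candidate, DesignProblem, ValidationError

__all__ = [
    "ObjectiveSpec",
    "CompositeScoreInputs",
    "StatePSSM",
    "composite_fold_score",
    "kabsch_superpose",
    "tm_score",
    "pssm_log_likelihood",
    "surrogate_composite",
    "register_scorer",
    "get_scorer",
    "PLUGIN_CONTRACTS",
    "make_batch_evaluator",
]


@dataclass(frozen=True)
class ObjectiveSpec:
    """A named minimization objective bound to one conformational state."""

    name: str
    state: str
    evaluator: Callable[[Candidate], float]

    def __post_init__(self) -> None:
        if not callable(self.evaluator):
            raise ValidationError(f"objective {self.name!r}: evaluator not callable")


@dataclass(frozen=True)
class CompositeScoreInputs:
    """Confidence components of the folding-propensity composite score."""

    mean_plddt: float
    ptm: float
    tm_to_template: float

    def __post_init__(self) -> None:
        for label, v in [
            ("mean_plddt", self.mean_plddt),
            ("ptm", self.ptm),
            ("tm_to_template", self.tm_to_template),
        ]:
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{label} must be in [0, 1], got {v}")


def composite_fold_score(inputs: CompositeScoreInputs) -> float:
    """Product of mean pLDDT (scaled to [0,1]), pTM and the TM-score of the
    predicted structure against the state template; bounded [0, 1], higher =
    greater folding propensity.  As an objective it is negated."""
    return inputs.mean_plddt * inputs.ptm * inputs.tm_to_template


# ---------------------------------------------------------------------------
# rigid-body geometry
# ---------------------------------------------------------------------------

def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``coords_b`` onto ``coords_a``.

    Fixed one-to-one correspondence; returns ``(rotation, translation,
    rmsd)`` with ``rotation @ b + translation ~ a`` and a proper rotation
    (det +1).  Degenerate inputs (fewer than 3 points, or rank-deficient
    point clouds where the optimal rotation is not unique) raise.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValidationError(f"coordinate shapes must match (n, 3): {a.shape} vs {b.shape}")
    if a.shape[0] < 3:
        raise ValidationError("need at least 3 points for superposition")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    # collinear/coincident clouds leave the rotation underdetermined
    if s[1] < 1e-10 * max(s[0], 1e-30):
        raise ValidationError("degenerate point cloud: optimal rotation not unique")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ca - rot @ cb
    diff = (b @ rot.T + trans) - a
    rmsd = float(np.sqrt((diff ** 2).sum() / a.shape[0]))
    return rot, trans, rmsd


def _tm_d0(length: int) -> float:
    """Standard TM-score normalization length, floored at 0.5 A."""
    if length > 15:
        d0 = 1.24 * (length - 15) ** (1.0 / 3.0) - 1.8
    else:
        d0 = 0.5
    return max(d0, 0.5)


def tm_score(coords_model: np.ndarray, coords_reference: np.ndarray,
             max_rounds: int = 20) -> float:
    """TM-score between CA traces with a fixed residue correspondence.

    TM = max over superpositions of (1/L) sum_i 1 / (1 + (d_i/d0)^2), with
    the canonical length-dependent d0 (floored at 0.5 A).  The search seeds
    iterative superposition from contiguous fragments of lengths L, L/2,
    L/4 (minimum 4), refining each by re-superposing on the residues within
    an adaptive distance cutoff until the aligned set is stable.  Value in
    (0, 1]; identical inputs give 1.0.
    """
    model = np.asarray(coords_model, dtype=float)
    ref = np.asarray(coords_reference, dtype=float)
    if model.shape != ref.shape:
        raise ValidationError(
            f"coordinate lists must have equal shape: {model.shape} vs {ref.shape}"
        )
    if model.ndim != 2 or model.shape[1] != 3 or model.shape[0] < 3:
        raise ValidationError("need (L, 3) coordinates with L >= 3")
    length = model.shape[0]
    d0 = _tm_d0(length)

    def score_for(rot: np.ndarray, trans: np.ndarray) -> tuple[float, np.ndarray]:
        moved = model @ rot.T + trans
        d = np.linalg.norm(moved - ref, axis=1)
        return float(np.mean(1.0 / (1.0 + (d / d0) ** 2))), d

    best = 0.0
    if length <= 32:
        # exhaustive contiguous fragment seeds: affordable at this size and
        # guarantees the global fragment-seeded optimum
        frag_lengths = list(range(length, 3, -1))
        stride = lambda frag: 1
    else:
        frag_lengths = sorted({length, max(length // 2, 4), max(length // 4, 4)},
                              reverse=True)
        stride = lambda frag: max(frag // 2, 1)
    for frag in frag_lengths:
        for start in range(0, length - frag + 1, stride(frag)):
            idx = np.arange(start, start + frag)
            if idx.size < 3:
                continue
            try:
                rot, trans, _ = kabsch_superpose(ref[idx], model[idx])
            except ValidationError:
                continue
            sc, d = score_for(rot, trans)
            best = max(best, sc)
            # distance-cutoff refinement
            prev_idx = idx
            for _ in range(max_rounds):
                cutoff = d0 + 1.0
                keep = np.flatnonzero(d < cutoff)
                while keep.size < 3:
                    cutoff += 0.5
                    keep = np.flatnonzero(d < cutoff)
                if keep.size == prev_idx.size and np.array_equal(keep, prev_idx):
                    break
                try:
                    rot, trans, _ = kabsch_superpose(ref[keep], model[keep])
                except ValidationError:
                    break
                sc, d = score_for(rot, trans)
                best = max(best, sc)
                prev_idx = keep
    return best


# ---------------------------------------------------------------------------
# PSSM surrogates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StatePSSM:
    """Per-designable-position residue probabilities for one state.

    A surrogate standing in for a state-conditioned sequence likelihood;
    probabilities include a pseudo-count so every residue has positive mass
    and log-likelihoods stay finite.
    """

    state: str
    alphabet: str
    probabilities: np.ndarray  # (n_positions, len(alphabet))
    pseudo_count: float = 1e-4

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 2 or p.shape[1] != len(self.alphabet):
            raise ValidationError(
                f"probability matrix shape {p.shape} does not match alphabet "
                f"size {len(self.alphabet)}"
            )
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("each position's probabilities must sum to 1")
        if np.any(p <= 0):
            raise ValidationError("probabilities must be strictly positive")
        object.__setattr__(self, "probabilities", p)

    @property
    def n_positions(self) -> int:
        return self.probabilities.shape[0]

    def modal_sequence(self) -> str:
        return "".join(self.alphabet[i] for i in self.probabilities.argmax(axis=1))

    def _indices(self, designed: str) -> np.ndarray:
        if len(designed) != self.n_positions:
            raise ValidationError(
                f"sequence length {len(designed)} != {self.n_positions} positions"
            )
        try:
            return np.array([self.alphabet.index(ch) for ch in designed])
        except ValueError as exc:
            raise ValidationError(f"residue not in PSSM alphabet: {exc}") from exc


def pssm_log_likelihood(candidate: Candidate | str, pssm: StatePSSM) -> float:
    """Mean over positions of ln p(residue | position).

    The corresponding objective value is the *negation* of this quantity
    (a negative log-likelihood, lower = better fit to the state).
    """
    designed = candidate.designed_residues if isinstance(candidate, Candidate) else candidate
    idx = pssm._indices(designed)
    logp = np.log(pssm.probabilities[np.arange(len(idx)), idx])
    return float(logp.mean())


def surrogate_composite(candidate: Candidate | str, pssm: StatePSSM) -> float:
    """Bounded, saturating surrogate with the range of the composite fold
    score: exp(mean log-likelihood - max attainable mean log-likelihood).

    1.0 for the PSSM's modal sequence, in (0, 1] otherwise.  The form is
    chosen purely so tests exercise a [0, 1]-bounded objective; it makes no
    biophysical claim.  As an objective it is negated.
    """
    designed = candidate.designed_residues if isinstance(candidate, Candidate) else candidate
    best = float(np.log(pssm.probabilities.max(axis=1)).mean())
    return float(np.exp(pssm_log_likelihood(designed, pssm) - best))


# ---------------------------------------------------------------------------
# plugin contracts
# ---------------------------------------------------------------------------

PLUGIN_CONTRACTS: dict[str, dict] = {
    # Inverse-folding state score: negative log likelihood of the full
    # sequence given one state's backbone, averaged over 5 scoring repeats.
    "pmpnn_sd_score": {
        "inputs": ("full_sequence", "state_structure"),
        "output": "one finite real (negative log likelihood, averaged over repeats)",
        "hyperparameters": {"temperature": 0.3, "score_repeats": 5},
        "determinism": "single value, deterministic given the plugin's seed",
        "arity": 2,
    },
    # Language-model per-position scores from a single forward pass with no
    # masking; higher = more native-like.
    "esm_position_scores": {
        "inputs": ("full_sequence",),
        "output": "one finite real per designable position",
        "hyperparameters": {"masking": "none", "passes": 1},
        "determinism": "deterministic given the sequence",
        "arity": 1,
    },
    # Structure-prediction composite score: the state backbone is supplied
    # as a template with its sequence replaced by gap tokens, sidechain
    # atoms deleted and glycine CB imputed; prediction runs with 1 recycle
    # and no multiple sequence alignment.
    "af2rank_score": {
        "inputs": ("full_sequence", "state_structure"),
        "output": "composite score in [0, 1] (mean pLDDT x pTM x TM-score)",
        "hyperparameters": {
            "recycles": 1,
            "template_sequence": "gap tokens",
            "template_sidechains": "deleted",
            "glycine_cb": "imputed",
            "msa": None,
        },
        "determinism": "deterministic given the sequence and state",
        "arity": 2,
    },
}

_SCORERS: dict[str, Callable] = {}


def register_scorer(contract: str, fn: Callable, name: str | None = None) -> None:
    """Register a plugin scorer under one of the declared contracts.

    Arity is checked at registration; a missing plugin at run time is a
    configuration error raised before any evaluation starts.
    """
    if contract not in PLUGIN_CONTRACTS:
        raise ValidationError(
            f"unknown plugin contract {contract!r}; known: {sorted(PLUGIN_CONTRACTS)}"
        )
    if not callable(fn):
        raise ValidationError(f"plugin for {contract!r} is not callable")
    import inspect

    n_params = len([
        p for p in inspect.signature(fn).parameters.values()
        if p.kind in (p.POSITIONAL_ONLY, p.POSITIONAL_OR_KEYWORD)
        and p.default is p.empty
    ])
    expected = PLUGIN_CONTRACTS[contract]["arity"]
    if n_params != expected:
        raise ValidationError(
            f"plugin for {contract!r} takes {n_params} required arguments, "
            f"contract requires {expected}"
        )
    _SCORERS[name or contract] = fn


def get_scorer(name: str) -> Callable:
    if name not in _SCORERS:
        raise ValidationError(f"no plugin scorer registered under {name!r}")
    return _SCORERS[name]


# ---------------------------------------------------------------------------
# batched evaluation
# ---------------------------------------------------------------------------

def make_batch_evaluator(specs: Sequence[ObjectiveSpec],
                         map_fn: Callable = map) -> Callable[[list[str]], np.ndarray]:
    """Bundle per-candidate objective evaluators into the batch contract
    used by the generational loop.

    ``map_fn`` is the parallel-evaluation hook: any order-preserving map
    (e.g. a process-pool map) may be substituted, and must give results
    identical to the builtin ``map``.
    """
    if not specs:
        raise ValidationError("at least one objective required")

    def evaluate(sequences: list[str]) -> np.ndarray:
        def row(seq: str) -> list[float]:
            return [float(spec.evaluator(Candidate(seq))) for spec in specs]

        return np.asarray(list(map_fn(row, sequences)), dtype=float)

    return evaluate
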