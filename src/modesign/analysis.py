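"""Evaluation metrics and post hoc procedures for designed-sequence
populations: native-sequence recovery, per-position entropy, 2-D
hypervolume, normalized substitution-matrix similarity, spectral
(Laplacian-eigenmaps) embedding, post hoc non-dominated filtering,
alignment trimming against a reference region, percentile similarity to an
annotated sequence set, and profile-matrix (logo) export.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .moea import fast_non_dominated_sort
from .problem import Candidate, DesignProblem, Population, ValidationError

__all__ = [
    "native_recovery",
    "mean_recovery",
    "positional_entropy",
    "entropy_ecdf",
    "hypervolume_2d",
    "blosum_similarity",
    "similarity_matrix",
    "spectral_embed",
    "posthoc_nondominated_filter",
    "trim_alignment_to_reference",
    "percentile_similarity_to_set",
    "profile_matrix",
]

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def native_recovery(candidate: Candidate | str, problem: DesignProblem) -> float:
    """Fraction of designable positions identical to the wild-type residue."""
    designed = candidate.designed_residues if isinstance(candidate, Candidate) else candidate
    reference = problem.reference_designed
    if len(designed) != len(reference):
        raise ValidationError(
            f"candidate length {len(designed)} != {len(reference)} designable positions"
        )
    matches = sum(a == b for a, b in zip(designed, reference))
    return matches / len(reference)


def mean_recovery(population: Population, problem: DesignProblem) -> float:
    """Population-average native sequence recovery."""
    return float(np.mean([native_recovery(c, problem) for c in population.members]))


def positional_entropy(population: Population | Sequence[str]) -> np.ndarray:
    """Shannon entropy (base e) of the empirical residue distribution at
    each designed position."""
    seqs = [c.designed_residues if isinstance(c, Candidate) else c
            for c in (population.members if isinstance(population, Population) else population)]
    if not seqs:
        raise ValidationError("empty population")
    length = len(seqs[0])
    entropies = np.zeros(length)
    for j in range(length):
        column = [s[j] for s in seqs]
        _, counts = np.unique(column, return_counts=True)
        p = counts / counts.sum()
        entropies[j] = float(-(p * np.log(p)).sum()) + 0.0  # avoid -0.0
    return entropies


def entropy_ecdf(entropies: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF of per-position entropies: (sorted values, cumulative
    fractions)."""
    vals = np.sort(np.asarray(entropies, dtype=float))
    fracs = np.arange(1, len(vals) + 1) / len(vals)
    return vals, fracs


def hypervolume_2d(points: np.ndarray, reference: Sequence[float]) -> float:
    """Exact 2-D hypervolume (minimization) of a point set w.r.t. a
    reference point.

    Only points that dominate the reference contribute; dominated and
    out-of-bounds points contribute nothing.  Computed by sorting the
    non-dominated contributing subset by the first coordinate and summing
    rectangle areas to the reference.  Inputs with more than two objectives
    are rejected: higher-dimensional hypervolume is out of scope.
    """
    ref = np.asarray(reference, dtype=float)
    if ref.shape != (2,) or not np.all(np.isfinite(ref)):
        raise ValidationError(f"reference must be a finite 2-vector, got {reference!r}")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        return 0.0
    if pts.shape[1] != 2:
        raise ValidationError(
            f"hypervolume supports 2-D points only, got dimension {pts.shape[1]}"
        )
    # keep points strictly inside the reference box (dominating the reference)
    inside = pts[np.all(pts < ref, axis=1)]
    if inside.size == 0:
        return 0.0
    # non-dominated subset: sort by x ascending (stable), then keep points
    # with strictly decreasing y
    order = np.lexsort((inside[:, 1], inside[:, 0]))
    hv = 0.0
    best_y = ref[1]
    for i in order:
        x, y = inside[i]
        if y < best_y:
            hv += (ref[0] - x) * (best_y - y)
            best_y = y
    return float(hv)


def _pair_score(a: str, b: str) -> float:
    try:
        return float(_BLOSUM62[a, b])
    except (KeyError, IndexError):
        raise ValidationError(
            f"residue pair ({a!r}, {b!r}) absent from BLOSUM62"
        ) from None


def blosum_similarity(seq_a: str, seq_b: str) -> float:
    """Normalized mean per-position BLOSUM62 similarity.

    Each per-position score s(a, b) is divided by sqrt(s(a,a) * s(b,b))
    before averaging, so self-similarity is exactly 1 and the measure is
    symmetric.  (Absolute values under other normalization conventions
    differ; this convention is fixed and documented here.)
    """
    if len(seq_a) != len(seq_b):
        raise ValidationError(
            f"sequences of unequal length: {len(seq_a)} vs {len(seq_b)}"
        )
    if not seq_a:
        raise ValidationError("empty sequences")
    scores = [
        _pair_score(a, b) / np.sqrt(_pair_score(a, a) * _pair_score(b, b))
        for a, b in zip(seq_a, seq_b)
    ]
    return float(np.mean(scores))


def similarity_matrix(sequences: Sequence[str]) -> np.ndarray:
    """Square symmetric normalized-similarity matrix with unit diagonal."""
    n = len(sequences)
    mat = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = blosum_similarity(sequences[i], sequences[j])
            mat[i, j] = mat[j, i] = s
    return mat


def spectral_embed(affinity: np.ndarray, dims: int = 2) -> np.ndarray:
    """Laplacian-eigenmaps embedding from a precomputed affinity matrix.

    Affinities are min-max shifted to [0, 1] (substitution-based
    similarities can be negative), the symmetric normalized graph Laplacian
    is formed, and the first ``dims`` nontrivial eigenvectors are returned.
    Deterministic; each eigenvector's sign is fixed by making its
    largest-magnitude entry positive.
    """
    from scipy.linalg import eigh

    a = np.asarray(affinity, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError(f"affinity must be square, got {a.shape}")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValidationError("affinity matrix must be symmetric")
    n = a.shape[0]
    if not (1 <= dims < n):
        raise ValidationError(f"dims must be in [1, {n - 1}], got {dims}")
    lo, hi = a.min(), a.max()
    w = (a - lo) / (hi - lo) if hi > lo else np.ones_like(a)
    w = (w + w.T) / 2.0  # keep exact symmetry after the shift
    deg = w.sum(axis=1)
    if np.any(deg <= 0):
        raise ValidationError("affinity matrix has an isolated (zero-degree) node")
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    lap = np.eye(n) - (w * d_inv_sqrt[:, None]) * d_inv_sqrt[None, :]
    vals, vecs = eigh(lap)
    # skip the trivial eigenvector (eigenvalue ~0); take the next `dims`
    coords = vecs[:, 1:1 + dims]
    for j in range(coords.shape[1]):
        k = np.argmax(np.abs(coords[:, j]))
        if coords[k, j] < 0:
            coords[:, j] = -coords[:, j]
    return coords


def posthoc_nondominated_filter(population: Population) -> Population:
    """Front 0 of non-dominated sorting over the population's objectives;
    idempotent."""
    obj = population.objective_matrix()
    front0 = fast_non_dominated_sort(obj).fronts[0]
    return Population(
        [population.members[i] for i in front0],
        iteration=population.iteration,
    )


def trim_alignment_to_reference(
    aligned: dict[str, str] | Sequence[tuple[str, str]],
    reference_id: str,
    problem: DesignProblem,
) -> tuple[dict[str, str], dict[str, int]]:
    """Extract the designable-region columns from an aligned sequence set.

    The reference row's non-gap columns are indexed against the reference
    sequence; the alignment columns carrying the designable positions are
    extracted for every row, and any row whose extracted region contains a
    gap is discarded.  Returns (retained trimmed sequences, counts dict
    with keys 'retained' and 'dropped').
    """
    items = dict(aligned)
    if reference_id not in items:
        raise ValidationError(f"reference row {reference_id!r} absent from alignment")
    ref_row = items[reference_id]
    # alignment column index for each 1-based reference position
    col_of: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(ref_row):
        if ch != "-":
            pos += 1
            col_of[pos] = col
    missing = [p for p in problem.designable_positions if p not in col_of]
    if missing:
        raise ValidationError(
            f"reference row does not cover designable positions {missing}"
        )
    cols = [col_of[p] for p in problem.designable_positions]
    retained: dict[str, str] = {}
    dropped = 0
    for name, row in items.items():
        if len(row) != len(ref_row):
            raise ValidationError(
                f"row {name!r} has length {len(row)} != alignment width {len(ref_row)}"
            )
        region = "".join(row[c] for c in cols)
        if "-" in region:
            dropped += 1
        else:
            retained[name] = region
    return retained, {"retained": len(retained), "dropped": dropped}


def percentile_similarity_to_set(candidate: Candidate | str,
                                 reference_set: Sequence[str],
                                 q: float = 95.0) -> float:
    """q-th percentile (default 95) of normalized BLOSUM62 similarity
    between a designed sequence and every member of a reference set.

    Percentile convention: linear interpolation between closest ranks
    (numpy's default).
    """
    if not reference_set:
        raise ValidationError("reference set must be non-empty")
    if not (0.0 < q <= 100.0):
        raise ValidationError(f"percentile q must be in (0, 100], got {q}")
    designed = candidate.designed_residues if isinstance(candidate, Candidate) else candidate
    sims = [blosum_similarity(designed, ref) for ref in reference_set]
    return float(np.percentile(sims, q))


def profile_matrix(population: Population | Sequence[str],
                   alphabet: str | None = None) -> pd.DataFrame:
    """Per-position residue frequency table (rows = positions, columns =
    residues, rows sum to 1) — the matrix form behind sequence-logo plots."""
    seqs = [c.designed_residues if isinstance(c, Candidate) else c
            for c in (population.members if isinstance(population, Population) else population)]
    if not seqs:
        raise ValidationError("empty population")
    length = len(seqs[0])
    if alphabet is None:
        alphabet = "".join(sorted({ch for s in seqs for ch in s}))
    table = np.zeros((length, len(alphabet)))
    index = {ch: i for i, ch in enumerate(alphabet)}
    for s in seqs:
        for j, ch in enumerate(s):
            table[j, index[ch]] += 1
    table /= len(seqs)
    return pd.DataFrame(table, columns=list(alphabet),
                        index=pd.RangeIndex(1, length + 1, name="position"))
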