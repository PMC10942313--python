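"""Combined-structure construction for tied multi-state sequence decoding.

Inverse-folding models that design one sequence against several
conformational states at once can be fed a single merged structure in which
the states are translated far enough apart that no inter-state atom pair
falls within the model's encodable distance range; the designable positions
of the different states are then tied together during decoding.  The
separation rule is

    r_ij >= 2 * max(r_i_max, r_j_max) + r_min

where r_i_max is the maximum distance between the centroid of structure i
(over CA atoms) and its CA atoms, and r_min defaults to 24 A.  Placement is
collinear along +x in state order, which is deterministic and satisfies
every pairwise constraint.  The layout additionally pads offsets with the
all-atom radius whenever a non-CA atom lies farther from the centroid than
any CA, so the separation guarantee holds at the atom level, not just for
the CA trace.

PDB reading/writing is backed by biotite; HETATM records (waters, ligands)
are dropped on read, and gaps in residue numbering (unmodeled loops) are
preserved as-is.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .problem import DesignProblem, ValidationError

__all__ = [
    "StateStructure",
    "LayoutSpec",
    "TieMap",
    "read_pdb",
    "write_pdb",
    "max_centroid_radius",
    "layout_offsets",
    "combine_structures",
]

DEFAULT_R_MIN = 24.0


@dataclass
class StateStructure:
    """One state's backbone structure plus its designable-residue map."""

    state: str
    atoms: struc.AtomArray
    designable_map: dict[int, tuple[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.atoms.coord)):
            raise ValidationError(f"state {self.state!r}: non-finite coordinates")
        residues = set(zip(self.atoms.chain_id.tolist(), self.atoms.res_id.tolist()))
        for pos, (chain, resnum) in self.designable_map.items():
            if (chain, resnum) not in residues:
                raise ValidationError(
                    f"state {self.state!r}: designable position {pos} maps to "
                    f"missing residue (chain {chain!r}, residue {resnum})"
                )

    @property
    def ca_coords(self) -> np.ndarray:
        mask = self.atoms.atom_name == "CA"
        if not mask.any():
            raise ValidationError(f"state {self.state!r} has no CA atoms")
        return self.atoms.coord[mask]

    def translated(self, offset: np.ndarray) -> "StateStructure":
        atoms = self.atoms.copy()
        atoms.coord = atoms.coord + np.asarray(offset, dtype=float)
        return StateStructure(self.state, atoms, dict(self.designable_map))


@dataclass(frozen=True)
class LayoutSpec:
    """Per-state translation vectors satisfying the pairwise separation rule."""

    r_min: float
    offsets: tuple[tuple[float, float, float], ...]


class TieMap(dict):
    """designable position -> [(state, chain, residue number), ...]."""

    def to_json(self) -> str:
        return json.dumps(
            {str(pos): [[s, c, r] for s, c, r in ties] for pos, ties in sorted(self.items())},
            indent=2,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _prevalidate_pdb(path: str | Path) -> None:
    """Scan ATOM records for malformed fixed-width fields, reporting the
    offending line number (biotite's own errors do not carry it)."""
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.startswith("ATOM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ValidationError(f"{path}: malformed ATOM line {lineno} (too short)")
            try:
                int(line[22:26])
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except ValueError:
                raise ValidationError(
                    f"{path}: malformed ATOM line {lineno} (unparseable field)"
                ) from None


def read_pdb(path: str | Path, state: str | None = None,
             designable_map: dict[int, tuple[str, int]] | None = None) -> StateStructure:
    """Read one state's structure from a PDB file.

    HETATM records (including waters) are ignored.  Duplicate
    (chain, residue, atom) records raise.  Gaps in residue numbering are
    accepted and preserved.
    """
    path = Path(path)
    _prevalidate_pdb(path)
    atoms = PDBFile.read(str(path)).get_structure(model=1)
    atoms = atoms[~atoms.hetero]
    if atoms.array_length() == 0:
        raise ValidationError(f"{path}: no ATOM records")
    keys = list(zip(atoms.chain_id.tolist(), atoms.res_id.tolist(),
                    atoms.atom_name.tolist()))
    seen: set = set()
    for key in keys:
        if key in seen:
            raise ValidationError(
                f"{path}: duplicate atom record (chain, residue, atom) = {key}"
            )
        seen.add(key)
    return StateStructure(
        state=state or path.stem,
        atoms=atoms,
        designable_map=designable_map or {},
    )


def write_pdb(structures: StateStructure | list[StateStructure],
              path: str | Path, layout: LayoutSpec | None = None) -> None:
    """Write one or more states to a PDB file, optionally translating each
    by its layout offset.  Coordinates keep PDB precision (3 decimals)."""
    if isinstance(structures, StateStructure):
        structures = [structures]
    if layout is not None:
        if len(layout.offsets) != len(structures):
            raise ValidationError(
                f"layout has {len(layout.offsets)} offsets for "
                f"{len(structures)} structures"
            )
        structures = [
            s.translated(np.asarray(off)) for s, off in zip(structures, layout.offsets)
        ]
    merged = structures[0].atoms
    for s in structures[1:]:
        merged = merged + s.atoms
    pdb_file = PDBFile()
    pdb_file.set_structure(merged)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def max_centroid_radius(structure: StateStructure) -> float:
    """Maximum distance from the CA centroid to any CA atom."""
    ca = structure.ca_coords
    centroid = ca.mean(axis=0)
    return float(np.linalg.norm(ca - centroid, axis=1).max())


def _all_atom_radius(structure: StateStructure) -> float:
    """Maximum distance from the CA centroid to ANY atom (>= CA radius)."""
    centroid = structure.ca_coords.mean(axis=0)
    return float(np.linalg.norm(structure.atoms.coord - centroid, axis=1).max())


def layout_offsets(radii: list[float], r_min: float = DEFAULT_R_MIN) -> LayoutSpec:
    """Collinear placement along +x satisfying, for every pair (i, j),
    centroid separation >= 2 * max(r_i, r_j) + r_min."""
    if r_min <= 0:
        raise ValidationError(f"r_min must be positive, got {r_min}")
    if any(r < 0 for r in radii):
        raise ValidationError("radii must be non-negative")
    xs: list[float] = []
    for i, r_i in enumerate(radii):
        if i == 0:
            xs.append(0.0)
            continue
        x = max(
            xs[j] + 2.0 * max(r_i, radii[j]) + r_min
            for j in range(i)
        )
        xs.append(x)
    return LayoutSpec(
        r_min=r_min,
        offsets=tuple((x, 0.0, 0.0) for x in xs),
    )


_CHAIN_POOL = string.ascii_uppercase + string.ascii_lowercase + string.digits


def combine_structures(states: list[StateStructure], problem: DesignProblem,
                       r_min: float = DEFAULT_R_MIN
                       ) -> tuple[StateStructure, TieMap]:
    """Merge translated copies of the states into one structure with unique
    chain ids, and emit the map tying each designable position across states.

    Each state's designable map must cover every designable position of the
    problem.  The translation-only layout guarantees a minimum inter-state
    atom distance of at least ``r_min`` and preserves intra-state geometry
    exactly.
    """
    if not states:
        raise ValidationError("at least one state required")
    for s in states:
        missing = [p for p in problem.designable_positions if p not in s.designable_map]
        if missing:
            raise ValidationError(
                f"state {s.state!r} designable map misses positions {missing}"
            )

    # pad with the all-atom radius so the guarantee is atom-level, then
    # re-center each state on its CA centroid before offsetting
    radii = [max(max_centroid_radius(s), _all_atom_radius(s)) for s in states]
    layout = layout_offsets(radii, r_min)

    used_chains: set[str] = set()
    merged_atoms = None
    tie_map = TieMap()
    for s, off in zip(states, layout.offsets):
        centroid = s.ca_coords.mean(axis=0)
        moved = s.translated(np.asarray(off) - centroid)
        rename: dict[str, str] = {}
        for chain in np.unique(moved.atoms.chain_id):
            chain = str(chain)
            if chain not in used_chains:
                rename[chain] = chain
            else:
                pool = [c for c in _CHAIN_POOL if c not in used_chains]
                if not pool:
                    raise ValidationError("chain-id pool exhausted during merge")
                rename[chain] = pool[0]
            used_chains.add(rename[chain])
        atoms = moved.atoms.copy()
        atoms.chain_id = np.array([rename[str(c)] for c in atoms.chain_id])
        for pos, (chain, resnum) in s.designable_map.items():
            tie_map.setdefault(pos, []).append((s.state, rename[chain], resnum))
        merged_atoms = atoms if merged_atoms is None else merged_atoms + atoms

    combined = StateStructure(state="combined", atoms=merged_atoms)
    return combined, tie_map


def default_designable_map(structure: StateStructure,
                           problem: DesignProblem) -> dict[int, tuple[str, int]]:
    """Map each designable position to the (single) chain residue with the
    same residue number — the common case where PDB numbering matches the
    reference sequence numbering."""
    mapping: dict[int, tuple[str, int]] = {}
    res_ids = set(structure.atoms.res_id.tolist())
    for pos in problem.designable_positions:
        if pos not in res_ids:
            raise ValidationError(
                f"state {structure.state!r}: no residue numbered {pos}"
            )
        chain = str(structure.atoms.chain_id[structure.atoms.res_id == pos][0])
        mapping[pos] = (chain, pos)
    return mapping
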