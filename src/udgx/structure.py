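"""PDB geometry: atom distances, Kabsch superposition, C-alpha RMSD.

Parsing goes through gemmi; the package keeps a flat, immutable atom list
(one atom per (chain, residue, atom name) after alternate-location
resolution) because every downstream operation is a selection plus a bit of
linear algebra.  The Kabsch algorithm (closed-form least-squares rigid
superposition via SVD, proper rotations only) is implemented here and
cross-checked in the test suite against an independent rotation-alignment
routine.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np

from .exceptions import (
    AtomSelectionError,
    InsufficientDataError,
    StructureFormatError,
)

__all__ = [
    "Atom",
    "Structure",
    "SuperpositionResult",
    "CaRmsdResult",
    "read_structure",
    "write_structure",
    "parse_selector",
    "atom_distance",
    "kabsch_superpose",
    "ca_rmsd",
]


@dataclass(frozen=True)
class Atom:
    chain: str
    residue_number: int
    residue_name: str
    name: str
    xyz: tuple[float, float, float]
    altloc: str = ""
    occupancy: float = 1.0
    element: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.residue_number, self.name)


@dataclass(frozen=True)
class Structure:
    """A flat list of atoms from one model of a coordinate file."""

    atoms: tuple[Atom, ...]
    model_id: str = "1"

    def __post_init__(self) -> None:
        keys = [(a.chain, a.residue_number, a.name, a.altloc) for a in self.atoms]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})[:5]
            raise StructureFormatError(f"duplicate atom identifiers, e.g. {dupes}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def select(self, chain: Optional[str] = None, residue_number: Optional[int] = None,
               name: Optional[str] = None) -> list[Atom]:
        out = []
        for a in self.atoms:
            if chain is not None and a.chain != chain:
                continue
            if residue_number is not None and a.residue_number != residue_number:
                continue
            if name is not None and a.name != name:
                continue
            out.append(a)
        return out

    def coords(self, atoms: Sequence[Atom]) -> np.ndarray:
        return np.array([a.xyz for a in atoms], dtype=float)


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties resolved toward altloc 'A' (then alphabetical)
    return min(atoms, key=lambda a: (-a.occ, a.altloc or "A"))


def read_structure(path: str | Path, model_index: int = 0) -> Structure:
    """Read a PDB (or mmCIF) file into a :class:`Structure`.

    One atom is kept per (chain, residue, atom name): among alternate
    locations the highest-occupancy conformer wins, ties going to altloc
    'A'.  ``model_index`` selects the model in multi-model files.
    """
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"{path}: no models found")
    if not 0 <= model_index < len(st):
        raise StructureFormatError(f"{path}: model index {model_index} outside 0..{len(st)-1}")
    model = st[model_index]
    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in residue:
                by_name.setdefault(atom.name, []).append(atom)
            for name, alts in by_name.items():
                a = _pick_altloc(alts)
                atoms.append(
                    Atom(
                        chain=chain.name,
                        residue_number=residue.seqid.num,
                        residue_name=residue.name,
                        name=name,
                        xyz=(a.pos.x, a.pos.y, a.pos.z),
                        altloc="",
                        occupancy=a.occ,
                        element=a.element.name,
                    )
                )
    if not atoms:
        raise StructureFormatError(f"{path}: no atoms parsed")
    return Structure(atoms=tuple(atoms), model_id=str(model.num))


def write_structure(s: Structure, path: str | Path) -> None:
    """Write *s* as a minimal PDB file (ATOM records, 3 dp coordinates)."""
    lines = []
    for i, a in enumerate(s.atoms, start=1):
        name = a.name if len(a.name) >= 4 else f" {a.name:<3}"
        x, y, z = a.xyz
        lines.append(
            f"ATOM  {i:>5d} {name}{'':1}{a.residue_name:<3} {a.chain:>1}"
            f"{a.residue_number:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def parse_selector(sel: str) -> tuple[str, int, str]:
    """Parse a ``chain:resnum:atomname`` selector string."""
    parts = sel.split(":")
    if len(parts) != 3:
        raise AtomSelectionError(f"selector {sel!r} is not chain:resnum:atomname")
    chain, resnum, name = parts
    try:
        return chain, int(resnum), name
    except ValueError:
        raise AtomSelectionError(f"selector {sel!r}: residue number not an integer") from None


def _resolve(s: Structure, sel: tuple[str, int, str] | str) -> Atom:
    if isinstance(sel, str):
        sel = parse_selector(sel)
    chain, resnum, name = sel
    hits = s.select(chain=chain, residue_number=resnum, name=name)
    if len(hits) == 0:
        raise AtomSelectionError(f"selector {chain}:{resnum}:{name} matches no atom")
    if len(hits) > 1:
        raise AtomSelectionError(f"selector {chain}:{resnum}:{name} is ambiguous ({len(hits)} atoms)")
    return hits[0]


def atom_distance(
    s: Structure,
    sel_a: tuple[str, int, str] | str,
    sel_b: tuple[str, int, str] | str,
) -> float:
    """Euclidean distance (Å) between two uniquely selected atoms."""
    a, b = _resolve(s, sel_a), _resolve(s, sel_b)
    return float(np.linalg.norm(np.subtract(a.xyz, b.xyz)))


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid transform R x + t mapping set A onto set B."""

    rotation: np.ndarray     # 3x3, proper (det = +1)
    translation: np.ndarray  # length 3
    rmsd: float              # Å
    n_atoms: int
    degenerate: bool = False

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(a: np.ndarray, b: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid superposition of paired point sets (Kabsch).

    Finds the proper rotation R and translation t minimising
    ``sum ||R a_i + t - b_i||^2`` and reports the residual RMSD.
    Reflections are excluded by the usual determinant sign correction.
    Collinear/degenerate sets are flagged but a solution is still
    returned.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 3:
        raise ValueError("need matched (n, 3) arrays with n >= 3")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    h = a0.T @ b0
    u, sing, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    # rank < 3 (collinear or planar-with-reflection ambiguity) -> flagged
    degenerate = bool(sing[-1] < 1e-9 * max(sing[0], 1.0))
    t = cb - rot @ ca
    diff = a0 @ rot.T - b0
    rmsd = float(np.sqrt((diff**2).sum() / a.shape[0]))
    return SuperpositionResult(
        rotation=rot, translation=t, rmsd=rmsd, n_atoms=a.shape[0], degenerate=degenerate
    )


@dataclass(frozen=True)
class CaRmsdResult:
    """C-alpha RMSD after optimal superposition, with the pairing size."""

    rmsd: float
    n_pairs: int
    superposition: SuperpositionResult


def ca_rmsd(s_a: Structure, s_b: Structure, chain: str) -> CaRmsdResult:
    """Kabsch-superposed RMSD over shared C-alpha atoms of one chain.

    Residues are paired by residue-number intersection (appropriate for
    point mutants of the same protein); hydrogens are irrelevant since only
    CA atoms enter.  Requires at least 3 shared C-alphas.
    """
    def ca_map(s: Structure) -> dict[int, Atom]:
        return {a.residue_number: a for a in s.select(chain=chain, name="CA")}

    ma, mb = ca_map(s_a), ca_map(s_b)
    shared = sorted(set(ma) & set(mb))
    if len(shared) < 3:
        raise InsufficientDataError(
            f"chain {chain!r}: only {len(shared)} shared C-alpha atoms"
        )
    xa = np.array([ma[r].xyz for r in shared], dtype=float)
    xb = np.array([mb[r].xyz for r in shared], dtype=float)
    sup = kabsch_superpose(xa, xb)
    return CaRmsdResult(rmsd=sup.rmsd, n_pairs=len(shared), superposition=sup)
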