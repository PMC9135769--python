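"""Structures, ensembles, atom selection and rigid-body superposition.

This module is the geometric substrate for the rest of the package: it reads
and writes PDB files (single- and multi-model), resolves alternate locations,
extracts residue segments, and provides Kabsch least-squares superposition
and RMSD between paired coordinate sets.

Conventions
-----------
* Residues are addressed by author (PDB) numbers; nothing is renumbered on
  read.
* Alternate locations are resolved by keeping the highest-occupancy atom;
  ties are broken toward the lexicographically smallest altloc identifier.
* Hydrogens are dropped on read unless ``keep_hydrogens=True``.
* The backbone atom set used for superposition and RMSD is N, CA, C.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "Ensemble",
    "Segment",
    "StructureError",
    "BACKBONE_ATOMS",
    "read_structure",
    "write_structure",
    "read_xyz_ensemble",
    "write_xyz_ensemble",
    "extract_segments",
    "backbone_selection",
    "coords_for",
    "kabsch_superpose",
    "rmsd",
]

BACKBONE_ATOMS = ("N", "CA", "C")


class StructureError(ValueError):
    """Raised for unreadable files, missing atoms, or invalid selections."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    number: int
    name: str
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise StructureError(f"residue {self.name} {self.number}{self.icode}: no atom named {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)


@dataclass
class Structure:
    """A single model: chains mapping chain ID to an ordered residue list."""

    chains: dict[str, list[Residue]]
    model_index: int = 0

    def residue(self, chain: str, number: int, icode: str = "") -> Residue:
        try:
            residues = self.chains[chain]
        except KeyError:
            raise StructureError(f"no chain {chain!r} in structure") from None
        for r in residues:
            if r.number == number and r.icode == icode:
                return r
        raise StructureError(f"chain {chain}: no residue {number}{icode}")

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for rs in self.chains.values() for r in rs)

    def atom_roster(self) -> list[tuple[str, int, str, str]]:
        """Ordered (chain, resnum, icode, atom name) keys of every atom."""
        return [
            (cid, r.number, r.icode, a.name)
            for cid, rs in self.chains.items()
            for r in rs
            for a in r.atoms
        ]

    def all_coords(self) -> np.ndarray:
        return np.array(
            [a.coords for rs in self.chains.values() for r in rs for a in r.atoms],
            dtype=float,
        )

    def set_all_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        i = 0
        for rs in self.chains.values():
            for r in rs:
                for a in r.atoms:
                    a.coords = coords[i]
                    i += 1
        if i != len(coords):
            raise StructureError("coordinate array does not match atom count")

    def copy(self) -> "Structure":
        return copy.deepcopy(self)


@dataclass
class Ensemble:
    """Ordered frames sharing one atom roster (e.g. NMR models, MD snapshots)."""

    frames: list[Structure]

    def __post_init__(self) -> None:
        if not self.frames:
            raise StructureError("ensemble must contain at least one frame")
        roster = self.frames[0].atom_roster()
        for i, f in enumerate(self.frames[1:], start=2):
            if f.atom_roster() != roster:
                raise StructureError(f"frame {i} atom roster differs from frame 1")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def coords(self, selection: Sequence[tuple] | None = None) -> np.ndarray:
        """(n_frames, n_atoms, 3) coordinate stack for a selection (default: all)."""
        if selection is None:
            return np.stack([f.all_coords() for f in self.frames])
        return np.stack([coords_for(f, selection) for f in self.frames])


@dataclass
class Segment:
    chain: str
    start: int
    end: int
    residues: list[Residue]

    def coords(self, atom_names: Sequence[str] = BACKBONE_ATOMS) -> np.ndarray:
        return np.array([r.atom(n).coords for r in self.residues for n in atom_names])


# ---------------------------------------------------------------------------
# PDB I/O (via gemmi)
# ---------------------------------------------------------------------------

def _first_bad_line(path: Path) -> str | None:
    """Scan a PDB file for the first malformed ATOM/HETATM record."""
    try:
        text = path.read_text(errors="replace")
    except OSError:
        return None
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except (ValueError, IndexError):
                return f"line {lineno}: {line.rstrip()}"
    return None


def _is_amino_acid(resname: str) -> bool:
    info = gemmi.find_tabulated_residue(resname)
    return info is not None and info.is_amino_acid()


def _convert_model(model: gemmi.Model, model_index: int, keep_hydrogens: bool) -> Structure:
    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            if not _is_amino_acid(res.name):
                continue
            # altloc groups by atom name; keep highest occupancy, ties -> 'A' side
            by_name: dict[str, gemmi.Atom] = {}
            for atom in res:
                if not keep_hydrogens and atom.element.is_hydrogen:
                    continue
                prev = by_name.get(atom.name)
                if prev is None:
                    by_name[atom.name] = atom
                elif (atom.occ, -ord(atom.altloc or "A")) > (prev.occ, -ord(prev.altloc or "A")):
                    by_name[atom.name] = atom
            atoms = [
                Atom(
                    name=a.name,
                    element=a.element.name,
                    coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=min(max(a.occ, 0.0), 1.0),
                    altloc=a.altloc or "",
                )
                for a in by_name.values()
            ]
            if atoms:
                residues.append(
                    Residue(
                        number=res.seqid.num,
                        name=res.name,
                        icode=(res.seqid.icode or "").strip(),
                        atoms=atoms,
                    )
                )
        if residues:
            chains[chain.name] = residues
    if not chains:
        raise StructureError("no polymer atoms in model")
    return Structure(chains=chains, model_index=model_index)


def read_structure(
    path: str | Path,
    model_policy: str = "first",
    keep_hydrogens: bool = False,
) -> Structure | Ensemble:
    """Read a PDB file into a :class:`Structure` or, for multi-model files
    with ``model_policy='all'``, an :class:`Ensemble`.

    Waters, ligands and other non-amino-acid residues are skipped; a file
    containing none raises ``StructureError('no polymer atoms')``.
    """
    path = Path(path)
    if model_policy not in ("first", "all"):
        raise ValueError("model_policy must be 'first' or 'all'")
    if not path.exists():
        raise StructureError(f"file not found: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        bad = _first_bad_line(path)
        hint = f" (first offending record at {bad})" if bad else ""
        raise StructureError(f"cannot parse {path}: {exc}{hint}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: file contains no models")
    bad = _first_bad_line(path)
    if bad is not None:
        raise StructureError(f"cannot parse {path}: malformed coordinate record at {bad}")
    try:
        if model_policy == "first":
            return _convert_model(st[0], 0, keep_hydrogens)
        frames = [_convert_model(m, i, keep_hydrogens) for i, m in enumerate(st)]
    except StructureError as exc:
        raise StructureError(f"{path}: {exc}") from None
    if len(frames) == 1:
        return frames[0]
    return Ensemble(frames=frames)


def write_structure(obj: Structure | Ensemble, path: str | Path) -> None:
    """Write a Structure or Ensemble as a PDB file (ATOM/MODEL records)."""
    frames = obj.frames if isinstance(obj, Ensemble) else [obj]
    st = gemmi.Structure()
    st.name = "topofold"
    for i, frame in enumerate(frames, start=1):
        model = gemmi.Model(i)
        for cid, residues in frame.chains.items():
            chain = gemmi.Chain(cid)
            for r in residues:
                res = gemmi.Residue()
                res.name = r.name
                res.seqid = gemmi.SeqId(r.number, r.icode or " ")
                for a in r.atoms:
                    atom = gemmi.Atom()
                    atom.name = a.name
                    atom.element = gemmi.Element(a.element)
                    atom.pos = gemmi.Position(*a.coords)
                    atom.occ = a.occupancy
                    atom.altloc = a.altloc or "\0"
                    res.add_atom(atom)
                chain.add_residue(res)
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    doc_path = Path(path)
    doc_path.parent.mkdir(parents=True, exist_ok=True)
    st.write_pdb(str(doc_path))


# ---------------------------------------------------------------------------
# Plain-text coordinate ensembles
# ---------------------------------------------------------------------------

def read_xyz_ensemble(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a whitespace-delimited per-frame xyz table.

    Format: a header line naming the atoms, then one ``x y z`` line per atom
    per frame, frames separated by blank lines. Returns (atom labels,
    coordinates of shape (n_frames, n_atoms, 3)).
    """
    lines = Path(path).read_text().splitlines()
    labels: list[str] | None = None
    frames: list[list[list[float]]] = []
    current: list[list[float]] = []
    for line in lines:
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            if current:
                frames.append(current)
                current = []
            continue
        if labels is None:
            labels = stripped.split()
            continue
        parts = stripped.split()
        if len(parts) != 3:
            raise StructureError(f"expected 3 coordinates per line, got: {stripped!r}")
        current.append([float(v) for v in parts])
    if current:
        frames.append(current)
    if labels is None or not frames:
        raise StructureError(f"{path}: no header or no frames")
    n = len(labels)
    for i, fr in enumerate(frames, start=1):
        if len(fr) != n:
            raise StructureError(f"frame {i} has {len(fr)} atoms, header names {n}")
    return labels, np.asarray(frames, dtype=float)


def write_xyz_ensemble(labels: Sequence[str], coords: np.ndarray, path: str | Path) -> None:
    coords = np.asarray(coords, dtype=float)
    out = [" ".join(labels)]
    for frame in coords:
        for xyz in frame:
            out.append(" ".join(f"{v:.6f}" for v in xyz))
        out.append("")
    Path(path).write_text("\n".join(out))


# ---------------------------------------------------------------------------
# Selections and segments
# ---------------------------------------------------------------------------

def extract_segments(
    structure: Structure,
    ranges: Iterable[tuple[str, int, int]],
) -> list[Segment]:
    """Extract residue segments by (chain, start, end) author-number ranges.

    Residue order inside each segment follows the chain; a range entirely
    absent, or with start > end, is an error listing the missing residues.
    """
    segments = []
    for chain_id, start, end in ranges:
        if start > end:
            raise StructureError(f"invalid range {chain_id} {start}-{end}: start > end")
        residues = [
            r
            for r in structure.chains.get(chain_id, [])
            if start <= r.number <= end
        ]
        if not residues:
            raise StructureError(
                f"range {chain_id} {start}-{end}: no residues present "
                f"(missing {start}..{end})"
            )
        segments.append(Segment(chain=chain_id, start=start, end=end, residues=residues))
    return segments


def backbone_selection(
    structure: Structure,
    chains: Sequence[str] | None = None,
    atom_names: Sequence[str] = BACKBONE_ATOMS,
) -> list[tuple[str, int, str, str]]:
    """Selection keys for backbone atoms of every residue (errors if missing)."""
    sel = []
    for cid, residues in structure.chains.items():
        if chains is not None and cid not in chains:
            continue
        for r in residues:
            for name in atom_names:
                if not r.has_atom(name):
                    raise StructureError(
                        f"residue {r.name} {cid}:{r.number}{r.icode} is missing atom {name}"
                    )
                sel.append((cid, r.number, r.icode, name))
    return sel


def coords_for(structure: Structure, selection: Sequence[tuple]) -> np.ndarray:
    """Coordinates (n, 3) for selection keys (chain, resnum, icode, atom name).

    Missing atoms raise, never silently drop: silent loss would change the
    meaning of any RMSD computed downstream.
    """
    out = np.empty((len(selection), 3))
    for i, (cid, num, icode, name) in enumerate(selection):
        out[i] = structure.residue(cid, num, icode).atom(name).coords
    return out


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns (rotation, translation, rmsd) such that
    ``mobile @ rotation.T + translation`` best fits ``reference``. The
    rotation is proper (det +1); reflections are excluded.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise StructureError(f"coordinate sets must share shape (n, 3); got {P.shape} vs {Q.shape}")
    n = len(P)
    if n < 3:
        raise StructureError("superposition needs at least 3 points")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    if np.linalg.matrix_rank(P0, tol=1e-10) < 2:
        raise StructureError("degenerate (collinear) coordinates: superposition undefined")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    value = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, value


def rmsd(a: np.ndarray, b: np.ndarray, superpose: bool = False) -> float:
    """Root-mean-square deviation of paired points, optionally after optimal
    rigid superposition."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise StructureError(f"mismatched coordinate counts: {a.shape} vs {b.shape}")
    if superpose:
        if np.array_equal(a, b):
            return 0.0
        return kabsch_superpose(a, b)[2]
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
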