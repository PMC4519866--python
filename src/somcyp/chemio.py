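"""Chemical file I/O and molecular-graph services.

Reads substrate structures (SDF V2000, MOL2) and ordered docking-pose
ensembles, and provides the graph primitives the site-of-metabolism
predictor consumes: per-carbon hydrogen equivalence classes (hydrogens on
one carbon yield the same radical on abstraction), carbon adjacency, and
Morgan-style symmetry labels used to elide duplicate energy evaluations.

All coordinates are in Angstrom.  Every hydrogen must be explicit in the
input: the abstraction energies downstream refer to specific hydrogen
atoms, so silent hydrogen addition is refused by contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Geometry import Point3D

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Molecule",
    "LigandPose",
    "HydrogenClass",
    "SomcypError",
    "InputError",
    "MoleculeFormatError",
    "ExplicitHydrogenError",
    "PoseSetError",
    "read_molecule",
    "write_molecule",
    "molecule_to_molblock",
    "read_pose_set",
    "hydrogen_equivalence_classes",
    "adjacent_carbons",
    "symmetry_classes",
]


# ---------------------------------------------------------------------------
# errors

class SomcypError(Exception):
    """Base class for all package errors."""


class InputError(SomcypError):
    """Invalid or malformed user input (distinct CLI exit code)."""


class MoleculeFormatError(InputError):
    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class ExplicitHydrogenError(InputError):
    """A carbon has an implicit-valence deficit: hydrogens must be explicit."""


class PoseSetError(InputError):
    pass


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: float  # 1, 2, 3 or 1.5 (aromatic)

    def other(self, k: int) -> int:
        return self.j if k == self.i else self.i


@dataclass
class Molecule:
    """A small molecule with explicit hydrogens and 3D coordinates (Å)."""

    symbols: list[str]
    coords: np.ndarray  # (n, 3) float64, Å
    bonds: list[Bond]
    charges: list[int] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if not self.charges:
            self.charges = [0] * len(self.symbols)
        if len(self.symbols) != len(self.coords):
            raise ValueError("symbol/coordinate count mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates in molecule {self.name!r}")
        n = len(self.symbols)
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n) or b.i == b.j:
                raise ValueError(f"bond ({b.i},{b.j}) references invalid atoms")

    # -- basic queries ------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def neighbors(self, i: int) -> list[int]:
        return [b.other(i) for b in self.bonds if i in (b.i, b.j)]

    def bonds_of(self, i: int) -> list[Bond]:
        return [b for b in self.bonds if i in (b.i, b.j)]

    def hydrogens_on(self, i: int) -> list[int]:
        return [j for j in self.neighbors(i) if self.symbols[j] == "H"]

    @property
    def carbon_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.symbols) if s == "C"]

    def is_sp3_carbon(self, i: int) -> bool:
        return self.symbols[i] == "C" and all(b.order == 1 for b in self.bonds_of(i))

    # -- geometry -----------------------------------------------------------
    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Molecule":
        new = self.coords @ np.asarray(rotation, float).T + np.asarray(translation, float)
        return replace(self, coords=new)

    def without_atom(self, idx: int) -> "Molecule":
        """Remove one atom at fixed geometry, reindexing bonds."""
        keep = [k for k in range(self.n_atoms) if k != idx]
        remap = {old: new for new, old in enumerate(keep)}
        bonds = [
            Bond(remap[b.i], remap[b.j], b.order)
            for b in self.bonds
            if idx not in (b.i, b.j)
        ]
        return Molecule(
            symbols=[self.symbols[k] for k in keep],
            coords=self.coords[keep],
            bonds=bonds,
            charges=[self.charges[k] for k in keep],
            name=self.name,
        )


@dataclass
class LigandPose:
    """One docked orientation of the substrate, in the protein frame."""

    molecule: Molecule
    rank: int
    score: float | None = None


@dataclass(frozen=True)
class HydrogenClass:
    """All hydrogens attached to one carbon (equal radical on abstraction)."""

    carbon_index: int
    hydrogen_indices: tuple[int, ...]
    class_id: int


# ---------------------------------------------------------------------------
# reading

_BOND_ORDER_FROM_RDKIT = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
    Chem.BondType.AROMATIC: 1.5,
}
_BOND_TYPE_TO_RDKIT = {
    1.0: Chem.BondType.SINGLE,
    2.0: Chem.BondType.DOUBLE,
    3.0: Chem.BondType.TRIPLE,
    1.5: Chem.BondType.AROMATIC,
}


def _from_rdkit(mol: Chem.Mol, name: str = "") -> Molecule:
    if mol.GetNumConformers() == 0:
        raise MoleculeFormatError("record carries no 3D coordinates")
    conf = mol.GetConformer()
    symbols, charges = [], []
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        symbols.append(sym[0].upper() + sym[1:].lower())
        charges.append(atom.GetFormalCharge())
    coords = np.array(
        [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y, conf.GetAtomPosition(i).z]
         for i in range(mol.GetNumAtoms())]
    )
    bonds = []
    for b in mol.GetBonds():
        order = _BOND_ORDER_FROM_RDKIT.get(b.GetBondType())
        if order is None:
            order = float(b.GetBondTypeAsDouble())
        bonds.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    if mol.HasProp("_Name") and mol.GetProp("_Name").strip():
        name = mol.GetProp("_Name").strip()
    return Molecule(symbols, coords, bonds, charges, name)


def check_explicit_hydrogens(m: Molecule) -> None:
    """Refuse carbons with an implicit-valence deficit (missing hydrogens)."""
    for i, sym in enumerate(m.symbols):
        if sym != "C":
            continue
        valence = sum(b.order for b in m.bonds_of(i)) + abs(m.charges[i])
        if valence < 3.5:
            raise ExplicitHydrogenError(
                f"carbon atom {i} in {m.name!r} has total bond order "
                f"{valence:g} < 4: hydrogens must be explicit in the input"
            )


def _locate_sdf_error(text: str) -> int | None:
    lines = text.splitlines()
    if len(lines) < 4:
        return len(lines) or 1
    counts = lines[3]
    try:
        na, nb = int(counts[0:3]), int(counts[3:6])
    except (ValueError, IndexError):
        return 4
    for k in range(na):
        ln = 4 + k
        if ln >= len(lines):
            return ln + 1
        try:
            [float(lines[ln][c : c + 10]) for c in (0, 10, 20)]
        except (ValueError, IndexError):
            return ln + 1
    for k in range(nb):
        ln = 4 + na + k
        if ln >= len(lines):
            return ln + 1
        try:
            int(lines[ln][0:3]), int(lines[ln][3:6])
        except (ValueError, IndexError):
            return ln + 1
    return None


def _sdf_blocks(text: str) -> list[str]:
    blocks, current = [], []
    for line in text.splitlines():
        if line.strip() == "$$$$":
            blocks.append("\n".join(current) + "\n")
            current = []
        else:
            current.append(line)
    if any(l.strip() for l in current):
        blocks.append("\n".join(current) + "\n")
    return blocks


def _parse_sdf_block(block: str, origin: str) -> Molecule:
    lines = block.splitlines()
    if len(lines) >= 4 and "V3000" in lines[3]:
        raise MoleculeFormatError(
            f"{origin}: V3000 connection tables are not supported; "
            "please supply SDF V2000",
            line=4,
        )
    mol = Chem.MolFromMolBlock(block, sanitize=False, removeHs=False)
    if mol is None:
        raise MoleculeFormatError(
            f"{origin}: failed to parse SDF V2000 record", line=_locate_sdf_error(block)
        )
    return _from_rdkit(mol)


def _mol2_blocks(text: str) -> list[str]:
    starts = [i for i, l in enumerate(text.splitlines()) if l.startswith("@<TRIPOS>MOLECULE")]
    if not starts:
        raise MoleculeFormatError("no @<TRIPOS>MOLECULE record found", line=1)
    lines = text.splitlines()
    bounds = starts + [len(lines)]
    return ["\n".join(lines[a:b]) + "\n" for a, b in zip(bounds, bounds[1:])]


def _parse_mol2_block(block: str, origin: str) -> Molecule:
    mol = Chem.MolFromMol2Block(block, sanitize=False, removeHs=False)
    if mol is None:
        raise MoleculeFormatError(f"{origin}: failed to parse MOL2 record", line=1)
    return _from_rdkit(mol)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt.lower()
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("sdf", "mol", "sd"):
        return "sdf"
    if suffix == "mol2":
        return "mol2"
    raise MoleculeFormatError(f"cannot infer format from file name {path.name!r}")


def read_molecule(path: str | Path, format: str | None = None) -> Molecule:
    """Read the first record of an SDF V2000 or MOL2 file.

    Raises :class:`MoleculeFormatError` on parse failure and
    :class:`ExplicitHydrogenError` when a carbon is missing hydrogens.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    text = path.read_text()
    if fmt == "sdf":
        m = _parse_sdf_block(_sdf_blocks(text)[0], path.name)
    elif fmt == "mol2":
        m = _parse_mol2_block(_mol2_blocks(text)[0], path.name)
    else:
        raise MoleculeFormatError(f"unknown format {fmt!r}; expected sdf or mol2")
    if not m.name:
        m.name = path.stem
    check_explicit_hydrogens(m)
    return m


def read_pose_set(
    path: str | Path,
    reference: Molecule,
    format: str | None = None,
    score_property: str = "ChemScore",
) -> list[LigandPose]:
    """Read an ordered multi-record pose file; rank = record index from 1.

    Every record must share the reference substrate's atom count and element
    sequence.  Scores are taken from `score_property` (SDF data field) when
    present.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    text = path.read_text()
    poses: list[LigandPose] = []
    if fmt == "sdf":
        blocks = _sdf_blocks(text)
        for k, block in enumerate(blocks, start=1):
            mol = Chem.MolFromMolBlock(block, sanitize=False, removeHs=False)
            if mol is None:
                raise MoleculeFormatError(
                    f"{path.name}: failed to parse pose record {k}",
                    line=_locate_sdf_error(block),
                )
            m = _from_rdkit(mol)
            score = None
            tag = f">  <{score_property}>"
            lines = block.splitlines()
            for ln, line in enumerate(lines):
                if line.strip().startswith(">") and f"<{score_property}>" in line:
                    try:
                        score = float(lines[ln + 1].strip())
                    except (IndexError, ValueError):
                        score = None
                    break
            poses.append(LigandPose(m, rank=k, score=score))
    elif fmt == "mol2":
        for k, block in enumerate(_mol2_blocks(text), start=1):
            poses.append(LigandPose(_parse_mol2_block(block, f"{path.name} record {k}"), rank=k))
    else:
        raise MoleculeFormatError(f"unknown format {fmt!r}; expected sdf or mol2")

    for pose in poses:
        pm = pose.molecule
        if pm.n_atoms != reference.n_atoms:
            raise PoseSetError(
                f"{path.name}: pose record {pose.rank} has {pm.n_atoms} atoms, "
                f"reference substrate has {reference.n_atoms}"
            )
        if pm.symbols != reference.symbols:
            raise PoseSetError(
                f"{path.name}: pose record {pose.rank} element sequence differs "
                "from the reference substrate"
            )
    return poses


# ---------------------------------------------------------------------------
# writing

def to_rdkit(m: Molecule) -> Chem.Mol:
    rw = Chem.RWMol()
    for sym, ch in zip(m.symbols, m.charges):
        atom = Chem.Atom(sym)
        atom.SetFormalCharge(int(ch))
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    for b in m.bonds:
        rw.AddBond(b.i, b.j, _BOND_TYPE_TO_RDKIT[float(b.order)])
    conf = Chem.Conformer(m.n_atoms)
    for i, xyz in enumerate(m.coords):
        conf.SetAtomPosition(i, Point3D(*map(float, xyz)))
    mol = rw.GetMol()
    mol.AddConformer(conf)
    mol.SetProp("_Name", m.name)
    return mol


def molecule_to_molblock(m: Molecule) -> str:
    return Chem.MolToMolBlock(to_rdkit(m), kekulize=False)


def write_molecule(m: Molecule, path: str | Path) -> Path:
    """Write a single-record SDF V2000 file."""
    path = Path(path)
    path.write_text(molecule_to_molblock(m) + "$$$$\n")
    return path


# ---------------------------------------------------------------------------
# graph services

def hydrogen_equivalence_classes(m: Molecule) -> list[HydrogenClass]:
    """One class per hydrogen-bearing carbon, ordered by carbon index.

    Hydrogens attached to the same carbon produce the same radical when
    abstracted, so they share one reaction-energy evaluation unit.
    """
    classes = []
    for carbon in m.carbon_indices:
        hyd = tuple(sorted(m.hydrogens_on(carbon)))
        if hyd:
            classes.append(HydrogenClass(carbon, hyd, class_id=len(classes)))
    return classes


def adjacent_carbons(m: Molecule, atom_index: int) -> set[int]:
    """Carbons exactly one bond away from `atom_index`."""
    if not (0 <= atom_index < m.n_atoms):
        raise IndexError(f"atom index {atom_index} out of range (n={m.n_atoms})")
    return {j for j in m.neighbors(atom_index) if m.symbols[j] == "C"}


def symmetry_classes(m: Molecule) -> list[int]:
    """Graph-symmetry labels by iterative Morgan-like refinement.

    Atoms receive equal labels when indistinguishable by (element, formal
    charge, sorted incident bond orders) extended over growing neighborhood
    shells.  Labels are dense integers, deterministic for a given input, and
    are intended for reporting and duplicate-energy elision only: the
    reactivity class unit remains "hydrogens on one carbon".
    """
    invariants: list[tuple] = [
        (
            m.symbols[i],
            m.charges[i],
            tuple(sorted(b.order for b in m.bonds_of(i))),
        )
        for i in range(m.n_atoms)
    ]
    labels = _dense(invariants)
    for _ in range(m.n_atoms + 1):
        refined = [
            (labels[i], tuple(sorted((b.order, labels[b.other(i)]) for b in m.bonds_of(i))))
            for i in range(m.n_atoms)
        ]
        new = _dense(refined)
        if new == labels:
            break
        labels = new
    return labels


def _dense(values: Sequence) -> list[int]:
    order = {v: k for k, v in enumerate(sorted(set(values)))}
    return [order[v] for v in values]
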