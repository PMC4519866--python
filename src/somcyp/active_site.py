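"""Geometric model of the CYP3A4 active site extracted from a holo PDB.

The predictor measures candidate sites against a handful of named
landmarks: the heme iron, the hydrogen-bond donor/acceptor residues
(Arg105, Arg106, Ser119, Ile301, Glu308), three conserved crystallographic
waters (619, 623, 637), and the phenylalanine cluster forming the
hydrophobic roof of the cavity (Phe57/108/219/220/241/304).  This module
pulls exactly those coordinates out of a PDB file; everything downstream
is pure geometry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .chemio import InputError

__all__ = [
    "ActiveSiteConfig",
    "ActiveSiteModel",
    "ActiveSiteError",
    "extract_active_site",
]


class ActiveSiteError(InputError):
    pass


# Polar atoms considered per residue.  Arg: guanidinium nitrogens;
# Ser: hydroxyl oxygen; Glu: carboxylate oxygens.  For Ile301 and Glu308
# the backbone O and N are included as well (the literature names the
# residues without saying which atoms interact; geometric criteria decide).
_DEFAULT_HBOND_RESIDUES: dict[str, tuple[int, str, tuple[str, ...]]] = {
    "Arg105": (105, "ARG", ("NE", "NH1", "NH2")),
    "Arg106": (106, "ARG", ("NE", "NH1", "NH2")),
    "Ser119": (119, "SER", ("OG",)),
    "Ile301": (301, "ILE", ("O", "N")),
    "Glu308": (308, "GLU", ("OE1", "OE2", "O", "N")),
}

_PHE_RING_ATOMS = ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")
_DEFAULT_PHE_RESIDUES: dict[str, int] = {
    "Phe57": 57,
    "Phe108": 108,
    "Phe219": 219,
    "Phe220": 220,
    "Phe241": 241,
    "Phe304": 304,
}
_DEFAULT_WATERS = (619, 623, 637)
_WATER_RESNAMES = {"HOH", "WAT", "H2O"}


@dataclass
class ActiveSiteConfig:
    """Which residues/waters to extract; numbering follows the PDB authors."""

    hbond_residues: dict[str, tuple[int, str, tuple[str, ...]]] = field(
        default_factory=lambda: dict(_DEFAULT_HBOND_RESIDUES)
    )
    phe_residues: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_PHE_RESIDUES))
    waters: tuple[int, ...] = _DEFAULT_WATERS
    chain: str | None = None  # default: first chain containing the heme


@dataclass
class ActiveSiteModel:
    """Positions (Å) of everything the pose-feature detectors measure against."""

    fe_position: np.ndarray
    hbond_residues: dict[str, list[tuple[str, np.ndarray]]]
    waters: dict[int, np.ndarray]
    phe_cluster: dict[str, list[tuple[str, np.ndarray]]]
    heme_atoms: list[tuple[str, np.ndarray]]
    warnings: list[str] = field(default_factory=list)
    source: str = ""

    def hbond_partner_atoms(self) -> list[tuple[str, np.ndarray]]:
        """Flat (label, position) list of residue polar atoms, stable order."""
        out = []
        for res, atoms in self.hbond_residues.items():
            out.extend((f"{res}:{name}", pos) for name, pos in atoms)
        return out

    def phe_ring_positions(self) -> np.ndarray:
        pts = [pos for atoms in self.phe_cluster.values() for _, pos in atoms]
        return np.array(pts).reshape(-1, 3)

    def heme_positions(self) -> np.ndarray:
        return np.array([pos for _, pos in self.heme_atoms]).reshape(-1, 3)

    def to_json(self, path: str | Path | None = None) -> str:
        def _pt(p):
            return [round(float(x), 6) for x in p]

        payload = {
            "source": self.source,
            "fe_position": _pt(self.fe_position),
            "hbond_residues": {
                res: {name: _pt(pos) for name, pos in atoms}
                for res, atoms in self.hbond_residues.items()
            },
            "waters": {str(k): _pt(v) for k, v in self.waters.items()},
            "phe_cluster": {
                res: {name: _pt(pos) for name, pos in atoms}
                for res, atoms in self.phe_cluster.items()
            },
            "heme_atoms": [[name, _pt(pos)] for name, pos in self.heme_atoms],
            "warnings": list(self.warnings),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _pos(atom: gemmi.Atom) -> np.ndarray:
    return np.array([atom.pos.x, atom.pos.y, atom.pos.z])


def extract_active_site(
    pdb: str | Path, config: ActiveSiteConfig | None = None
) -> ActiveSiteModel:
    """Build an :class:`ActiveSiteModel` from a CYP3A4 complex PDB file.

    Fatal only when no heme iron exists; configured residues or waters that
    are absent are recorded as warnings so partial structures stay usable.
    """
    config = config or ActiveSiteConfig()
    path = Path(pdb)
    structure = gemmi.read_structure(str(path))
    if len(structure) == 0:
        raise ActiveSiteError(f"{path.name}: no models in structure")
    model = structure[0]

    fe_position = None
    heme_atoms: list[tuple[str, np.ndarray]] = []
    heme_chain = None
    for chain in model:
        for residue in chain:
            for atom in residue:
                if atom.element.name == "Fe" or atom.name.strip().upper() == "FE":
                    fe_position = _pos(atom)
                    heme_chain = chain.name
                    heme_atoms = [
                        (a.name, _pos(a)) for a in residue if a.element.name != "H"
                    ]
                    break
            if fe_position is not None:
                break
        if fe_position is not None:
            break
    if fe_position is None:
        raise ActiveSiteError(
            f"{path.name}: no heme iron (FE) atom found; cannot build the "
            "active-site model"
        )

    wanted_chain = config.chain or heme_chain
    warnings: list[str] = []

    def _find_residue(num: int, resname: str):
        # prefer the heme/configured chain, fall back to any chain
        chains = [c for c in model if c.name == wanted_chain]
        chains += [c for c in model if c.name != wanted_chain]
        for chain in chains:
            for residue in chain:
                if residue.seqid.num == num and residue.name.strip() == resname:
                    return residue
        return None

    hbond_residues: dict[str, list[tuple[str, np.ndarray]]] = {}
    for label, (num, resname, atom_names) in config.hbond_residues.items():
        residue = _find_residue(num, resname)
        if residue is None:
            warnings.append(f"residue {label} ({resname} {num}) not found")
            continue
        atoms = [
            (name, _pos(residue[name][0]))
            for name in atom_names
            if name in residue
        ]
        missing = [n for n in atom_names if n not in residue]
        if missing:
            warnings.append(f"{label}: missing polar atoms {','.join(missing)}")
        if atoms:
            hbond_residues[label] = atoms
        else:
            warnings.append(f"{label}: no usable polar atoms")

    phe_cluster: dict[str, list[tuple[str, np.ndarray]]] = {}
    for label, num in config.phe_residues.items():
        residue = _find_residue(num, "PHE")
        if residue is None:
            warnings.append(f"residue {label} (PHE {num}) not found")
            continue
        atoms = [(name, _pos(residue[name][0])) for name in _PHE_RING_ATOMS if name in residue]
        if atoms:
            phe_cluster[label] = atoms
        else:
            warnings.append(f"{label}: no ring carbons found")

    waters: dict[int, np.ndarray] = {}
    for num in config.waters:
        found = None
        for chain in model:
            for residue in chain:
                if residue.seqid.num == num and residue.name.strip() in _WATER_RESNAMES:
                    if "O" in residue:
                        found = _pos(residue["O"][0])
                    break
            if found is not None:
                break
        if found is None:
            warnings.append(f"water {num} not found")
        else:
            waters[num] = found

    return ActiveSiteModel(
        fe_position=fe_position,
        hbond_residues=hbond_residues,
        waters=waters,
        phe_cluster=phe_cluster,
        heme_atoms=heme_atoms,
        warnings=warnings,
        source=path.name,
    )
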