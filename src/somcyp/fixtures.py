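"""Self-contained synthetic inputs: toy active sites, poses, molecules.

Everything the pipeline consumes can be generated here with no download:
a minimal CYP3A4-like PDB (heme iron plus the named residues and
waters), multi-record SDF pose ensembles with exactly placed site–iron
distances, and a set of reference molecules with exact-symmetry
geometries (Td methane, eclipsed ethane) built from ideal internal
coordinates.  All outputs are deterministic functions of their spec.

These fixtures are synthetic stand-ins for docking output and a real
CYP3A4 crystal structure: they honour every downstream contract but make
no claim of structural realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chemio import Bond, InputError, LigandPose, Molecule, molecule_to_molblock

__all__ = [
    "FixtureSpec",
    "PosePlacement",
    "FixtureSpecError",
    "make_toy_active_site",
    "make_pose_set",
    "reference_molecules",
]

CC = 1.530  # sp3 C-C bond, Å
CH = 1.090
CN = 1.470
CO_DOUBLE = 1.220
TET = math.degrees(math.acos(-1.0 / 3.0))  # 109.471...


class FixtureSpecError(InputError):
    pass


# ---------------------------------------------------------------------------
# geometry helpers

def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Right-handed rotation matrix about `axis` by `angle_deg`."""
    u = _unit(axis)
    c, s = math.cos(math.radians(angle_deg)), math.sin(math.radians(angle_deg))
    ux, uy, uz = u
    k = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return c * np.eye(3) + s * k + (1 - c) * np.outer(u, u)


def _complete_tetrahedron(u1: np.ndarray, u2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit directions completing a tetrahedron around two given bonds."""
    w1 = _unit(u1 + u2)
    w2 = _unit(np.cross(u1, u2))
    a, b = 1.0 / math.sqrt(3.0), math.sqrt(2.0 / 3.0)
    return -a * w1 + b * w2, -a * w1 - b * w2


def _methyl_hydrogens(carbon: np.ndarray, attach_dir: np.ndarray,
                      ref_perp: np.ndarray, phase_deg: float = 0.0) -> list[np.ndarray]:
    """Three H positions on a methyl carbon; attach_dir points C -> heavy atom."""
    axis = _unit(attach_dir)
    perp = _unit(ref_perp - np.dot(ref_perp, axis) * axis)
    tilted = (math.cos(math.radians(TET)) * axis
              + math.sin(math.radians(TET)) * perp)  # at angle TET from the bond
    out = []
    for k in range(3):
        rot = rotation_about_axis(axis, phase_deg + 120.0 * k)
        out.append(carbon + CH * _unit(rot @ tilted))
    return out


# ---------------------------------------------------------------------------
# reference molecules

def _methane() -> Molecule:
    d = CH / math.sqrt(3.0)
    coords = np.array([
        [0.0, 0.0, 0.0],
        [d, d, d], [d, -d, -d], [-d, d, -d], [-d, -d, d],
    ])
    bonds = [Bond(0, k, 1.0) for k in (1, 2, 3, 4)]
    return Molecule(["C", "H", "H", "H", "H"], coords, bonds, name="methane")


def _eclipsed_ethane() -> Molecule:
    half = CC / 2.0
    c1, c2 = np.array([0.0, 0.0, half]), np.array([0.0, 0.0, -half])
    theta = math.radians(180.0 - TET)  # H polar angle from the C-C axis
    coords = [c1, c2]
    symbols = ["C", "C"]
    bonds = [Bond(0, 1, 1.0)]
    for ci, (center, zsign) in enumerate([(c1, 1.0), (c2, -1.0)]):
        for k in range(3):
            phi = math.radians(120.0 * k)  # same azimuths top/bottom: eclipsed
            direction = np.array([
                math.sin(theta) * math.cos(phi),
                math.sin(theta) * math.sin(phi),
                zsign * math.cos(theta),
            ])
            coords.append(center + CH * direction)
            symbols.append("H")
            bonds.append(Bond(ci, len(symbols) - 1, 1.0))
    return Molecule(symbols, np.array(coords), bonds, name="eclipsed-ethane")


def _propane() -> Molecule:
    half_angle = math.radians(TET / 2.0)
    u1 = np.array([math.sin(half_angle), 0.0, math.cos(half_angle)])
    u2 = np.array([-math.sin(half_angle), 0.0, math.cos(half_angle)])
    c2 = np.zeros(3)
    c1, c3 = CC * u1, CC * u2
    symbols = ["C", "C", "C"]
    coords = [c1, c2, c3]
    bonds = [Bond(0, 1, 1.0), Bond(1, 2, 1.0)]

    def add_h(pos):
        symbols.append("H")
        coords.append(pos)

    h1, h2 = _complete_tetrahedron(u1, u2)
    add_h(c2 + CH * h1); bonds.append(Bond(1, len(symbols) - 1, 1.0))
    add_h(c2 + CH * h2); bonds.append(Bond(1, len(symbols) - 1, 1.0))
    for carbon_idx, center, attach in ((0, c1, c2 - c1), (2, c3, c2 - c3)):
        for pos in _methyl_hydrogens(center, attach, np.array([0.0, 1.0, 0.0])):
            add_h(pos)
            bonds.append(Bond(carbon_idx, len(symbols) - 1, 1.0))
    return Molecule(symbols, np.array(coords), bonds, name="propane")


def _trimethylamine() -> Molecule:
    n = np.zeros(3)
    symbols = ["N"]
    coords = [n]
    bonds: list[Bond] = []
    theta = math.radians(TET)
    for k in range(3):
        phi = math.radians(120.0 * k)
        direction = np.array([
            math.sin(theta) * math.cos(phi),
            math.sin(theta) * math.sin(phi),
            math.cos(theta),
        ])
        c = n + CN * direction
        symbols.append("C")
        coords.append(c)
        c_idx = len(symbols) - 1
        bonds.append(Bond(0, c_idx, 1.0))
        for pos in _methyl_hydrogens(c, n - c, np.array([0.0, 0.0, 1.0])):
            symbols.append("H")
            coords.append(pos)
            bonds.append(Bond(c_idx, len(symbols) - 1, 1.0))
    return Molecule(symbols, np.array(coords), bonds, name="trimethylamine")


def _hexagon(radius: float) -> list[np.ndarray]:
    return [
        radius * np.array([math.cos(math.radians(60 * k)),
                           math.sin(math.radians(60 * k)), 0.0])
        for k in range(6)
    ]


def _toluene() -> Molecule:
    ring = _hexagon(1.395)
    symbols = ["C"] * 6
    coords = list(ring)
    bonds = [Bond(k, (k + 1) % 6, 1.5) for k in range(6)]  # aromatic ring
    # methyl on C0, ring hydrogens on C1..C5
    c0 = ring[0]
    cm = c0 + 1.51 * _unit(c0)
    symbols.append("C")
    coords.append(cm)
    cm_idx = len(symbols) - 1
    bonds.append(Bond(0, cm_idx, 1.0))
    for k in range(1, 6):
        h = ring[k] + 1.08 * _unit(ring[k])
        symbols.append("H")
        coords.append(h)
        bonds.append(Bond(k, len(symbols) - 1, 1.0))
    for pos in _methyl_hydrogens(cm, c0 - cm, np.array([0.0, 0.0, 1.0])):
        symbols.append("H")
        coords.append(pos)
        bonds.append(Bond(cm_idx, len(symbols) - 1, 1.0))
    return Molecule(symbols, np.array(coords), bonds, name="toluene")


def _cyclohexanone() -> Molecule:
    # chair ring; C0 is the carbonyl carbon
    z0 = 0.25
    radius = math.sqrt(CC**2 - 4 * z0**2) / math.sqrt(2.0 - 2.0 * math.cos(math.radians(60.0)))
    ring = [
        np.array([radius * math.cos(math.radians(60 * k)),
                  radius * math.sin(math.radians(60 * k)),
                  z0 * (-1.0) ** k])
        for k in range(6)
    ]
    symbols = ["C"] * 6
    coords = list(ring)
    bonds = [Bond(k, (k + 1) % 6, 1.0) for k in range(6)]
    # carbonyl oxygen on C0, pointing outward in the ring plane
    outward = _unit(np.array([ring[0][0], ring[0][1], 0.0]))
    o = ring[0] + CO_DOUBLE * outward
    symbols.append("O")
    coords.append(o)
    bonds.append(Bond(0, 6, 2.0))
    for k in range(1, 6):
        u1 = _unit(ring[(k + 1) % 6] - ring[k])
        u2 = _unit(ring[k - 1] - ring[k])
        for direction in _complete_tetrahedron(u1, u2):
            symbols.append("H")
            coords.append(ring[k] + CH * direction)
            bonds.append(Bond(k, len(symbols) - 1, 1.0))
    return Molecule(symbols, np.array(coords), bonds, name="cyclohexanone")


def reference_molecules() -> dict[str, Molecule]:
    """Named set of small molecules with embedded exact geometries."""
    mols = [
        _methane(), _eclipsed_ethane(), _propane(),
        _trimethylamine(), _toluene(), _cyclohexanone(),
    ]
    return {m.name: m for m in mols}


# ---------------------------------------------------------------------------
# toy active site

# Local residue templates: atom name -> offset (Å) from the anchor atom.
# Idealized side-chain geometry; only atoms the feature detectors read are
# guaranteed to be meaningful.
_RESIDUE_TEMPLATES: dict[str, tuple[str, dict[str, np.ndarray]]] = {
    "SER": ("OG", {
        "N": np.array([-1.9, 1.1, -2.1]), "CA": np.array([-1.2, 0.0, -2.4]),
        "C": np.array([-2.0, -1.2, -2.8]), "O": np.array([-3.2, -1.1, -2.9]),
        "CB": np.array([-0.4, -0.4, -1.2]), "OG": np.array([0.0, 0.0, 0.0]),
    }),
    "ARG": ("NH1", {
        "N": np.array([-5.6, 1.0, -1.6]), "CA": np.array([-5.0, 0.0, -2.4]),
        "C": np.array([-5.8, -1.3, -2.4]), "O": np.array([-7.0, -1.3, -2.5]),
        "CB": np.array([-3.6, -0.2, -1.9]), "CG": np.array([-2.8, 0.9, -1.3]),
        "CD": np.array([-1.5, 0.5, -0.8]), "NE": np.array([-0.9, 1.5, 0.0]),
        "CZ": np.array([-0.3, 1.2, 1.1]),
        "NH1": np.array([0.0, 0.0, 0.0]),
        "NH2": np.array([-0.2, 2.2, 2.0]),
    }),
    "ILE": ("O", {
        "N": np.array([-1.2, 1.8, 0.9]), "CA": np.array([-1.8, 0.9, 0.0]),
        "C": np.array([-1.2, -0.4, 0.2]), "O": np.array([0.0, 0.0, 0.0]),
        "CB": np.array([-3.3, 0.9, 0.2]), "CG1": np.array([-4.0, 2.1, -0.4]),
        "CG2": np.array([-3.9, -0.4, -0.3]), "CD1": np.array([-5.5, 2.1, -0.2]),
    }),
    "GLU": ("OE1", {
        "N": np.array([-4.6, 1.5, -1.9]), "CA": np.array([-4.2, 0.5, -2.8]),
        "C": np.array([-5.0, -0.8, -2.7]), "O": np.array([-6.2, -0.8, -2.9]),
        "CB": np.array([-2.8, 0.2, -2.4]), "CG": np.array([-2.0, 1.2, -1.6]),
        "CD": np.array([-0.7, 0.7, -1.1]),
        "OE1": np.array([0.0, 0.0, 0.0]),
        "OE2": np.array([-0.4, 1.0, -2.2]),
    }),
}
_RESNAME_BY_LABEL = {"Arg": "ARG", "Ser": "SER", "Ile": "ILE", "Glu": "GLU", "Phe": "PHE"}


@dataclass
class FixtureSpec:
    """What the toy active site contains and where.

    residues: label like "Ser119" -> anchor-atom position.  waters: water
    residue number -> oxygen position.  phe_residues: label -> ring-center
    position.  The heme is emitted as FE plus four pyrrole-like nitrogens.
    """

    fe_position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    residues: dict[str, np.ndarray] = field(default_factory=dict)
    waters: dict[int, np.ndarray] = field(default_factory=dict)
    phe_residues: dict[str, np.ndarray] = field(default_factory=dict)
    include_fe: bool = True
    seed: int = 0


def _parse_residue_label(label: str) -> tuple[str, int]:
    head = label.rstrip("0123456789")
    num = label[len(head):]
    resname = _RESNAME_BY_LABEL.get(head.capitalize())
    if resname is None or not num:
        raise FixtureSpecError(
            f"unsupported residue label {label!r} "
            f"(expected e.g. Ser119, Arg105, Phe57)"
        )
    return resname, int(num)


def _pdb_line(serial: int, name: str, resname: str, chain: str, resseq: int,
              pos: np.ndarray, element: str, hetatm: bool = False) -> str:
    record = "HETATM" if hetatm else "ATOM  "
    name_field = f" {name:<3s}" if len(name) < 4 and len(element) == 1 else f"{name:<4s}"
    return (
        f"{record}{serial:5d} {name_field} {resname:>3s} {chain}{resseq:4d}    "
        f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2s}"
    )


def make_toy_active_site(spec: FixtureSpec, path: str | Path) -> Path:
    """Emit a minimal CYP3A4-like PDB parseable by `extract_active_site`."""
    if not spec.include_fe:
        raise FixtureSpecError(
            "a toy active site must contain the heme iron: downstream "
            "extraction treats a missing FE as fatal"
        )
    lines: list[str] = ["REMARK   1 somcyp synthetic toy active site"]
    serial = 1
    fe = np.asarray(spec.fe_position, float)

    for label in sorted(spec.residues):
        resname, resseq = _parse_residue_label(label)
        if resname == "PHE":
            raise FixtureSpecError(
                f"{label}: phenylalanines belong in spec.phe_residues"
            )
        anchor_name, template = _RESIDUE_TEMPLATES[resname]
        anchor = np.asarray(spec.residues[label], float)
        for name, offset in template.items():
            pos = anchor + offset
            lines.append(_pdb_line(serial, name, resname, "A", resseq, pos, name[0]))
            serial += 1

    for label in sorted(spec.phe_residues):
        resname, resseq = _parse_residue_label(label)
        if resname != "PHE":
            raise FixtureSpecError(f"{label}: not a phenylalanine label")
        center = np.asarray(spec.phe_residues[label], float)
        ring = _hexagon(1.39)
        names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
        order = [0, 1, 5, 2, 4, 3]  # CG, CD1, CD2, CE1, CE2, CZ around the ring
        for name, k in zip(names, order):
            lines.append(
                _pdb_line(serial, name, "PHE", "A", resseq, center + ring[k], "C")
            )
            serial += 1

    # minimal heme: FE plus four square-planar nitrogens
    lines.append(_pdb_line(serial, "FE", "HEM", "A", 508, fe, "Fe", hetatm=True))
    serial += 1
    for name, offset in (
        ("NA", (2.0, 0.0, 0.0)), ("NB", (0.0, 2.0, 0.0)),
        ("NC", (-2.0, 0.0, 0.0)), ("ND", (0.0, -2.0, 0.0)),
    ):
        lines.append(
            _pdb_line(serial, name, "HEM", "A", 508, fe + np.array(offset), "N", hetatm=True)
        )
        serial += 1

    for num in sorted(spec.waters):
        pos = np.asarray(spec.waters[num], float)
        lines.append(_pdb_line(serial, "O", "HOH", "W", num, pos, "O", hetatm=True))
        serial += 1

    lines.append("END")
    out = Path(path)
    out.write_text("\n".join(lines) + "\n")
    return out


# ---------------------------------------------------------------------------
# pose sets

@dataclass
class PosePlacement:
    """One rigid placement of the substrate.

    Either give an explicit rigid `transform` (rotation, translation), or a
    target: rotate by `rotation` about the substrate centroid, then
    translate so `carbon_index` sits at fe_position + fe_distance *
    direction (distance honoured to < 1e-6 Å by construction).
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray | None = None  # explicit mode when set
    carbon_index: int | None = None
    fe_distance: float | None = None
    direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    score: float | None = None

    def validate(self) -> None:
        r = np.asarray(self.rotation, float)
        if r.shape != (3, 3) or not np.allclose(r @ r.T, np.eye(3), atol=1e-8) \
                or not math.isclose(float(np.linalg.det(r)), 1.0, abs_tol=1e-8):
            raise FixtureSpecError(
                "placement rotation is not a proper rigid rotation "
                "(orthonormal, det +1)"
            )
        if self.translation is None:
            if self.carbon_index is None or self.fe_distance is None:
                raise FixtureSpecError(
                    "placement needs either an explicit translation or "
                    "(carbon_index, fe_distance)"
                )
            if self.fe_distance < 0:
                raise FixtureSpecError("requested site-Fe distance must be >= 0")


def make_pose_set(
    substrate: Molecule,
    placements: list[PosePlacement],
    path: str | Path,
    fe_position=(0.0, 0.0, 0.0),
    score_property: str = "ChemScore",
) -> Path:
    """Write a multi-record SDF V2000 pose file; record order = rank order."""
    fe = np.asarray(fe_position, float)
    blocks: list[str] = []
    for k, placement in enumerate(placements, start=1):
        placement.validate()
        rot = np.asarray(placement.rotation, float)
        centroid = substrate.coords.mean(axis=0)
        rotated = (substrate.coords - centroid) @ rot.T + centroid
        if placement.translation is not None:
            coords = rotated + np.asarray(placement.translation, float)
        else:
            target = fe + placement.fe_distance * _unit(placement.direction)
            coords = rotated + (target - rotated[placement.carbon_index])
        pose_mol = Molecule(
            list(substrate.symbols), coords, list(substrate.bonds),
            list(substrate.charges), name=f"{substrate.name}-pose{k}",
        )
        block = molecule_to_molblock(pose_mol)
        if placement.score is not None:
            block += f"\n>  <{score_property}>\n{placement.score:.4f}\n"
        blocks.append(block + "\n$$$$\n")
    out = Path(path)
    out.write_text("".join(blocks))
    return out
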