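"""Per-pose qualification signals: site–heme distances and key features.

A candidate carbon is accessible in a docking pose when it sits within a
distance window of the heme iron; the pose itself is anchored in the
cavity when it shows at least one key interaction feature — a hydrogen
bond to one of the named residues/waters, or a lipophilic contact with
the Phe-cluster roof or the heme face.  This module computes those
signals for one pose at a time; aggregation over the pose ensemble
belongs to the predictor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .active_site import ActiveSiteModel
from .chemio import InputError, LigandPose

__all__ = [
    "HBondCriteria",
    "LipophilicCriteria",
    "HBondFeature",
    "LipophilicFeature",
    "PoseFeatureRecord",
    "site_heme_distance",
    "detect_hydrogen_bonds",
    "detect_lipophilic_contacts",
    "pose_feature_record",
    "qualifying_pose_fraction",
    "features_to_frame",
]

DEFAULT_DISTANCE_WINDOW = (2.5, 7.5)  # Å, endpoints inclusive


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria (standard values; configurable)."""

    max_donor_acceptor_distance: float = 3.5  # Å
    min_donor_angle: float = 120.0  # degrees, at the donated hydrogen

    def __post_init__(self):
        if self.max_donor_acceptor_distance <= 0:
            raise ValueError("H-bond distance cutoff must be positive")
        if not 0 < self.min_donor_angle <= 180:
            raise ValueError("H-bond angle must lie in (0, 180]")


@dataclass(frozen=True)
class LipophilicCriteria:
    max_contact_distance: float = 4.5  # Å, carbon–carbon
    min_contact_count: int = 3

    def __post_init__(self):
        if self.max_contact_distance <= 0:
            raise ValueError("lipophilic distance cutoff must be positive")
        if self.min_contact_count < 1:
            raise ValueError("lipophilic contact count must be >= 1")


@dataclass(frozen=True)
class HBondFeature:
    ligand_atom: int
    partner: str  # e.g. "Ser119:OG" or "HOH-623:O"
    distance: float  # Å, ligand polar atom to partner atom
    angle: float | None  # degrees at H when the ligand donates, else None
    ligand_is_donor: bool


@dataclass(frozen=True)
class LipophilicFeature:
    ligand_atom: int  # closest ligand carbon
    partner: str  # "Phe-cluster" or "heme"
    distance: float  # Å, closest contact
    n_contacts: int


@dataclass
class PoseFeatureRecord:
    pose_rank: int
    hbond_features: list[HBondFeature]
    lipophilic_features: list[LipophilicFeature]
    site_distances: dict[int, float]  # candidate carbon index -> Fe distance

    @property
    def has_key_feature(self) -> bool:
        return bool(self.hbond_features) or bool(self.lipophilic_features)


def site_heme_distance(pose: LigandPose, carbon_index: int, site: ActiveSiteModel) -> float:
    """Euclidean Fe→carbon distance in Å."""
    m = pose.molecule
    if not (0 <= carbon_index < m.n_atoms):
        raise IndexError(f"atom index {carbon_index} out of range (n={m.n_atoms})")
    if m.symbols[carbon_index] != "C":
        raise InputError(
            f"atom {carbon_index} is {m.symbols[carbon_index]}, not carbon; "
            "site–heme distances are defined for candidate carbons"
        )
    return float(np.linalg.norm(m.coords[carbon_index] - site.fe_position))


def _angle_at(h: np.ndarray, donor: np.ndarray, acceptor: np.ndarray) -> float:
    v1, v2 = donor - h, acceptor - h
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return 180.0
    c = float(np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0))
    return math.degrees(math.acos(c))


def detect_hydrogen_bonds(
    pose: LigandPose, site: ActiveSiteModel, crit: HBondCriteria | None = None
) -> list[HBondFeature]:
    """Hydrogen bonds between ligand N/O atoms and the named partners.

    When the ligand atom carries hydrogens it is evaluated as the donor:
    donor–acceptor distance plus D–H...A angle.  A ligand N/O without
    hydrogens (e.g. a carbonyl oxygen) is evaluated as acceptor on the
    distance criterion alone, because the crystallographic protein model
    and waters carry no hydrogens to define an angle.  At most one feature
    is emitted per (ligand atom, partner atom) pair.
    """
    crit = crit or HBondCriteria()
    m = pose.molecule
    features: list[HBondFeature] = []

    partners = site.hbond_partner_atoms()
    water_partners = [(f"HOH-{num}:O", pos) for num, pos in site.waters.items()]

    for i, sym in enumerate(m.symbols):
        if sym not in ("N", "O"):
            continue
        hydrogens = m.hydrogens_on(i)
        for label, ppos in partners + water_partners:
            d = float(np.linalg.norm(m.coords[i] - ppos))
            if d > crit.max_donor_acceptor_distance:
                continue
            is_water = label.startswith("HOH-")
            if hydrogens and not is_water:
                best = max(
                    _angle_at(m.coords[h], m.coords[i], ppos) for h in hydrogens
                )
                if best >= crit.min_donor_angle:
                    features.append(HBondFeature(i, label, d, best, True))
                # misaligned ligand donor: no feature for this pair
            elif hydrogens and is_water:
                # waters: distance criterion alone (no hydrogens either side)
                features.append(HBondFeature(i, label, d, None, True))
            else:
                features.append(HBondFeature(i, label, d, None, False))
    return features


def detect_lipophilic_contacts(
    pose: LigandPose,
    site: ActiveSiteModel,
    crit: LipophilicCriteria | None = None,
    heme_carbons: set[int] | None = None,
) -> list[LipophilicFeature]:
    """Phe-cluster and heme lipophilic contact features.

    A feature fires when at least `min_contact_count` ligand-carbon /
    partner-atom pairs lie within `max_contact_distance`.  For the heme
    face the counted ligand carbons can be restricted (the predictor
    passes the candidate-site carbons: "hydrophobic toward the heme"
    refers to the metabolized face).
    """
    crit = crit or LipophilicCriteria()
    m = pose.molecule
    carbons = m.carbon_indices
    features: list[LipophilicFeature] = []
    if not carbons:
        return features

    def _check(ligand_idx: list[int], targets: np.ndarray, label: str):
        if not ligand_idx or targets.size == 0:
            return
        pts = m.coords[ligand_idx]
        dist = np.linalg.norm(pts[:, None, :] - targets[None, :, :], axis=2)
        mask = dist <= crit.max_contact_distance
        n = int(mask.sum())
        if n >= crit.min_contact_count:
            flat = int(np.argmin(dist))
            features.append(
                LipophilicFeature(
                    ligand_atom=ligand_idx[flat // dist.shape[1]],
                    partner=label,
                    distance=float(dist.min()),
                    n_contacts=n,
                )
            )

    _check(carbons, site.phe_ring_positions(), "Phe-cluster")
    heme_idx = sorted(heme_carbons) if heme_carbons is not None else carbons
    _check(heme_idx, site.heme_positions(), "heme")
    return features


def pose_feature_record(
    pose: LigandPose,
    site: ActiveSiteModel,
    candidate_carbons: list[int],
    hbond_criteria: HBondCriteria | None = None,
    lipophilic_criteria: LipophilicCriteria | None = None,
) -> PoseFeatureRecord:
    """All qualification signals of one pose in a single record."""
    return PoseFeatureRecord(
        pose_rank=pose.rank,
        hbond_features=detect_hydrogen_bonds(pose, site, hbond_criteria),
        lipophilic_features=detect_lipophilic_contacts(
            pose, site, lipophilic_criteria, heme_carbons=set(candidate_carbons)
        ),
        site_distances={
            c: site_heme_distance(pose, c, site) for c in candidate_carbons
        },
    )


def pose_weights(n: int, scheme: str = "uniform") -> np.ndarray:
    """Normalized per-pose weights; rank 1 first."""
    if scheme == "uniform":
        w = np.ones(n)
    elif scheme in ("linear_rank", "rank"):
        w = np.arange(n, 0, -1, dtype=float)  # n, n-1, ..., 1
    else:
        raise ValueError(f"unknown weight scheme {scheme!r}")
    return w / w.sum()


def qualifying_pose_fraction(
    carbon_index: int,
    poses: list[LigandPose],
    site: ActiveSiteModel,
    window: tuple[float, float] = DEFAULT_DISTANCE_WINDOW,
    weights: str = "uniform",
) -> float:
    """Weighted fraction of poses with the site in the Fe-distance window.

    Weights are normalized to sum 1 over the pose set; the window is a
    closed interval.  Uniform weights give the plain in-window fraction.
    """
    if not poses:
        raise InputError("qualifying_pose_fraction requires a nonempty pose set")
    low, high = window
    w = pose_weights(len(poses), weights)
    total = 0.0
    for k, pose in enumerate(poses):
        d = site_heme_distance(pose, carbon_index, site)
        if low <= d <= high:
            total += w[k]
    return float(total)


def features_to_frame(records: list[PoseFeatureRecord]) -> pd.DataFrame:
    """Flatten feature records to a table (TSV/JSON export)."""
    rows = []
    for rec in records:
        for f in rec.hbond_features:
            rows.append(
                dict(pose_rank=rec.pose_rank, feature="hbond", partner=f.partner,
                     ligand_atom=f.ligand_atom, distance=round(f.distance, 3),
                     angle=None if f.angle is None else round(f.angle, 1),
                     n_contacts=None)
            )
        for f in rec.lipophilic_features:
            rows.append(
                dict(pose_rank=rec.pose_rank, feature="lipophilic", partner=f.partner,
                     ligand_atom=f.ligand_atom, distance=round(f.distance, 3),
                     angle=None, n_contacts=f.n_contacts)
            )
    return pd.DataFrame(
        rows,
        columns=["pose_rank", "feature", "partner", "ligand_atom",
                 "distance", "angle", "n_contacts"],
    )
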