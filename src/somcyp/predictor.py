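"""The mechanism-based site-of-metabolism model.

Workflow: enumerate candidate carbons by reaction type (aliphatic
hydroxylation at sp3 C–H, N-dealkylation at H-bearing carbons alpha to
nitrogen), qualify them against the docked pose ensemble (site–heme-iron
distance window plus at least one key interaction feature in the same
pose), expand to carbons one bond away, rank the surviving sites by
hydrogen-abstraction energy, and report the top-k (default 3) as the
predicted sites of metabolism.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__ as _ENGINE_VERSION
from .active_site import ActiveSiteModel
from .chemio import (
    HydrogenClass,
    InputError,
    LigandPose,
    Molecule,
    adjacent_carbons,
    hydrogen_equivalence_classes,
)
from .cndo import CndoParameters, rank_hydrogen_classes, HARTREE_KCAL
from .pose_features import (
    DEFAULT_DISTANCE_WINDOW,
    HBondCriteria,
    LipophilicCriteria,
    pose_feature_record,
    qualifying_pose_fraction,
)

__all__ = [
    "CandidateSite",
    "PredictorConfig",
    "QualifiedSite",
    "PredictedSite",
    "Prediction",
    "enumerate_candidate_sites",
    "qualify_sites",
    "expand_adjacent_sites",
    "predict_sites",
]

ALIPHATIC_HYDROXYLATION = "aliphatic_hydroxylation"
N_DEALKYLATION = "n_dealkylation"
REACTION_TYPES = (ALIPHATIC_HYDROXYLATION, N_DEALKYLATION)


@dataclass(frozen=True)
class CandidateSite:
    carbon_index: int
    reaction_type: str
    hydrogen_class: HydrogenClass


@dataclass
class PredictorConfig:
    """Tunables of the prediction model (defaults follow the method)."""

    distance_window: tuple[float, float] = DEFAULT_DISTANCE_WINDOW
    poses_kept: int = 10
    require_feature: bool = True
    adjacency_expansion: bool = True
    k: int = 3
    weight_scheme: str = "uniform"
    hbond_criteria: HBondCriteria = field(default_factory=HBondCriteria)
    lipophilic_criteria: LipophilicCriteria = field(default_factory=LipophilicCriteria)

    def __post_init__(self):
        low, high = self.distance_window
        if not low < high:
            raise ValueError("distance window must satisfy low < high")
        if self.poses_kept < 1 or self.k < 1:
            raise ValueError("poses_kept and k must be >= 1")

    @classmethod
    def from_dict(cls, data: dict) -> "PredictorConfig":
        data = dict(data)
        kwargs = {}
        if "distance_window" in data:
            kwargs["distance_window"] = tuple(data.pop("distance_window"))
        if "hbond" in data:
            kwargs["hbond_criteria"] = HBondCriteria(**data.pop("hbond"))
        if "lipophilic" in data:
            kwargs["lipophilic_criteria"] = LipophilicCriteria(**data.pop("lipophilic"))
        for key in ("poses_kept", "require_feature", "adjacency_expansion", "k",
                    "weight_scheme"):
            if key in data:
                kwargs[key] = data.pop(key)
        if data:
            raise InputError(f"unknown config keys: {sorted(data)}")
        return cls(**kwargs)

    def digest(self) -> str:
        payload = {
            "distance_window": list(self.distance_window),
            "poses_kept": self.poses_kept,
            "require_feature": self.require_feature,
            "adjacency_expansion": self.adjacency_expansion,
            "k": self.k,
            "weight_scheme": self.weight_scheme,
            "hbond": asdict(self.hbond_criteria),
            "lipophilic": asdict(self.lipophilic_criteria),
        }
        return hashlib.sha1(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class QualifiedSite:
    site: CandidateSite
    pose_fraction: float
    flags: dict  # distance / hbond / lipophilic / adjacency_derived


@dataclass
class PredictedSite:
    site: CandidateSite
    delta_h: float  # hartree
    delta_h_kcal: float
    pose_fraction: float
    flags: dict
    rank: int  # dense rank over carbons, 1 = most labile
    in_top_k: bool


@dataclass
class Prediction:
    substrate: str
    entries: list[PredictedSite]
    k: int
    provenance: dict
    warnings: list[str] = field(default_factory=list)

    def top(self, k: int | None = None) -> list[PredictedSite]:
        k = k or self.k
        return [e for e in self.entries if e.rank <= k]

    def top_carbons(self, k: int | None = None) -> list[int]:
        seen: list[int] = []
        for e in self.top(k):
            if e.site.carbon_index not in seen:
                seen.append(e.site.carbon_index)
        return seen

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                rank=e.rank,
                carbon_index=e.site.carbon_index,
                reaction_type=e.site.reaction_type,
                delta_h_hartree=round(e.delta_h, 8),
                delta_h_kcal=round(e.delta_h_kcal, 4),
                pose_fraction=round(e.pose_fraction, 6),
                hbond=e.flags.get("hbond", False),
                lipophilic=e.flags.get("lipophilic", False),
                adjacency_derived=e.flags.get("adjacency_derived", False),
                in_top_k=e.in_top_k,
            )
            for e in self.entries
        ]
        return pd.DataFrame(
            rows,
            columns=["rank", "carbon_index", "reaction_type", "delta_h_hartree",
                     "delta_h_kcal", "pose_fraction", "hbond", "lipophilic",
                     "adjacency_derived", "in_top_k"],
        )

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "substrate": self.substrate,
            "k": self.k,
            "sites": self.to_frame().to_dict(orient="records"),
            "provenance": self.provenance,
            "warnings": self.warnings,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------

def enumerate_candidate_sites(
    m: Molecule, reaction_types: tuple[str, ...] = REACTION_TYPES
) -> list[CandidateSite]:
    """All candidate carbons, per reaction type.

    Aliphatic hydroxylation: sp3 carbons bearing >= 1 hydrogen (aromatic
    and otherwise unsaturated carbons are out of scope).  N-dealkylation:
    H-bearing sp3 carbons single-bonded to a nitrogen; a carbon may appear
    under both types.
    """
    for rt in reaction_types:
        if rt not in REACTION_TYPES:
            raise InputError(f"unknown reaction type {rt!r}")
    class_by_carbon = {
        cls.carbon_index: cls for cls in hydrogen_equivalence_classes(m)
    }
    sites: list[CandidateSite] = []
    for carbon in m.carbon_indices:
        cls = class_by_carbon.get(carbon)
        if cls is None or not m.is_sp3_carbon(carbon):
            continue
        bonded_to_n = any(
            m.symbols[j] == "N" and b.order == 1
            for b in m.bonds_of(carbon)
            for j in [b.other(carbon)]
        )
        if ALIPHATIC_HYDROXYLATION in reaction_types:
            sites.append(CandidateSite(carbon, ALIPHATIC_HYDROXYLATION, cls))
        if N_DEALKYLATION in reaction_types and bonded_to_n:
            sites.append(CandidateSite(carbon, N_DEALKYLATION, cls))
    return sites


def qualify_sites(
    sites: list[CandidateSite],
    poses: list[LigandPose],
    site_model: ActiveSiteModel,
    config: PredictorConfig | None = None,
) -> list[QualifiedSite]:
    """Sites with >= 1 kept pose inside the distance window and anchored.

    A pose "anchors" the substrate when it exhibits at least one key
    feature (hydrogen bond or lipophilic contact); feature attribution is
    pose-level, so one anchor qualifies every in-window site of that pose.
    With require_feature=False, distance alone qualifies.
    """
    config = config or PredictorConfig()
    if not poses:
        raise InputError("qualify_sites requires a nonempty pose set")
    kept = poses[: config.poses_kept]
    candidate_carbons = [s.carbon_index for s in sites]
    records = [
        pose_feature_record(
            pose, site_model, candidate_carbons,
            config.hbond_criteria, config.lipophilic_criteria,
        )
        for pose in kept
    ]
    low, high = config.distance_window
    qualified: list[QualifiedSite] = []
    for site in sites:
        hit_hbond = hit_lipo = False
        any_pose = False
        for rec in records:
            d = rec.site_distances[site.carbon_index]
            if not (low <= d <= high):
                continue
            if config.require_feature and not rec.has_key_feature:
                continue
            any_pose = True
            hit_hbond |= bool(rec.hbond_features)
            hit_lipo |= bool(rec.lipophilic_features)
        if any_pose:
            fraction = qualifying_pose_fraction(
                site.carbon_index, kept, site_model,
                window=config.distance_window, weights=config.weight_scheme,
            )
            qualified.append(
                QualifiedSite(
                    site=site,
                    pose_fraction=fraction,
                    flags=dict(distance=True, hbond=hit_hbond,
                               lipophilic=hit_lipo, adjacency_derived=False),
                )
            )
    return qualified


def expand_adjacent_sites(
    qualified: list[QualifiedSite],
    all_candidates: list[CandidateSite],
    m: Molecule,
) -> list[QualifiedSite]:
    """Add candidate sites one bond away from each qualified site.

    Derived sites inherit the best parent pose fraction and are flagged;
    they never seed further expansion, so the operation is idempotent.
    """
    present = {(q.site.carbon_index, q.site.reaction_type) for q in qualified}
    out = list(qualified)
    additions: dict[tuple[int, str], QualifiedSite] = {}
    for q in qualified:
        if q.flags.get("adjacency_derived"):
            continue
        for neighbor in sorted(adjacent_carbons(m, q.site.carbon_index)):
            for cand in all_candidates:
                if cand.carbon_index != neighbor:
                    continue
                key = (cand.carbon_index, cand.reaction_type)
                if key in present:
                    continue
                prev = additions.get(key)
                if prev is None or q.pose_fraction > prev.pose_fraction:
                    additions[key] = QualifiedSite(
                        site=cand,
                        pose_fraction=q.pose_fraction,
                        flags=dict(distance=False, hbond=False,
                                   lipophilic=False, adjacency_derived=True),
                    )
    out.extend(additions[k] for k in sorted(additions))
    return out


def predict_sites(
    m: Molecule,
    poses: list[LigandPose],
    site_model: ActiveSiteModel,
    params: CndoParameters | None = None,
    config: PredictorConfig | None = None,
    energy_table: dict[int, float] | None = None,
) -> Prediction:
    """Run the full mechanism-based model and return ranked predictions.

    Sites are ordered ascending by class dH_rxn; ties break by higher pose
    fraction, then lower carbon index.  Entries sharing a carbon (both
    reaction types) share one dense rank so duplicates never consume extra
    top-k positions.  `energy_table` (carbon index -> dH_rxn, hartree)
    bypasses the built-in engine.
    """
    config = config or PredictorConfig()
    warnings: list[str] = []
    candidates = enumerate_candidate_sites(m)
    provenance = {
        "substrate": m.name,
        "n_atoms": m.n_atoms,
        "config": config.digest(),
        "engine": f"somcyp-{_ENGINE_VERSION}",
        "energy_source": "table" if energy_table else "cndo2",
    }
    if not candidates:
        warnings.append(
            f"substrate {m.name!r} has no candidate sites "
            "(no sp3 C-H or N-alpha C-H carbons)"
        )
        return Prediction(m.name, [], config.k, provenance, warnings)

    qualified = qualify_sites(candidates, poses, site_model, config)
    if config.adjacency_expansion:
        qualified = expand_adjacent_sites(qualified, candidates, m)
    if not qualified:
        warnings.append(
            f"no site of {m.name!r} qualified under the distance window "
            f"{config.distance_window} and feature requirement"
        )
        return Prediction(m.name, [], config.k, provenance, warnings)

    # one energy per hydrogen class among the qualified sites
    needed = {}
    for q in qualified:
        needed[q.site.hydrogen_class.class_id] = q.site.hydrogen_class
    if energy_table is not None:
        energies = {}
        for cls in needed.values():
            if cls.carbon_index not in energy_table:
                raise InputError(
                    f"energy table lacks carbon {cls.carbon_index} "
                    f"(substrate {m.name!r})"
                )
            energies[cls.class_id] = float(energy_table[cls.carbon_index])
    else:
        ranked = rank_hydrogen_classes(m, sorted(needed.values(), key=lambda c: c.class_id), params)
        energies = {e.hydrogen_class.class_id: e.delta_h for e in ranked}

    # sort ascending by energy; energies closer than 1e-9 hartree (symmetry
    # images, fp noise) are ties broken by higher pose fraction then lower
    # carbon index
    by_energy = sorted(qualified, key=lambda q: energies[q.site.hydrogen_class.class_id])
    keyed: list[QualifiedSite] = []
    group: list[QualifiedSite] = []

    def _flush():
        group.sort(key=lambda q: (-q.pose_fraction, q.site.carbon_index,
                                  q.site.reaction_type))
        keyed.extend(group)

    for q in by_energy:
        e = energies[q.site.hydrogen_class.class_id]
        if group and e - energies[group[-1].site.hydrogen_class.class_id] > 1e-9:
            _flush()
            group = []
        group.append(q)
    _flush()
    # dense ranks per carbon: both reaction types of one carbon share a rank
    carbon_rank: dict[int, int] = {}
    for q in keyed:
        if q.site.carbon_index not in carbon_rank:
            carbon_rank[q.site.carbon_index] = len(carbon_rank) + 1
    entries = [
        PredictedSite(
            site=q.site,
            delta_h=energies[q.site.hydrogen_class.class_id],
            delta_h_kcal=energies[q.site.hydrogen_class.class_id] * HARTREE_KCAL,
            pose_fraction=q.pose_fraction,
            flags=q.flags,
            rank=carbon_rank[q.site.carbon_index],
            in_top_k=carbon_rank[q.site.carbon_index] <= config.k,
        )
        for q in keyed
    ]
    return Prediction(m.name, entries, config.k, provenance, warnings)
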