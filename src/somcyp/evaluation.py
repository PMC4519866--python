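"""Top-3 scoring protocol and accuracy tables.

A substrate prediction is counted correct when any experimentally known
metabolic site appears among the top three ranked positions; for
substrates with several observed metabolites one hit suffices.  Accuracy
is aggregated per reaction type and overall as Nc/N with the ratio in
percent to two decimals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .chemio import InputError
from .predictor import Prediction, REACTION_TYPES

__all__ = [
    "SiteAnnotation",
    "EvaluationReport",
    "AnnotationError",
    "score_substrate",
    "aggregate",
    "read_annotations",
    "accuracy_ratio",
]

CORRECT = "correct"
INCORRECT = "incorrect"


class AnnotationError(InputError):
    pass


@dataclass
class SiteAnnotation:
    """Experimentally known metabolic sites of one substrate."""

    substrate_id: str
    known_sites: list[tuple[int, str]]  # (carbon index, reaction type)
    set_id: str = "training"

    def __post_init__(self):
        if not self.known_sites:
            raise AnnotationError(
                f"substrate {self.substrate_id!r}: at least one known site required"
            )
        for carbon, rtype in self.known_sites:
            if rtype not in REACTION_TYPES:
                raise AnnotationError(
                    f"substrate {self.substrate_id!r}: unknown reaction type {rtype!r}"
                )

    @property
    def reaction_types(self) -> list[str]:
        seen = []
        for _, rt in self.known_sites:
            if rt not in seen:
                seen.append(rt)
        return seen


def accuracy_ratio(nc: int, n: int) -> float:
    """Percentage of correct predictions, rounded to 2 decimals."""
    if n <= 0:
        raise ValueError("N must be positive")
    if not 0 <= nc <= n:
        raise ValueError("Nc must satisfy 0 <= Nc <= N")
    return round(100.0 * nc / n, 2)


def score_substrate(pred: Prediction, ann: SiteAnnotation, k: int = 3) -> str:
    """'correct' iff any known site's carbon is in the top-k predictions.

    Matching is on carbon identity; adjacency-derived sites count as their
    own carbon.  The annotation must use the same atom indexing as the
    prediction's substrate.
    """
    n_atoms = pred.provenance.get("n_atoms")
    for carbon, _ in ann.known_sites:
        if n_atoms is not None and not 0 <= carbon < n_atoms:
            raise AnnotationError(
                f"substrate {ann.substrate_id!r}: annotated carbon {carbon} "
                f"out of range for a {n_atoms}-atom structure "
                "(check the atom-label map)"
            )
    top = set(pred.top_carbons(k))
    known = {carbon for carbon, _ in ann.known_sites}
    return CORRECT if top & known else INCORRECT


@dataclass
class EvaluationReport:
    """Nc/N/ratio per reaction type and overall, plus per-substrate verdicts."""

    rows: dict[str, tuple[int, int, float]]  # label -> (Nc, N, ratio %)
    verdicts: dict[str, str] = field(default_factory=dict)
    set_id: str | None = None

    def to_frame(self) -> pd.DataFrame:
        data = [
            dict(reaction_type=label, Nc=nc, N=n, ratio_pct=ratio)
            for label, (nc, n, ratio) in self.rows.items()
        ]
        return pd.DataFrame(data, columns=["reaction_type", "Nc", "N", "ratio_pct"])

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "set_id": self.set_id,
            "rows": {
                label: {"Nc": nc, "N": n, "ratio_pct": ratio}
                for label, (nc, n, ratio) in self.rows.items()
            },
            "verdicts": self.verdicts,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def aggregate(
    verdicts: Mapping[str, str],
    annotations: Mapping[str, SiteAnnotation],
    set_id: str | None = None,
) -> EvaluationReport:
    """Accuracy per reaction type and overall.

    A substrate with known sites of both reaction types is counted once in
    each type row but once overall, so overall Nc equals the sum of the
    type rows whenever reaction types partition the substrates.
    """
    for sid in verdicts:
        if sid not in annotations:
            raise AnnotationError(f"verdict for unannotated substrate {sid!r}")
    rows: dict[str, tuple[int, int, float]] = {}
    for rtype in REACTION_TYPES:
        members = [
            sid for sid, ann in annotations.items()
            if sid in verdicts and rtype in ann.reaction_types
        ]
        if members:
            nc = sum(verdicts[sid] == CORRECT for sid in members)
            rows[rtype] = (nc, len(members), accuracy_ratio(nc, len(members)))
    all_sids = [sid for sid in annotations if sid in verdicts]
    nc = sum(verdicts[sid] == CORRECT for sid in all_sids)
    rows["overall"] = (nc, len(all_sids), accuracy_ratio(nc, len(all_sids)))
    return EvaluationReport(rows=rows, verdicts=dict(verdicts), set_id=set_id)


def read_annotations(
    path: str | Path,
    label_maps: Mapping[str, Mapping[str, int]] | None = None,
) -> dict[str, SiteAnnotation]:
    """Read an annotation TSV: substrate_id, carbon_label, reaction_type, set_id.

    `label_maps` translates positional nomenclature (e.g. "C-6") to atom
    indices per substrate; numeric labels pass through directly.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"substrate_id", "carbon_label", "reaction_type", "set_id"}
    if not required.issubset(df.columns):
        raise AnnotationError(
            f"{path}: annotation file needs columns {sorted(required)}"
        )
    out: dict[str, SiteAnnotation] = {}
    grouped: dict[str, dict] = {}
    for _, row in df.iterrows():
        sid = row["substrate_id"]
        label = str(row["carbon_label"]).strip()
        if label_maps and sid in label_maps and label in label_maps[sid]:
            carbon = int(label_maps[sid][label])
        else:
            try:
                carbon = int(label)
            except ValueError as err:
                raise AnnotationError(
                    f"{path}: substrate {sid!r} carbon label {label!r} is not "
                    "numeric and has no entry in the label map"
                ) from err
        rec = grouped.setdefault(sid, {"sites": [], "set_id": row["set_id"]})
        rec["sites"].append((carbon, row["reaction_type"]))
    for sid, rec in grouped.items():
        out[sid] = SiteAnnotation(sid, rec["sites"], rec["set_id"])
    return out
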