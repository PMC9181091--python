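"""Combined prioritization of repurposing candidates.

Proximity results are filtered to those significantly associated with
the disease (empirical p strictly below alpha) and then ranked by a
three-key order: network similarity descending, GSEA score descending
(NA sorts below 0), and drug name ascending case-insensitively (drug id
as the final tie-break).  A radial-plot export places each candidate at
radius 1 - similarity, so the most proximal drugs sit at the center,
colored by GSEA score bucket.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .proximity import ProximityResult
from .signatures import GseaScore

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankedCandidate:
    """One prioritized drug with its rank and supporting scores."""

    rank: int
    drug_id: str
    drug_name: str
    similarity: float
    p_emp: float
    gsea: Optional[int]  # None = NA (no profile in the signature library)
    target_annotation: str = ""


def filter_significant(
    results: Sequence[ProximityResult], alpha: float = 0.05
) -> list[ProximityResult]:
    """Keep results with empirical p strictly below alpha."""
    if not 0 < alpha <= 1:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    kept = [r for r in results if r.p_emp < alpha]
    logger.info("significance filter: kept %d of %d drugs at p < %g", len(kept), len(results), alpha)
    return kept


def _sort_key(r: ProximityResult, gsea: Optional[int]):
    # NA (None) maps to -1 so it sorts below a GSEA score of 0
    g = -1 if gsea is None else gsea
    return (-r.similarity, -g, r.drug_name.lower(), r.drug_id)


def rank_candidates(
    results: Sequence[ProximityResult],
    gsea_scores: Mapping[str, GseaScore],
    annotations: Mapping[str, str] | None = None,
) -> list[RankedCandidate]:
    """Three-key total order: similarity desc, GSEA desc (NA last), name asc.

    ``gsea_scores`` may omit drugs (treated as NA).  Ranks are assigned
    1..K with no gaps; duplicate drug ids are an error.
    """
    ids = [r.drug_id for r in results]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate drug ids in results: {dupes}")
    annotations = annotations or {}

    def gsea_of(drug_id: str) -> Optional[int]:
        gs = gsea_scores.get(drug_id)
        return None if gs is None else gs.score

    ordered = sorted(results, key=lambda r: _sort_key(r, gsea_of(r.drug_id)))
    return [
        RankedCandidate(
            rank=i,
            drug_id=r.drug_id,
            drug_name=r.drug_name,
            similarity=r.similarity,
            p_emp=r.p_emp,
            gsea=gsea_of(r.drug_id),
            target_annotation=annotations.get(r.drug_id, ""),
        )
        for i, r in enumerate(ordered, start=1)
    ]


RANKED_COLUMNS = [
    "rank", "drug_name", "similarity", "p_value", "gsea_score", "drug_id", "target",
]


def ranked_to_frame(candidates: Sequence[RankedCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rank": c.rank,
                "drug_name": c.drug_name,
                "similarity": c.similarity,
                "p_value": c.p_emp,
                "gsea_score": "na" if c.gsea is None else c.gsea,
                "drug_id": c.drug_id,
                "target": c.target_annotation,
            }
            for c in candidates
        ],
        columns=RANKED_COLUMNS,
    )


def write_ranked(candidates: Sequence[RankedCandidate], path) -> None:
    ranked_to_frame(candidates).to_csv(path, sep="\t", index=False)


def read_ranked(path) -> list[RankedCandidate]:
    df = pd.read_csv(
        path, sep="\t", dtype={"drug_id": str, "drug_name": str, "gsea_score": str}
    )
    df["target"] = df.get("target", pd.Series(dtype=str)).fillna("")
    return [
        RankedCandidate(
            rank=int(row.rank),
            drug_id=row.drug_id,
            drug_name=row.drug_name,
            similarity=float(row.similarity),
            p_emp=float(row.p_value),
            gsea=None if row.gsea_score == "na" else int(row.gsea_score),
            target_annotation=str(row.target),
        )
        for row in df.itertuples()
    ]


def export_radial(
    candidates: Sequence[RankedCandidate], class_filter: str | None = None
) -> pd.DataFrame:
    """Plot-ready radial table: radius = 1 - similarity, color = GSEA bucket.

    ``class_filter`` keeps only candidates whose target annotation
    contains the given substring (case-insensitive), e.g. a drug class
    like a receptor family.
    """
    rows = []
    for c in candidates:
        if class_filter and class_filter.lower() not in c.target_annotation.lower():
            continue
        rows.append(
            {
                "drug_id": c.drug_id,
                "drug_name": c.drug_name,
                "radius": 1.0 - c.similarity,
                "color_key": "na" if c.gsea is None else str(c.gsea),
            }
        )
    return pd.DataFrame(rows, columns=["drug_id", "drug_name", "radius", "color_key"])
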