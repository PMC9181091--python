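"""Signature-reversal scoring of drugs against disease expression data.

Each disease expression dataset contributes a disease signature: the
genes differentially expressed between disease and control, split into
up- and down-regulated sets at a Benjamini-Hochberg adjusted p-value
threshold.  Each drug contributes a ranked gene list (most up-regulated
by treatment first).  A two-sided weighted Kolmogorov-Smirnov
connectivity score on [-1, 1] measures whether the drug's profile
mimics (+) or reverses (-) the disease signature; a drug reverses the
disease when the score is negative.  The integer "GSEA score" of a drug
is the number of datasets (0..N) whose signature it reverses, or NA if
the drug has no expression profile in the library at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DiseaseSignature:
    """Up/down differentially expressed gene sets for one dataset."""

    dataset_id: str
    up: frozenset
    down: frozenset
    alpha: float

    def __post_init__(self):
        if self.up & self.down:
            raise ValueError(f"{self.dataset_id}: up and down sets overlap")

    @property
    def empty(self) -> bool:
        return not (self.up or self.down)


@dataclass(frozen=True)
class DrugSignature:
    """Ranked expression profile of one drug treatment.

    ``ranked_genes`` is ordered most up-regulated first; ``scores`` is
    the aligned per-gene differential statistic, non-increasing.
    """

    drug_id: str
    ranked_genes: tuple
    scores: tuple
    profile_id: str = ""

    def __post_init__(self):
        if len(self.ranked_genes) != len(self.scores):
            raise ValueError("ranked_genes and scores must align")
        if len(set(self.ranked_genes)) != len(self.ranked_genes):
            raise ValueError(f"{self.drug_id}: duplicate genes in ranking")
        if any(a < b for a, b in zip(self.scores, self.scores[1:])):
            raise ValueError(f"{self.drug_id}: scores are not non-increasing")

    @classmethod
    def from_scores(cls, drug_id: str, gene_scores: Mapping, profile_id: str = "") -> "DrugSignature":
        # deterministic ordering: by descending score, gene id breaks ties
        items = sorted(gene_scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return cls(
            drug_id=drug_id,
            ranked_genes=tuple(g for g, _ in items),
            scores=tuple(float(s) for _, s in items),
            profile_id=profile_id,
        )


@dataclass(frozen=True)
class GseaScore:
    """Count of disease datasets a drug's signature reverses (None = NA)."""

    drug_id: str
    score: Optional[int]
    n_datasets: int

    def __post_init__(self):
        if self.score is not None and not (0 <= self.score <= self.n_datasets):
            raise ValueError(f"score {self.score} outside [0, {self.n_datasets}]")


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


DE_COLUMNS = ("gene_id", "effect", "p_raw")


def read_de_table(path) -> pd.DataFrame:
    """Differential-expression TSV with columns gene_id, effect, p_raw.

    ``effect`` is a signed statistic (log fold-change or just a sign);
    only its sign is used downstream.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing DE columns {missing}")
    return df


def select_de_genes(table: pd.DataFrame, alpha: float, dataset_id: str = "") -> DiseaseSignature:
    """BH-adjust raw p-values and split survivors into up/down gene sets.

    Selection is strict: adjusted p < alpha.  Genes with a zero effect
    cannot be assigned a direction and are dropped with a log message.
    An empty signature is returned (with a warning) rather than raised,
    so callers can decide whether to skip the dataset.
    """
    if table.empty:
        raise ValueError("empty DE table")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    adj = bh_adjust(table["p_raw"].to_numpy())
    sig = adj < alpha
    effect = table["effect"].to_numpy(dtype=float)
    up = frozenset(table.loc[sig & (effect > 0), "gene_id"])
    down = frozenset(table.loc[sig & (effect < 0), "gene_id"])
    n_zero = int(np.count_nonzero(sig & (effect == 0)))
    if n_zero:
        logger.info("%s: dropped %d significant genes with zero effect", dataset_id, n_zero)
    logger.info(
        "%s: %d up, %d down of %d genes at adjusted p < %g",
        dataset_id, len(up), len(down), len(table), alpha,
    )
    if not (up or down):
        logger.warning("%s: no genes survive adjusted p < %g", dataset_id, alpha)
    return DiseaseSignature(dataset_id=dataset_id, up=up, down=down, alpha=alpha)


def enrichment_score(ranked: DrugSignature, gene_set: Iterable, weight: float = 1.0) -> float:
    """Signed weighted-KS running-sum enrichment of a gene set in a ranking.

    Walking the ranked list, the running sum rises by |score|^weight
    (normalized over set members) at each set member and falls by
    1/(L - k) otherwise; the statistic is the extremum of the running
    sum, in [-1, 1].  Positive = the set concentrates at the top of the
    ranking, negative = at the bottom.
    """
    gene_set = set(gene_set)
    genes = ranked.ranked_genes
    L = len(genes)
    hit = np.fromiter((g in gene_set for g in genes), dtype=bool, count=L)
    k = int(hit.sum())
    if k == 0:
        raise ValueError(f"{ranked.drug_id}: gene set does not intersect the ranking")
    if k == L:
        return 1.0  # degenerate: every ranked gene is a member
    w = np.abs(np.asarray(ranked.scores, dtype=float)) ** weight
    w_hit = np.where(hit, w, 0.0)
    total = w_hit.sum()
    if total == 0:  # all member scores are zero: fall back to equal weights
        w_hit = hit / k
        total = 1.0
    steps = w_hit / total - (~hit) / (L - k)
    run = np.cumsum(steps)
    return float(run[np.argmax(np.abs(run))])


def connectivity_score(drug: DrugSignature, disease: DiseaseSignature) -> float:
    """Two-sided connectivity between a drug profile and a disease signature.

    WTCS convention: with ES_up and ES_down the enrichment of the
    disease up/down sets in the drug ranking, the score is
    (ES_up - ES_down)/2 when the two have opposite signs and 0
    otherwise.  Negative score = the drug reverses the disease
    signature (disease-up genes pushed down and vice versa).  If the
    disease signature has only one direction, the score falls back to
    the single available enrichment (sign-flipped for the down set).
    """
    if disease.empty:
        raise ValueError(f"{disease.dataset_id}: empty disease signature")
    has_up = bool(disease.up)
    has_down = bool(disease.down)
    es_up = enrichment_score(drug, disease.up) if has_up else None
    es_dn = enrichment_score(drug, disease.down) if has_down else None
    if has_up and has_down:
        if np.sign(es_up) != np.sign(es_dn):
            return (es_up - es_dn) / 2.0
        return 0.0
    return es_up if has_up else -es_dn


def gsea_score(
    drug_id: str,
    connectivities: Optional[Mapping[str, float]],
    n_datasets: int,
) -> GseaScore:
    """Count datasets with strictly negative connectivity (None = NA).

    ``connectivities`` maps dataset id to score; datasets for which the
    drug-dataset pair was unusable are simply absent and contribute
    nothing.  ``connectivities=None`` means the drug has no profile in
    the signature library at all, yielding an NA score.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    if connectivities is None:
        return GseaScore(drug_id=drug_id, score=None, n_datasets=n_datasets)
    score = sum(1 for v in connectivities.values() if v < 0)
    return GseaScore(drug_id=drug_id, score=score, n_datasets=n_datasets)


def read_drug_signatures(path) -> dict[str, list[DrugSignature]]:
    """Long-format library TSV: drug_id, gene_id, score [, profile_id].

    Returns one or more ranked profiles per drug (several cell-line
    profiles are possible when ``profile_id`` is present).
    """
    df = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "gene_id": str})
    for col in ("drug_id", "gene_id", "score"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    has_profile = "profile_id" in df.columns
    library: dict[str, list[DrugSignature]] = {}
    group_keys = ["drug_id", "profile_id"] if has_profile else ["drug_id"]
    for key, grp in df.groupby(group_keys, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        drug_id = key[0]
        profile_id = str(key[1]) if has_profile else ""
        scores = dict(zip(grp["gene_id"], grp["score"].astype(float)))
        sig = DrugSignature.from_scores(drug_id, scores, profile_id=profile_id)
        library.setdefault(drug_id, []).append(sig)
    return library


def read_drug_signature_gmt(path) -> dict[str, list[DrugSignature]]:
    """GMT pair library: set ids ``<drug>_UP`` and ``<drug>_DN``.

    Up members get score +1 and down members -1 (rank order within a
    block is alphabetical), which preserves the sign structure that the
    connectivity score depends on, though not fine-grained ranks.
    """
    from .entity_io import read_gmt

    halves: dict[str, dict[str, float]] = {}
    for gs in read_gmt(path):
        if gs.set_id.endswith("_UP"):
            drug, sign = gs.set_id[:-3], 1.0
        elif gs.set_id.endswith("_DN"):
            drug, sign = gs.set_id[:-3], -1.0
        else:
            raise ValueError(f"{path}: set id {gs.set_id!r} lacks _UP/_DN suffix")
        scores = halves.setdefault(drug, {})
        for gene in gs.members:
            scores[gene] = sign
    return {
        drug: [DrugSignature.from_scores(drug, scores)]
        for drug, scores in sorted(halves.items())
    }


def collapse_connectivity(values: Sequence[float], how: str = "extreme") -> float:
    """Collapse multi-profile (cell line) connectivities to one value.

    ``extreme`` keeps the value of largest magnitude (deterministic
    tie-break toward the negative); ``majority`` returns the median.
    """
    if not values:
        raise ValueError("no connectivity values to collapse")
    if how == "extreme":
        return min(values, key=lambda v: (-abs(v), v))
    if how == "majority":
        return float(np.median(values))
    raise ValueError(f"unknown collapse mode {how!r}")


def score_library(
    disease_signatures: Sequence[DiseaseSignature],
    library: Mapping[str, Sequence[DrugSignature]],
    drug_ids: Iterable[str],
    collapse: str = "extreme",
) -> tuple[pd.DataFrame, dict[str, GseaScore]]:
    """Connectivity of every drug against every dataset, plus GSEA scores.

    Drugs absent from the library get NA; drug-dataset pairs whose
    signatures do not overlap the drug's ranking are skipped (logged)
    and contribute nothing to the count.
    """
    n_datasets = len(disease_signatures)
    usable = [s for s in disease_signatures if not s.empty]
    for s in disease_signatures:
        if s.empty:
            logger.warning("dataset %s has an empty signature; skipped", s.dataset_id)
    rows = []
    scores: dict[str, GseaScore] = {}
    for drug_id in sorted(set(drug_ids)):
        profiles = library.get(drug_id)
        if not profiles:
            scores[drug_id] = gsea_score(drug_id, None, n_datasets)
            rows.append({"drug_id": drug_id})
            continue
        conns: dict[str, float] = {}
        for sig in usable:
            per_profile = []
            for prof in profiles:
                try:
                    per_profile.append(connectivity_score(prof, sig))
                except ValueError:
                    continue
            if per_profile:
                conns[sig.dataset_id] = collapse_connectivity(per_profile, collapse)
        scores[drug_id] = gsea_score(drug_id, conns, n_datasets)
        rows.append({"drug_id": drug_id, **{f"conn_{k}": v for k, v in conns.items()}})
    table = pd.DataFrame(rows)
    table["gsea_score"] = [
        "na" if scores[d].score is None else scores[d].score for d in table["drug_id"]
    ]
    table["n_datasets"] = n_datasets
    return table, scores


def write_gsea_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_gsea_scores(path) -> dict[str, GseaScore]:
    df = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "gsea_score": str})
    out = {}
    for row in df.itertuples():
        score = None if row.gsea_score == "na" else int(row.gsea_score)
        out[row.drug_id] = GseaScore(
            drug_id=row.drug_id, score=score, n_datasets=int(row.n_datasets)
        )
    return out
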