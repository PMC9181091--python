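"""Readers and validation for disease gene sets and drug-target tables.

Disease-associated genes arrive as GMT gene sets (Broad format) or
two-column TSVs; drug-target interactions arrive as long-format TSVs
(one row per drug-target pair, DrugBank-style accessions).  Target
identifiers can be passed through a user-supplied two-column id map
(e.g. UniProt to Entrez); unmapped identifiers are dropped rather than
passed through, and drugs left with no mapped targets are excluded from
scoring and reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .interactome import Interactome

logger = logging.getLogger(__name__)


class GmtParseError(ValueError):
    """A GMT line could not be parsed."""


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene identifiers (e.g. one disease's genes)."""

    set_id: str
    name: str
    members: frozenset

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene set {self.set_id!r} has no members")
        for m in self.members:
            if not isinstance(m, str) or not m or m != m.strip():
                raise ValueError(
                    f"gene set {self.set_id!r}: invalid member {m!r}"
                )

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class DrugRecord:
    """One drug with its target gene set."""

    drug_id: str
    name: str
    targets: frozenset

    def __post_init__(self):
        if not self.drug_id:
            raise ValueError("drug_id must be non-empty")


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT file: ``set_id <TAB> description <TAB> member...``

    Duplicate members within a line collapse; duplicate set ids across
    lines are an error.  An empty file yields an empty list.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            set_id = fields[0].strip()
            if set_id in seen:
                raise GmtParseError(f"{path}: line {lineno}: duplicate set id {set_id!r}")
            seen.add(set_id)
            members = frozenset(m.strip() for m in fields[2:] if m.strip())
            sets.append(GeneSet(set_id=set_id, name=fields[1].strip(), members=members))
    return sets


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.name, *sorted(s.members)]) + "\n")


def read_id_map(path) -> dict:
    """Two-column TSV ``source_id <TAB> target_id`` -> dict (many-to-one ok)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["source", "target"], dtype=str)
    df = df.dropna()
    mapping = {}
    for source, target in zip(df["source"].str.strip(), df["target"].str.strip()):
        if not source or not target:
            raise ValueError(f"{path}: empty identifier in id map")
        mapping[source] = target
    return mapping


REQUIRED_DRUG_COLUMNS = ("drug_id", "drug_name", "target_id")


def read_drug_targets(path, idmap: Mapping | None = None) -> list[DrugRecord]:
    """Long-format drug-target TSV -> one :class:`DrugRecord` per drug.

    Requires columns ``drug_id``, ``drug_name``, ``target_id``.  When an
    id map is given, target ids are translated and unmapped ids dropped;
    drugs whose mapped target set ends up empty are excluded and their
    count logged (they are unscoreable).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_DRUG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records: list[DrugRecord] = []
    n_excluded = 0
    for drug_id, grp in df.groupby("drug_id", sort=True):
        name = grp["drug_name"].iloc[0]
        targets = {t.strip() for t in grp["target_id"].dropna() if t.strip()}
        if idmap is not None:
            targets = {idmap[t] for t in targets if t in idmap}
        if not targets:
            n_excluded += 1
            continue
        records.append(DrugRecord(drug_id=drug_id, name=name, targets=frozenset(targets)))
    if n_excluded:
        logger.info("%s: excluded %d drugs with no (mapped) targets", path, n_excluded)
    return records


def write_drug_targets(records: Iterable[DrugRecord], path) -> None:
    rows = [
        {"drug_id": r.drug_id, "drug_name": r.name, "target_id": t}
        for r in sorted(records, key=lambda r: r.drug_id)
        for t in sorted(r.targets)
    ]
    pd.DataFrame(rows, columns=list(REQUIRED_DRUG_COLUMNS)).to_csv(path, sep="\t", index=False)


def merge_drug_libraries(libraries: Sequence[Sequence[DrugRecord]]) -> list[DrugRecord]:
    """Union of several drug-target libraries (targets merged per drug id).

    The first library providing a drug supplies its display name.
    Mirrors supplementing a primary target database with a secondary one.
    """
    merged: dict[str, DrugRecord] = {}
    for lib in libraries:
        for rec in lib:
            if rec.drug_id in merged:
                prev = merged[rec.drug_id]
                merged[rec.drug_id] = DrugRecord(
                    drug_id=rec.drug_id,
                    name=prev.name,
                    targets=prev.targets | rec.targets,
                )
            else:
                merged[rec.drug_id] = rec
    return [merged[k] for k in sorted(merged)]


def restrict_to_graph(members: Iterable, g: Interactome) -> tuple[set, set]:
    """Split a gene set into (kept, dropped) by interactome membership."""
    members = set(members)
    kept = {m for m in members if m in g}
    dropped = members - kept
    if dropped:
        logger.info("restricted gene set: kept %d, dropped %d", len(kept), len(dropped))
    if not kept:
        logger.warning("no members of the gene set are in the interactome")
    return kept, dropped
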