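"""Synthetic pipeline inputs with controlled, known signal.

Every input the pipeline consumes can be generated here with planted
ground truth, so each stage is testable end to end without external
databases: a preferential-attachment interactome (heavy-tailed degrees,
like real protein-protein interaction networks) with a planted
connected disease module; drug-target sets either proximal to the
module or degree-matched random; and disease/drug expression signatures
in which a known subset of drugs reverses the disease signature with a
controlled strength.

Ground-truth labels are written to a sidecar table only, never into the
files the pipeline readers consume, so the readers cannot leak labels
into scoring.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .entity_io import DrugRecord, GeneSet, write_drug_targets, write_gmt
from .interactome import Interactome, build_degree_bins, sample_degree_matched
from .signatures import DrugSignature

logger = logging.getLogger(__name__)


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study; defaults define the standard benchmark.

    The default benchmark is a 2,000-node preferential-attachment graph
    with a planted 25-gene disease module, 10 module-proximal and 40
    degree-matched random drugs of 3 targets each, and three disease
    expression datasets whose signatures the "reversing" drugs invert
    with strength 0.8 under 5% placement noise.
    """

    n_nodes: int = 2000
    edges_per_node: int = 3
    module_size: int = 25
    n_drugs_proximal: int = 10
    n_drugs_random: int = 40
    targets_per_drug: int = 3
    n_datasets: int = 3
    genes_per_signature: int = 200
    reversal_strength: float = 0.8
    noise_p: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.module_size < self.n_nodes:
            raise ValueError("module_size must be in [1, n_nodes)")
        for name in (
            "n_nodes", "edges_per_node", "n_drugs_proximal", "n_drugs_random",
            "targets_per_drug", "n_datasets", "genes_per_signature",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("reversal_strength", "noise_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _gene_label(i: int) -> str:
    return f"G{i:05d}"


def generate_interactome(cfg: SyntheticConfig) -> tuple[Interactome, GeneSet]:
    """Preferential-attachment graph plus a planted connected disease module.

    The module is grown by repeated random frontier expansion from a
    random seed node, so it is connected by construction; growth is
    retried with a derived seed if it stalls (possible only on graphs
    smaller than the module's component).
    """
    rng = np.random.default_rng(cfg.seed)
    ba_seed = int(rng.integers(2**31))
    g = nx.barabasi_albert_graph(cfg.n_nodes, cfg.edges_per_node, seed=ba_seed)
    g = nx.relabel_nodes(g, {i: _gene_label(i) for i in g.nodes})
    inter = Interactome(g)
    for attempt in range(100):
        module = _grow_module(inter, cfg.module_size, np.random.default_rng(int(rng.integers(2**31))))
        if module is not None:
            break
    else:
        raise RuntimeError(f"could not grow a connected {cfg.module_size}-node module in 100 attempts")
    disease = GeneSet(set_id="DISEASE", name="planted disease module", members=frozenset(module))
    logger.info("generated %d-node graph with %d-gene planted module", inter.n_nodes, len(module))
    return inter, disease


def _grow_module(g: Interactome, size: int, rng: np.random.Generator) -> set | None:
    nodes = sorted(g.nodes)
    start = nodes[int(rng.integers(len(nodes)))]
    module = {start}
    while len(module) < size:
        frontier = sorted(
            {nb for m in module for nb in g.graph.neighbors(m)} - module
        )
        if not frontier:
            return None
        module.add(frontier[int(rng.integers(len(frontier)))])
    return module


def plant_drugs(
    g: Interactome, module: GeneSet, cfg: SyntheticConfig
) -> tuple[list[DrugRecord], pd.DataFrame]:
    """Proximal and degree-matched random drugs with a ground-truth sidecar.

    Proximal drugs draw targets from the module and its first graph
    neighborhood.  Random drugs draw a proximal-style template and then
    replace it with a degree-matched sample from anywhere in the graph,
    so the two classes share a degree profile and proximity differences
    cannot be explained by target degree alone.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    pool = sorted(module.members | {nb for m in module.members for nb in g.graph.neighbors(m)})
    if len(pool) < cfg.targets_per_drug:
        raise ValueError(
            f"module neighborhood has {len(pool)} nodes; need >= {cfg.targets_per_drug}"
        )
    bins = build_degree_bins(g, min_bin_size=min(100, max(1, g.n_nodes // 10)))
    drugs: list[DrugRecord] = []
    labels = []
    for i in range(cfg.n_drugs_proximal):
        idx = rng.choice(len(pool), size=cfg.targets_per_drug, replace=False)
        targets = frozenset(pool[j] for j in idx)
        drug_id = f"DSYN{i:04d}"
        drugs.append(DrugRecord(drug_id=drug_id, name=f"proxidrug-{i:02d}", targets=targets))
        labels.append({"drug_id": drug_id, "proximity_label": "proximal"})
    for i in range(cfg.n_drugs_random):
        idx = rng.choice(len(pool), size=cfg.targets_per_drug, replace=False)
        template = [pool[j] for j in idx]
        targets = frozenset(sample_degree_matched(g, bins, template, rng))
        drug_id = f"DSYN{cfg.n_drugs_proximal + i:04d}"
        drugs.append(DrugRecord(drug_id=drug_id, name=f"randodrug-{i:02d}", targets=targets))
        labels.append({"drug_id": drug_id, "proximity_label": "random"})
    return drugs, pd.DataFrame(labels)


#: role cycle for non-proximal drugs in the signature library
_RANDOM_ROLES = ("null", "mimicking", "absent")


def generate_signatures(
    cfg: SyntheticConfig, drugs: list[DrugRecord]
) -> tuple[dict[str, pd.DataFrame], dict[str, list[DrugSignature]], pd.DataFrame]:
    """Disease DE tables, a drug-signature library, and reversal labels.

    Each dataset's DE table plants an up/down gene split whose raw
    p-values survive Benjamini-Hochberg at 0.05 cleanly (planted genes
    get p in [1e-8, 1e-5], background in [0.2, 1]).  Datasets draw
    their up/down genes from shared pools, emulating a common disease
    program across cohorts, so a single drug profile can reverse (or
    mimic) all of them at once.  Reversing drugs push disease-up genes
    to the bottom of their ranking and disease-down genes to the top,
    each gene independently with probability ``reversal_strength``;
    ``noise_p`` then flips individual placements.  Null drugs are pure
    background; "absent" drugs are left out of the library entirely
    (the NA path).
    """
    rng = np.random.default_rng(cfg.seed + 2)
    n_sig = cfg.genes_per_signature
    n_de = max(2, n_sig // 5)  # planted up and down genes per dataset
    universe_size = max(1000, 5 * n_sig)
    universe = [f"T{i:05d}" for i in range(universe_size)]

    # shared disease program pools (disjoint)
    pool_idx = rng.choice(universe_size, size=4 * n_de, replace=False)
    up_pool = [universe[i] for i in pool_idx[: 2 * n_de]]
    dn_pool = [universe[i] for i in pool_idx[2 * n_de :]]
    background = sorted(set(universe) - set(up_pool) - set(dn_pool))

    de_tables: dict[str, pd.DataFrame] = {}
    all_up: set[str] = set()
    all_dn: set[str] = set()
    for j in range(cfg.n_datasets):
        ds = f"DS{j + 1}"
        up = [up_pool[i] for i in rng.choice(len(up_pool), size=n_de, replace=False)]
        dn = [dn_pool[i] for i in rng.choice(len(dn_pool), size=n_de, replace=False)]
        n_bg = n_sig - len(up) - len(dn)
        bg = [background[i] for i in rng.choice(len(background), size=n_bg, replace=False)]
        rows = []
        for gene in up:
            rows.append((gene, rng.uniform(1.0, 3.0), 10 ** rng.uniform(-8, -5)))
        for gene in dn:
            rows.append((gene, -rng.uniform(1.0, 3.0), 10 ** rng.uniform(-8, -5)))
        for gene in bg:
            rows.append((gene, rng.normal(0.0, 0.3), rng.uniform(0.2, 1.0)))
        df = pd.DataFrame(rows, columns=["gene_id", "effect", "p_raw"])
        de_tables[ds] = df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
        all_up.update(up)
        all_dn.update(dn)

    library: dict[str, list[DrugSignature]] = {}
    labels = []
    for k, drug in enumerate(sorted(drugs, key=lambda d: d.drug_id)):
        if k < cfg.n_drugs_proximal:
            role = "reversing"
        else:
            role = _RANDOM_ROLES[(k - cfg.n_drugs_proximal) % len(_RANDOM_ROLES)]
        labels.append({"drug_id": drug.drug_id, "signature_label": role})
        if role == "absent":
            continue
        scores = _drug_profile(rng, universe, all_up, all_dn, role, cfg)
        library[drug.drug_id] = [DrugSignature.from_scores(drug.drug_id, scores)]
    return de_tables, library, pd.DataFrame(labels)


def _drug_profile(
    rng: np.random.Generator,
    universe: list[str],
    disease_up: set[str],
    disease_dn: set[str],
    role: str,
    cfg: SyntheticConfig,
) -> dict[str, float]:
    """Per-gene treatment scores for one drug profile.

    Background scores are standard normal; planted genes get a strong
    shift (magnitude > 5, outside the background range in practice)
    whose direction encodes reversal or mimicry.
    """
    scores = {g: float(rng.normal()) for g in universe}
    if role == "null":
        return scores
    flip = -1.0 if role == "reversing" else 1.0
    for gene in sorted(disease_up):
        if rng.random() < cfg.reversal_strength:
            mag = 5.0 + rng.exponential(1.0)
            sign = flip if rng.random() >= cfg.noise_p else -flip
            scores[gene] = sign * mag
    for gene in sorted(disease_dn):
        if rng.random() < cfg.reversal_strength:
            mag = 5.0 + rng.exponential(1.0)
            sign = -flip if rng.random() >= cfg.noise_p else flip
            scores[gene] = sign * mag
    return scores


def generate_all(cfg: SyntheticConfig) -> dict:
    """Run the full generator; returns a bundle keyed by artifact name."""
    graph, disease = generate_interactome(cfg)
    drugs, prox_truth = plant_drugs(graph, disease, cfg)
    de_tables, library, sig_truth = generate_signatures(cfg, drugs)
    truth = prox_truth.merge(sig_truth, on="drug_id", how="outer")
    return {
        "config": cfg,
        "graph": graph,
        "disease": disease,
        "drugs": drugs,
        "de_tables": de_tables,
        "library": library,
        "truth": truth,
    }


def write_fixtures(cfg: SyntheticConfig, outdir) -> dict[str, Path]:
    """Write every generated artifact in the formats the readers consume.

    Ground truth goes to ``truth.tsv`` only (a sidecar the pipeline
    never reads).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = generate_all(cfg)
    paths: dict[str, Path] = {}

    paths["edge_list"] = outdir / "edge_list.tsv"
    with open(paths["edge_list"], "w") as fh:
        fh.write("# synthetic interactome edge list\n")
        for u, v in sorted(tuple(sorted(e)) for e in bundle["graph"].graph.edges):
            fh.write(f"{u}\t{v}\n")

    paths["disease"] = outdir / "disease.gmt"
    write_gmt([bundle["disease"]], paths["disease"])

    paths["drug_targets"] = outdir / "drug_targets.tsv"
    write_drug_targets(bundle["drugs"], paths["drug_targets"])

    for ds, df in bundle["de_tables"].items():
        p = outdir / f"de_{ds}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[f"de_{ds}"] = p

    paths["drug_signatures"] = outdir / "drug_signatures.tsv"
    rows = []
    for drug_id in sorted(bundle["library"]):
        for prof in bundle["library"][drug_id]:
            for gene, score in zip(prof.ranked_genes, prof.scores):
                rows.append({"drug_id": drug_id, "gene_id": gene, "score": score})
    pd.DataFrame(rows).to_csv(paths["drug_signatures"], sep="\t", index=False)

    paths["truth"] = outdir / "truth.tsv"
    bundle["truth"].to_csv(paths["truth"], sep="\t", index=False)

    paths["config"] = outdir / "config.yaml"
    cfg.to_yaml(paths["config"])
    logger.info("wrote synthetic fixtures to %s", outdir)
    return paths
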