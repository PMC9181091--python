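from pathlib import Path

import networkx as nx
import pandas as pd
import pytest

from netproxrx.interactome import Interactome, build_degree_bins
from netproxrx.proximity import ProximityResult
from netproxrx.signatures import GseaScore

EXAMPLES = Path(__file__).resolve().parent.parent / "examples"


@pytest.fixture
def path_graph():
    """Path A-B-C-D-E."""
    g = nx.path_graph(["A", "B", "C", "D", "E"])
    return Interactome(g)


@pytest.fixture
def small_ba_graph():
    g = nx.barabasi_albert_graph(200, 2, seed=42)
    return Interactome(nx.relabel_nodes(g, {i: f"G{i:03d}" for i in g.nodes}))


@pytest.fixture
def small_bins(small_ba_graph):
    return build_degree_bins(small_ba_graph, min_bin_size=20)


@pytest.fixture
def histaminergic_example():
    """Nine-drug worked example: precomputed similarity/p/GSEA triples.

    Returns (proximity results, gsea score map, annotations).
    """
    df = pd.read_csv(
        EXAMPLES / "histaminergic_candidates.tsv",
        sep="\t",
        dtype={"drug_id": str, "drug_name": str, "gsea_score": str},
    )
    results, gsea, notes = [], {}, {}
    for row in df.itertuples():
        results.append(
            ProximityResult(
                drug_id=row.drug_id,
                drug_name=row.drug_name,
                disease_id="MS",
                d_closest=float("nan"),
                z=float("nan"),
                p_emp=float(row.p_value),
                similarity=float(row.similarity),
                n_permutations=0,
                seed=0,
            )
        )
        score = None if row.gsea_score == "na" else int(row.gsea_score)
        gsea[row.drug_id] = GseaScore(drug_id=row.drug_id, score=score, n_datasets=3)
        notes[row.drug_id] = row.target
    return results, gsea, notes
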