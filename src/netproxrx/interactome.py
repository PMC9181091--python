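"""Protein-protein interactome graph services.

The interactome is an undirected simple graph whose nodes are gene
identifiers and whose edges are binary physical interactions.  All
proximity scoring in this package reduces to three services provided
here: multi-source breadth-first shortest-path distances, contiguous
degree binning, and degree-matched random sampling (the null model that
preserves the hub/leaf profile of an observed gene set).

Distances are unweighted hop counts.  For graphs up to a few thousand
nodes an all-pairs distance matrix is computed once (scipy csgraph) and
cached on the instance, which makes permutation nulls with hundreds of
thousands of set-to-set distance queries practical on one CPU; larger
graphs fall back to per-query BFS.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.sparse.csgraph as csgraph

logger = logging.getLogger(__name__)

#: Above this node count the all-pairs matrix cache is skipped (memory),
#: and set-to-set distances fall back to per-query BFS.
MATRIX_CACHE_MAX_NODES = 6000


class EdgeListParseError(ValueError):
    """A line of an edge-list file could not be parsed."""


class Interactome:
    """Undirected simple graph of gene nodes.

    Self-loops are dropped and duplicate/reversed edges collapse to one
    undirected edge on construction, so the invariant ``sum(degrees) ==
    2 * n_edges`` always holds.
    """

    def __init__(self, graph: nx.Graph):
        g = nx.Graph()
        g.add_nodes_from(graph.nodes)
        g.add_edges_from((u, v) for u, v in graph.edges if u != v)
        self._g = g
        self._adj = {n: tuple(g.neighbors(n)) for n in g}
        self._dist_matrix: np.ndarray | None = None
        self._node_index: dict[str, int] | None = None

    # -- basic accessors -------------------------------------------------
    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> set:
        return set(self._g.nodes)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    @property
    def degree_index(self) -> dict:
        return dict(self._g.degree())

    def __contains__(self, node) -> bool:
        return node in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    # -- distances -------------------------------------------------------
    def distances_from(self, sources: Iterable) -> dict:
        """Hop distance from every reachable node to its nearest source.

        Multi-source BFS: sources get distance 0; nodes in other
        components are absent from the returned mapping.
        """
        sources = list(sources)
        missing = sorted(s for s in sources if s not in self._g)
        if missing:
            raise KeyError(f"source nodes not in graph: {missing}")
        dist = {s: 0 for s in sources}
        queue = deque(sources)
        adj = self._adj
        while queue:
            u = queue.popleft()
            du = dist[u] + 1
            for v in adj[u]:
                if v not in dist:
                    dist[v] = du
                    queue.append(v)
        return dist

    def _matrix(self) -> tuple[np.ndarray, dict]:
        """All-pairs hop-distance matrix, built once and cached."""
        if self._dist_matrix is None:
            order = sorted(self._g.nodes)
            index = {n: i for i, n in enumerate(order)}
            adj = nx.to_scipy_sparse_array(self._g, nodelist=order, format="csr")
            dm = csgraph.shortest_path(adj, method="D", unweighted=True)
            self._dist_matrix = dm.astype(np.float32)
            self._node_index = index
            logger.info("cached %d x %d distance matrix", len(order), len(order))
        return self._dist_matrix, self._node_index

    def closest_distance(self, targets: Iterable, disease: Iterable) -> float:
        """Mean over targets of the hop distance to the nearest disease gene.

        Uses the cached all-pairs matrix when the graph is small enough,
        otherwise one multi-source BFS from the disease set.  Returns
        ``inf`` if some target is unreachable from every disease gene.
        """
        targets = list(targets)
        disease = list(disease)
        if not targets or not disease:
            raise ValueError("targets and disease sets must be non-empty")
        if self.n_nodes <= MATRIX_CACHE_MAX_NODES:
            dm, index = self._matrix()
            t_idx = [index[t] for t in targets]
            d_idx = [index[d] for d in disease]
            return float(dm[np.ix_(d_idx, t_idx)].min(axis=0).mean())
        dist = self.distances_from(disease)
        vals = [dist.get(t, np.inf) for t in targets]
        return float(np.mean(vals))


@dataclass(frozen=True)
class DegreeBins:
    """Contiguous degree bins over the nodes of one graph.

    Each bin is a ``((deg_lo, deg_hi), nodes)`` pair; degree classes are
    never split across bins, every bin holds at least ``min_bin_size``
    nodes, and an undersized final remainder is merged into the previous
    bin.  ``node_to_bin`` resolves the bin of any graph node in O(1).
    """

    bins: tuple
    min_bin_size: int
    node_to_bin: Mapping = field(repr=False)

    def bin_of(self, node) -> int:
        try:
            return self.node_to_bin[node]
        except KeyError:
            raise KeyError(f"node {node!r} has no degree bin") from None

    def members(self, bin_idx: int) -> Sequence:
        return self.bins[bin_idx][1]


def load_edge_list(path, delimiter: str | None = None) -> Interactome:
    """Read a two-column edge list into an :class:`Interactome`.

    Lines starting with ``#`` and blank lines are ignored; extra columns
    beyond the first two are ignored.  ``delimiter=None`` splits on any
    whitespace.  Self-loops are dropped and duplicate or reversed edges
    collapse to a single undirected edge.
    """
    g = nx.Graph()
    n_lines = n_self = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(delimiter)
            if len(fields) < 2:
                raise EdgeListParseError(
                    f"{path}: line {lineno}: expected >= 2 fields, got {len(fields)}"
                )
            u, v = fields[0].strip(), fields[1].strip()
            n_lines += 1
            if u == v:
                n_self += 1
                g.add_node(u)
                continue
            g.add_edge(u, v)
    if g.number_of_nodes() == 0:
        raise ValueError(f"{path}: empty graph (no valid edges)")
    dupes = n_lines - n_self - g.number_of_edges()
    logger.info(
        "loaded %s: %d nodes, %d edges (%d self-loops dropped, %d duplicates collapsed)",
        path, g.number_of_nodes(), g.number_of_edges(), n_self, dupes,
    )
    return Interactome(g)


def largest_connected_component(g: Interactome) -> Interactome:
    """Induced subgraph on the largest connected component.

    Ties on component size are broken in favour of the component
    containing the lexicographically smallest node.  Restricting to the
    LCC makes every pairwise distance finite, which the proximity stage
    relies on.
    """
    if g.n_nodes == 0:
        raise ValueError("empty graph")
    comps = sorted(nx.connected_components(g.graph), key=lambda c: (-len(c), min(c)))
    keep = comps[0]
    removed = g.n_nodes - len(keep)
    if removed:
        logger.info("LCC restriction removed %d of %d nodes", removed, g.n_nodes)
    return Interactome(g.graph.subgraph(keep).copy())


def shortest_path_lengths_from(g: Interactome, sources: Iterable) -> dict:
    """Multi-source BFS distances; see :meth:`Interactome.distances_from`."""
    return g.distances_from(sources)


def build_degree_bins(g: Interactome, min_bin_size: int = 100) -> DegreeBins:
    """Group nodes into contiguous degree bins of at least ``min_bin_size``.

    Nodes are sorted by degree and whole degree classes are accumulated
    greedily until a bin reaches the minimum size; an undersized final
    remainder is absorbed into the previous bin.  With
    ``min_bin_size=1`` every degree class becomes its own bin.
    """
    n = g.n_nodes
    if min_bin_size < 1 or min_bin_size > n:
        raise ValueError(f"min_bin_size must be in [1, {n}], got {min_bin_size}")
    by_degree: dict[int, list] = {}
    for node, deg in g.degree_index.items():
        by_degree.setdefault(deg, []).append(node)
    bins: list[tuple[tuple[int, int], list]] = []
    cur_nodes: list = []
    cur_lo: int | None = None
    for deg in sorted(by_degree):
        if cur_lo is None:
            cur_lo = deg
        cur_nodes.extend(sorted(by_degree[deg]))
        if len(cur_nodes) >= min_bin_size:
            bins.append(((cur_lo, deg), cur_nodes))
            cur_nodes, cur_lo = [], None
    if cur_nodes:
        if bins:  # undersized remainder merges into the previous bin
            (lo, _), prev = bins.pop()
            prev = prev + cur_nodes
            bins.append(((lo, max(by_degree)), prev))
        else:
            bins.append(((cur_lo, max(by_degree)), cur_nodes))
    node_to_bin = {node: i for i, (_, members) in enumerate(bins) for node in members}
    return DegreeBins(
        bins=tuple((rng, tuple(members)) for rng, members in bins),
        min_bin_size=min_bin_size,
        node_to_bin=node_to_bin,
    )


def sample_degree_matched(
    g: Interactome,
    bins: DegreeBins,
    template: Iterable,
    rng_seed: int | np.random.Generator,
) -> set:
    """Random node set with the same per-bin degree profile as ``template``.

    For each template node one node is drawn from that node's degree
    bin; draws within a bin are without replacement, so the sampled set
    has exactly the template's cardinality.  A bin whose size equals the
    number of template nodes it must supply is returned in full (which
    may include the template nodes themselves; logged at debug level).
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    template = list(template)
    needed: dict[int, int] = {}
    for node in template:
        b = bins.bin_of(node)  # raises KeyError for unknown nodes
        needed[b] = needed.get(b, 0) + 1
    sampled: list = []
    for b in sorted(needed):
        members = bins.members(b)
        k = needed[b]
        if k > len(members):
            raise ValueError(
                f"bin {b} has {len(members)} nodes but template needs {k}"
            )
        if k == len(members):
            logger.debug("bin %d exhausted: forced to return all %d members", b, k)
            sampled.extend(members)
        else:
            idx = rng.choice(len(members), size=k, replace=False)
            sampled.extend(members[i] for i in idx)
    return set(sampled)
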