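"""Entity co-occurrence networks from binary incidence matrices.

Each retained entity is a binary vector over tweets; edges carry the cosine
similarity of the two incidence rows and survive only if the weight strictly
exceeds the threshold tau. Community structure is found with an own
implementation of the Louvain (fast unfolding) two-phase heuristic, with
modularity computed by an independent function that doubles as its oracle.
"""

from __future__ import annotations

import csv
import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from .entities import EntityMention

logger = logging.getLogger(__name__)

DEFAULT_TAU_DRUG_DRUG = 0.005
DEFAULT_TAU_DRUG_SYMPTOM = 0.05


@dataclass
class IncidenceMatrix:
    """Binary entity x tweet occurrence structure."""

    entities: list  # ordered canonical names
    tweet_ids: list  # ordered, shared across entity classes
    matrix: sp.csr_matrix  # binary
    classes: dict  # canonical -> concept class

    def row(self, canonical: str) -> np.ndarray:
        return np.asarray(
            self.matrix[self.entities.index(canonical)].todense()
        ).ravel()

    @property
    def shape(self):
        return self.matrix.shape


def build_incidence(
    mentions: Iterable[EntityMention],
    retained: Iterable[str],
    tweet_ids: Sequence[str],
    count_mode: bool = False,
) -> IncidenceMatrix:
    """Entity x tweet matrix: cell 1 iff the entity occurs in the tweet.

    Mention multiplicity within a tweet is collapsed unless ``count_mode``;
    entities with no mentions among ``tweet_ids`` are excluded (no all-zero
    rows).
    """
    retained = set(retained)
    col_of = {tid: j for j, tid in enumerate(tweet_ids)}
    cells: dict = defaultdict(int)
    classes: dict = {}
    present: set = set()
    for m in mentions:
        if m.canonical not in retained or m.tweet_id not in col_of:
            continue
        cells[(m.canonical, col_of[m.tweet_id])] += 1
        classes[m.canonical] = m.concept_class
        present.add(m.canonical)
    entities = sorted(present)
    row_of = {e: i for i, e in enumerate(entities)}
    if cells:
        rows, cols, vals = zip(
            *(
                (row_of[e], j, c if count_mode else 1)
                for (e, j), c in cells.items()
            )
        )
    else:
        rows = cols = vals = ()
    matrix = sp.csr_matrix(
        (np.asarray(vals, dtype=np.int64), (rows, cols)),
        shape=(len(entities), len(tweet_ids)),
    )
    return IncidenceMatrix(
        entities=entities,
        tweet_ids=list(tweet_ids),
        matrix=matrix,
        classes={e: classes[e] for e in entities},
    )


def save_incidence(inc: IncidenceMatrix, prefix) -> None:
    """Persist as MTX sparse coordinate plus row/column label sidecars."""
    prefix = Path(prefix)
    mmwrite(str(prefix.with_suffix(".mtx")), inc.matrix.tocoo(), field="integer")
    prefix.with_suffix(".rows.txt").write_text(
        "".join(f"{e}\t{inc.classes[e]}\n" for e in inc.entities), encoding="utf-8"
    )
    prefix.with_suffix(".cols.txt").write_text(
        "".join(t + "\n" for t in inc.tweet_ids), encoding="utf-8"
    )


def load_incidence(prefix) -> IncidenceMatrix:
    prefix = Path(prefix)
    matrix = sp.csr_matrix(mmread(str(prefix.with_suffix(".mtx"))))
    entities, classes = [], {}
    for line in prefix.with_suffix(".rows.txt").read_text(encoding="utf-8").splitlines():
        name, cls = line.split("\t")
        entities.append(name)
        classes[name] = cls
    tweet_ids = prefix.with_suffix(".cols.txt").read_text(encoding="utf-8").splitlines()
    return IncidenceMatrix(entities=entities, tweet_ids=tweet_ids, matrix=matrix, classes=classes)


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """u.v / (|u||v|); for binary vectors, overlap over the geometric mean
    of support sizes."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(u.dot(v) / (nu * nv))


def cosine_matrix(matrix: sp.spmatrix) -> np.ndarray:
    """All pairwise row cosines of a (sparse) incidence matrix."""
    M = sp.csr_matrix(matrix, dtype=np.float64)
    gram = np.asarray((M @ M.T).todense())
    norms = np.sqrt(np.diag(gram))
    if (norms == 0).any():
        raise ValueError("cosine similarity undefined for all-zero rows")
    return gram / np.outer(norms, norms)


def build_network(
    inc: IncidenceMatrix,
    tau: float = DEFAULT_TAU_DRUG_DRUG,
    drop_isolated: bool = True,
) -> nx.Graph:
    """Undirected graph with an edge iff cosine similarity strictly
    exceeds tau; isolated nodes are pruned by default."""
    W = cosine_matrix(inc.matrix)
    G = nx.Graph(tau=tau)
    for i, e in enumerate(inc.entities):
        G.add_node(e, concept_class=inc.classes[e])
    n = len(inc.entities)
    for i in range(n):
        for j in range(i + 1, n):
            if W[i, j] > tau:
                G.add_edge(inc.entities[i], inc.entities[j], weight=float(W[i, j]))
    if drop_isolated:
        G.remove_nodes_from([v for v, d in G.degree() if d == 0])
    for v in G.nodes:
        G.nodes[v]["degree"] = G.degree(v)
    return G


def drug_symptom_network(
    drug_inc: IncidenceMatrix,
    symptom_inc: IncidenceMatrix,
    tau: float = DEFAULT_TAU_DRUG_SYMPTOM,
    cross_only: bool = True,
    drop_isolated: bool = True,
) -> nx.Graph:
    """Network over the union row set of two incidence matrices.

    By default only drug-symptom (cross-class) edges are emitted; requires
    both matrices to share the same tweet-id column ordering.
    """
    if drug_inc.tweet_ids != symptom_inc.tweet_ids:
        raise ValueError("incidence matrices must share identical column ordering")
    entities = drug_inc.entities + symptom_inc.entities
    classes = {**drug_inc.classes, **symptom_inc.classes}
    stacked = sp.vstack([drug_inc.matrix, symptom_inc.matrix]).tocsr()
    W = cosine_matrix(stacked)
    n_drugs = len(drug_inc.entities)
    G = nx.Graph(tau=tau)
    for e in entities:
        G.add_node(e, concept_class=classes[e])
    for i in range(len(entities)):
        for j in range(i + 1, len(entities)):
            if cross_only and (i < n_drugs) == (j < n_drugs):
                continue
            if W[i, j] > tau:
                G.add_edge(entities[i], entities[j], weight=float(W[i, j]))
    if drop_isolated:
        G.remove_nodes_from([v for v, d in G.degree() if d == 0])
    for v in G.nodes:
        G.nodes[v]["degree"] = G.degree(v)
    return G


@dataclass
class Partition:
    membership: dict  # node -> community id
    q: float

    def communities(self) -> list:
        groups: dict = defaultdict(set)
        for node, c in self.membership.items():
            groups[c].add(node)
        return [groups[c] for c in sorted(groups)]


def modularity(
    G: nx.Graph, membership: Mapping, resolution: float = 1.0
) -> float:
    """Weighted modularity Q of a node->community map.

    Q = sum over communities of [L_c/m - resolution * (d_c/(2m))^2], with m
    the total edge weight, L_c the intra-community weight, and d_c the sum
    of weighted degrees. An empty edge set yields Q = 0 with a warning.
    """
    for v in G.nodes:
        if v not in membership:
            raise ValueError(f"partition does not cover node {v!r}")
    m = G.size(weight="weight")
    if m == 0:
        logger.warning("modularity of an empty edge set defined as 0")
        return 0.0
    intra: dict = defaultdict(float)
    deg: dict = defaultdict(float)
    for u, v, w in G.edges(data="weight", default=1.0):
        if membership[u] == membership[v]:
            intra[membership[u]] += w
        deg[membership[u]] += w
        deg[membership[v]] += w
    # degree counts self-loops twice
    for u, v, w in nx.selfloop_edges(G, data="weight", default=1.0):
        deg[membership[u]] += w
    q = 0.0
    for c in set(membership.values()):
        q += intra.get(c, 0.0) / m - resolution * (deg.get(c, 0.0) / (2 * m)) ** 2
    return q


class _LouvainGraph:
    """Adjacency with separate self-loop weights for the aggregation phase."""

    def __init__(self):
        self.adj: dict = defaultdict(dict)  # u -> {v: w}, u != v
        self.self_w: dict = defaultdict(float)
        self.nodes: list = []

    @classmethod
    def from_nx(cls, G: nx.Graph) -> "_LouvainGraph":
        lg = cls()
        lg.nodes = sorted(G.nodes, key=str)
        for v in lg.nodes:
            lg.self_w[v] = 0.0
        for u, v, w in G.edges(data="weight", default=1.0):
            if u == v:
                lg.self_w[u] += w
            else:
                lg.adj[u][v] = lg.adj[u].get(v, 0.0) + w
                lg.adj[v][u] = lg.adj[v].get(u, 0.0) + w
        return lg

    def degree(self, u) -> float:
        return sum(self.adj[u].values()) + 2.0 * self.self_w[u]

    def total_weight(self) -> float:
        return sum(sum(nbrs.values()) for nbrs in self.adj.values()) / 2.0 + sum(
            self.self_w.values()
        )


def _one_level(lg: _LouvainGraph, m: float, resolution: float, order: list):
    """Local-moving phase; returns (membership, improved)."""
    community = {v: v for v in lg.nodes}
    sigma_tot = {v: lg.degree(v) for v in lg.nodes}
    k = {v: lg.degree(v) for v in lg.nodes}
    improved = False
    moved = True
    while moved:
        moved = False
        for u in order:
            c_old = community[u]
            w_to: dict = defaultdict(float)
            for v, w in lg.adj[u].items():
                w_to[community[v]] += w
            sigma_tot[c_old] -= k[u]
            best_c, best_gain = c_old, w_to.get(c_old, 0.0) / m - resolution * (
                sigma_tot[c_old] * k[u]
            ) / (2.0 * m * m)
            for c, w in sorted(w_to.items(), key=lambda cw: str(cw[0])):
                if c == c_old:
                    continue
                gain = w / m - resolution * (sigma_tot[c] * k[u]) / (2.0 * m * m)
                if gain > best_gain + 1e-12:
                    best_c, best_gain = c, gain
            community[u] = best_c
            sigma_tot[best_c] += k[u]
            if best_c != c_old:
                moved = True
                improved = True
    return community, improved


def _aggregate(lg: _LouvainGraph, community: Mapping) -> "_LouvainGraph":
    agg = _LouvainGraph()
    comms = sorted(set(community.values()), key=str)
    agg.nodes = comms
    for c in comms:
        agg.self_w[c] = 0.0
    for u in lg.nodes:
        agg.self_w[community[u]] += lg.self_w[u]
    seen = set()
    for u in lg.nodes:
        for v, w in lg.adj[u].items():
            if (v, u) in seen:
                continue
            seen.add((u, v))
            cu, cv = community[u], community[v]
            if cu == cv:
                agg.self_w[cu] += w
            else:
                agg.adj[cu][cv] = agg.adj[cu].get(cv, 0.0) + w
                agg.adj[cv][cu] = agg.adj[cv].get(cu, 0.0) + w
    return agg


def louvain(
    G: nx.Graph, resolution: float = 1.0, seed: Optional[int] = None
) -> Partition:
    """Two-phase Louvain modularity maximization.

    Nodes are visited in sorted order; a seed shuffles the visiting order
    (deterministically) instead. The reported Q is recomputed with
    :func:`modularity` on the returned membership.
    """
    if G.number_of_nodes() == 0:
        raise ValueError("louvain requires a non-empty network")
    membership = {v: i for i, v in enumerate(sorted(G.nodes, key=str))}
    if G.number_of_edges() == 0:
        return Partition(membership=membership, q=modularity(G, membership, resolution))
    lg = _LouvainGraph.from_nx(G)
    m = lg.total_weight()
    rng = np.random.default_rng(seed) if seed is not None else None
    # node -> community of aggregated super-node, refined level by level
    assignment = {v: v for v in G.nodes}
    while True:
        order = list(lg.nodes)
        if rng is not None:
            rng.shuffle(order)
        community, improved = _one_level(lg, m, resolution, order)
        if not improved:
            break
        assignment = {v: community[assignment[v]] for v in assignment}
        lg = _aggregate(lg, community)
    labels = {c: i for i, c in enumerate(sorted(set(assignment.values()), key=str))}
    membership = {v: labels[c] for v, c in assignment.items()}
    return Partition(membership=membership, q=modularity(G, membership, resolution))


def annotate_atc(G: nx.Graph, atc_map: Mapping[str, str]) -> nx.Graph:
    """Attach level-1 ATC letters as node attributes; unmapped -> 'unknown'."""
    for v in G.nodes:
        G.nodes[v]["atc"] = atc_map.get(v, "unknown")
    return G


def partition_agreement(
    partition: Partition, labels: Mapping[str, str]
) -> tuple:
    """(ARI, NMI) between a partition and a node labelling, restricted to
    nodes with a known (non-'unknown') label."""
    nodes = [
        v
        for v in partition.membership
        if v in labels and labels[v] != "unknown"
    ]
    if not nodes:
        raise ValueError("no labelled nodes to compare")
    a = [partition.membership[v] for v in nodes]
    b = [labels[v] for v in nodes]
    return (
        float(adjusted_rand_score(b, a)),
        float(normalized_mutual_info_score(b, a)),
    )


def top_neighbors(G: nx.Graph, node, k: int = 10) -> list:
    """k strongest neighbors of a node by edge weight; ties by name."""
    if node not in G:
        raise KeyError(f"node {node!r} not in network")
    nbrs = [
        (v, float(G.edges[node, v].get("weight", 1.0))) for v in G.neighbors(node)
    ]
    nbrs.sort(key=lambda vw: (-vw[1], str(vw[0])))
    return nbrs[:k]


def export_network(
    G: nx.Graph,
    path,
    fmt: str = "gexf",
    partition: Optional[Partition] = None,
) -> None:
    """Write GEXF 1.2 / GraphML (Gephi-loadable) or an edge CSV."""
    H = G.copy()
    H.graph.clear()
    if partition is not None:
        for v in H.nodes:
            H.nodes[v]["community"] = int(partition.membership[v])
    for v in H.nodes:  # writers reject None attribute values
        for key in [k for k, val in H.nodes[v].items() if val is None]:
            del H.nodes[v][key]
    path = Path(path)
    if fmt == "gexf":
        nx.write_gexf(H, path, version="1.2draft")
    elif fmt == "graphml":
        nx.write_graphml(H, path)
    elif fmt == "edge-csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["source", "target", "weight"])
            for u, v, w in sorted(H.edges(data="weight", default=1.0)):
                writer.writerow([u, v, repr(float(w))])
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def import_network(path, fmt: str = "gexf") -> nx.Graph:
    path = Path(path)
    if fmt == "gexf":
        return nx.read_gexf(path)
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "edge-csv":
        G = nx.Graph()
        with open(path, "r", encoding="utf-8", newline="") as fh:
            for row in csv.DictReader(fh):
                G.add_edge(row["source"], row["target"], weight=float(row["weight"]))
        return G
    raise ValueError(f"unknown export format {fmt!r}")
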