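"""Similarity Index, orthology bands, family similarity networks and MCL.

Profile-vs-sequence hits are summarized by the normalized Similarity Index

    SI = log2((Lt / Lp) * S)

where ``Lt`` is the aligned target length, ``Lp`` the profile length and
``S`` the alignment score in bits.  SI bands operationalize homology classes:
SI > 7.5 ortholog, 5.0 < SI <= 7.5 paralog, 2.5 <= SI <= 5.0 related,
SI < 2.5 discard.  Families whose best reciprocal hit clears a threshold are
joined by an edge weighted with that SI; the resulting graph is partitioned
with the Markov Clustering algorithm (MCL) and nodes are ranked by degree
(connectivity) to nominate founder lineages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "similarity_index",
    "classify_similarity",
    "SimilarityNetwork",
    "build_network",
    "mcl_cluster",
    "node_connectivity",
    "BANDS",
]

#: Band boundaries on SI: (lower, upper, label]; scanned in order.
BANDS = (
    (7.5, math.inf, "ortholog"),
    (5.0, 7.5, "paralog"),
    (2.5, 5.0, "related"),
)


def similarity_index(Lt: float, Lp: float, S: float) -> float:
    """Normalized Similarity Index ``log2((Lt/Lp) * S)``.

    Parameters
    ----------
    Lt : aligned target length (residues), >= 1
    Lp : profile length (match columns), >= 1
    S : alignment score (bits), > 0
    """
    if Lt < 1 or Lp < 1:
        raise ValueError("Lt and Lp must be >= 1")
    if S <= 0:
        raise ValueError("S must be positive (log2 undefined otherwise)")
    return math.log2((Lt / Lp) * S)


def classify_similarity(SI: float) -> str:
    """Band for a Similarity Index value.

    ortholog if SI > 7.5; paralog if 5.0 < SI <= 7.5; related if
    2.5 <= SI <= 5.0; discard if SI < 2.5.  Every finite SI falls in exactly
    one band.
    """
    if not math.isfinite(SI):
        raise ValueError("SI must be finite")
    if SI > 7.5:
        return "ortholog"
    if SI > 5.0:
        return "paralog"
    if SI >= 2.5:
        return "related"
    return "discard"


FUNCTION_LABELS = frozenset(
    {
        "16S rRNA",
        "23S rRNA",
        "tRNA",
        "ribosomal protein",
        "cofactor/vitamin",
        "unknown",
    }
)


@dataclass
class SimilarityNetwork:
    """Weighted, undirected family similarity graph.

    ``graph`` stores nodes with a ``function`` attribute and edges with an
    ``SI`` weight; ``clusters`` is filled by :func:`mcl_cluster`.
    """

    graph: nx.Graph
    min_SI: float
    clusters: dict[str, int] = field(default_factory=dict)
    converged: bool = True

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def connectivity(self) -> dict[str, int]:
        return {n: self.graph.degree[n] for n in self.graph.nodes}

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"node_a": min(a, b), "node_b": max(a, b), "SI": d["SI"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "SI"]).sort_values(
            ["node_a", "node_b"], ignore_index=True
        )


def build_network(
    hits: pd.DataFrame,
    node_labels: dict[str, str],
    min_SI: float = 2.5,
) -> SimilarityNetwork:
    """Build the family similarity network from a profile-scan hit table.

    ``hits`` needs columns ``family`` (profile), ``target_family`` (family of
    the scanned sequence) and ``SI``.  One node per labeled family; an
    undirected edge joins each family pair whose best hit in either direction
    reaches ``min_SI``, weighted with that best SI.  Self-hits are dropped.
    """
    if min_SI < 0:
        raise ValueError("min_SI must be >= 0")
    required = {"family", "target_family", "SI"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    referenced = set(hits["family"]) | set(hits["target_family"])
    unlabeled = referenced - set(node_labels)
    if unlabeled:
        raise ValueError(f"hits reference unlabeled families: {sorted(unlabeled)}")

    g = nx.Graph()
    for fam in sorted(node_labels):
        g.add_node(fam, function=node_labels[fam])

    best: dict[tuple[str, str], float] = {}
    for fam, tfam, si in hits[["family", "target_family", "SI"]].itertuples(index=False):
        if fam == tfam:
            continue
        key = (min(fam, tfam), max(fam, tfam))
        if si > best.get(key, -math.inf):
            best[key] = float(si)
    for (a, b), si in best.items():
        if si >= min_SI:
            g.add_edge(a, b, SI=si)
    return SimilarityNetwork(graph=g, min_SI=min_SI)


def mcl_cluster(
    network: SimilarityNetwork,
    inflation: float = 2.0,
    expansion: int = 2,
    prune_below: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> dict[str, int]:
    """Markov Clustering on the SI-weighted graph.

    The edge-weight matrix gets self-loops (weight = max incident edge
    weight, 1.0 for isolated nodes), is column-normalized, then alternates
    expansion (matrix power) and inflation (elementwise power followed by
    column renormalization) with pruning of entries below ``prune_below``
    until the largest column change drops below ``tol``.  Clusters are read
    from the attractor rows; every node lands in exactly one cluster
    (overlaps resolved to the first attractor in row order).  Cluster ids are
    renumbered by the lexicographically smallest member so the labelling is
    independent of node insertion order.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    if expansion < 2:
        raise ValueError("expansion must be >= 2")
    if tol <= 0:
        raise ValueError("tol must be positive")

    nodes = sorted(network.graph.nodes)
    n = len(nodes)
    if n == 0:
        network.clusters = {}
        return {}
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for a, b, d in network.graph.edges(data=True):
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = d["SI"]
    loop = m.max(axis=0)
    loop[loop == 0] = 1.0
    m[np.diag_indices(n)] = loop
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = m**inflation
        m[m < prune_below] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m /= colsum
        if np.abs(m - prev).max() < tol:
            converged = True
            break
    network.converged = converged

    # attractors: rows with non-negligible diagonal mass
    attractors = [i for i in range(n) if m[i, i] > 1e-6]
    if not attractors:  # pathological; fall back to row argmax
        attractors = sorted(set(int(np.argmax(m[:, j])) for j in range(n)))
    assignment = np.full(n, -1, dtype=int)
    for cid, a in enumerate(attractors):
        members = np.nonzero(m[a] > 1e-6)[0]
        for j in members:
            if assignment[j] == -1:
                assignment[j] = cid
    for j in range(n):  # unclaimed nodes become singletons
        if assignment[j] == -1:
            assignment[j] = len(attractors) + j

    # canonical ids: order clusters by their lexicographically smallest node
    by_cluster: dict[int, list[str]] = {}
    for j, cid in enumerate(assignment):
        by_cluster.setdefault(cid, []).append(nodes[j])
    canonical = {
        old: new
        for new, old in enumerate(
            sorted(by_cluster, key=lambda c: min(by_cluster[c]))
        )
    }
    clusters = {nodes[j]: canonical[assignment[j]] for j in range(n)}
    network.clusters = clusters
    return clusters


def node_connectivity(network: SimilarityNetwork) -> pd.DataFrame:
    """Node degree table, sorted by descending degree then node name."""
    rows = [
        {"node": n, "degree": network.graph.degree[n]}
        for n in sorted(network.graph.nodes)
    ]
    frame = pd.DataFrame(rows, columns=["node", "degree"])
    return frame.sort_values(
        ["degree", "node"], ascending=[False, True], ignore_index=True
    )
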