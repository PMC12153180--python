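"""Per-family sequence similarity networks, Louvain communities, divergent
clusters and meta-network condensation.

An SSN has one node per seed or retrieved environmental sequence of a family
and one edge per sequence pair whose alignment passes the retention
thresholds in at least one direction, weighted by percent identity.
Communities are found by seeded Louvain modularity optimisation; "divergent"
communities — candidate reservoirs of novel diversity — are large, almost
purely environmental, and on average far from any published sequence.
"""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Optional, Sequence

import networkx as nx
import pandas as pd
from networkx.algorithms.community import louvain_communities

from .pairalign import filter_hits
from .records import Cluster, SequenceRecord

logger = logging.getLogger("divmine.ssncluster")


def build_ssn(
    sequences: Sequence[SequenceRecord],
    hits: pd.DataFrame,
    max_evalue: float = 1e-5,
    min_identity_pct: float = 30.0,
    min_mutual_coverage: float = 0.8,
) -> nx.Graph:
    """Build the family SSN from an all-against-all hit table.

    Every sequence becomes a node (isolated if nothing passes). An edge is
    drawn iff at least one direction of the pair passes the thresholds;
    its weight is the maximum identity over passing directions. Self-loops
    are dropped.
    """
    g = nx.Graph()
    for s in sequences:
        g.add_node(s.id, source=s.source, sample_id=s.sample_id)
    passing = filter_hits(hits, max_evalue, min_identity_pct, min_mutual_coverage)
    for _, row in passing.iterrows():
        a, b = str(row["qseqid"]), str(row["sseqid"])
        if a == b:
            continue
        w = float(row["pident"])
        if g.has_edge(a, b):
            if w > g[a][b]["weight"]:
                g[a][b]["weight"] = w
        else:
            g.add_edge(a, b, weight=w)
    logger.info("SSN: %d nodes, %d edges", g.number_of_nodes(), g.number_of_edges())
    return g


def partition_louvain(
    ssn: nx.Graph,
    seed: int,
    weighted: bool = True,
    resolution: float = 1.0,
) -> List[Cluster]:
    """Louvain modularity partition of an SSN, deterministic for a seed.

    Identity weights are used by default; ``weighted=False`` optimises
    unweighted modularity. Isolated nodes become singleton clusters.
    Clusters are ordered (descending size, then smallest member id) and
    labelled ``C0001``, ``C0002``, ...
    """
    if ssn.number_of_nodes() == 0:
        raise ValueError("empty SSN")
    communities = louvain_communities(
        ssn, weight="weight" if weighted else None, resolution=resolution, seed=seed
    )
    communities = sorted(communities, key=lambda c: (-len(c), min(c)))
    return [
        Cluster(cluster_id=f"C{i:04d}", member_ids=frozenset(c))
        for i, c in enumerate(communities, start=1)
    ]


def cluster_statistics(
    cluster: Cluster,
    source_of: Dict[str, str],
    similarity_of: Optional[Dict[str, Optional[float]]] = None,
) -> Cluster:
    """Fill a cluster's environmental fraction and mean closest-published
    similarity (averaged over environmental members with a defined value)."""
    members = cluster.member_ids
    n_env = sum(1 for m in members if source_of.get(m) == "environmental")
    cluster.env_fraction = n_env / len(members)
    if similarity_of is not None:
        vals = [
            similarity_of[m]
            for m in members
            if source_of.get(m) == "environmental" and similarity_of.get(m) is not None
        ]
        cluster.mean_closest_published_similarity = (sum(vals) / len(vals)) if vals else None
    return cluster


def select_divergent_clusters(
    clusters: Sequence[Cluster],
    min_size: int = 30,
    min_env_fraction: float = 0.9,
    max_mean_similarity: float = 40.0,
) -> List[Cluster]:
    """Retain clusters with >= ``min_size`` members, >= ``min_env_fraction``
    environmental, and mean closest-published similarity
    <= ``max_mean_similarity`` (thresholds inclusive as printed). Clusters
    with an undefined mean are excluded and logged."""
    selected = []
    for c in clusters:
        if c.size < min_size:
            continue
        if c.env_fraction is None or c.env_fraction < min_env_fraction:
            continue
        if c.mean_closest_published_similarity is None:
            logger.info("cluster %s excluded: undefined mean closest-published similarity", c.cluster_id)
            continue
        if c.mean_closest_published_similarity <= max_mean_similarity:
            selected.append(c)
    logger.info("divergent-cluster selection: %d/%d retained", len(selected), len(clusters))
    return selected


def condense_meta_network(ssn: nx.Graph, clusters: Sequence[Cluster]) -> nx.Graph:
    """Condense an SSN into its cluster-level meta-network.

    Meta-nodes are clusters; a meta-edge joins two clusters with >= 1
    inter-cluster edge, weighted by the proportion of realised inter-cluster
    edges: ``crossing edges / (|A| * |B|)``, in (0, 1].
    """
    covered = set()
    cluster_of = {}
    for c in clusters:
        for m in c.member_ids:
            if m in cluster_of:
                raise ValueError(f"node {m} appears in two clusters")
            cluster_of[m] = c.cluster_id
        covered |= c.member_ids
    if covered != set(ssn.nodes):
        raise ValueError("clusters do not partition the SSN node set")
    sizes = {c.cluster_id: c.size for c in clusters}
    meta = nx.Graph()
    meta.add_nodes_from(sizes)
    crossing: Dict[tuple, int] = {}
    for a, b in ssn.edges():
        ca, cb = cluster_of[a], cluster_of[b]
        if ca == cb:
            continue
        key = tuple(sorted((ca, cb)))
        crossing[key] = crossing.get(key, 0) + 1
    for (ca, cb), n in crossing.items():
        meta.add_edge(ca, cb, weight=n / (sizes[ca] * sizes[cb]))
    return meta


def clusters_to_frame(clusters: Sequence[Cluster], family_id: str = "") -> pd.DataFrame:
    rows = [
        {"sequence_id": m, "family_id": family_id, "cluster_id": c.cluster_id}
        for c in clusters
        for m in sorted(c.member_ids)
    ]
    return pd.DataFrame(rows, columns=["sequence_id", "family_id", "cluster_id"])


def cluster_stats_frame(clusters: Sequence[Cluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "size": c.size,
                "env_fraction": c.env_fraction,
                "mean_closest_published_similarity": c.mean_closest_published_similarity,
            }
            for c in clusters
        ],
        columns=["cluster_id", "size", "env_fraction", "mean_closest_published_similarity"],
    )
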