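"""Seed-family selection from a reference all-against-all similarity network.

Conserved families shared between Archaea and Bacteria are identified as
connected components of the reference SSN that mix Domains of life
assortatively (sequences connect preferentially within their own Domain,
indicating vertical conservation rather than lateral transfer) and that
contain enough members from both prokaryotic Domains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import networkx as nx
import pandas as pd

logger = logging.getLogger("divmine.refselect")


@dataclass
class ReferenceComponent:
    """One connected component of the reference SSN with Domain labels."""

    member_ids: frozenset
    edges: frozenset  # frozenset of frozenset pairs
    domain_of: Dict[str, str]

    @property
    def size(self) -> int:
        return len(self.member_ids)

    def domain_count(self, domain: str) -> int:
        return sum(1 for m in self.member_ids if self.domain_of.get(m) == domain)


def connected_components(
    edges: Iterable[Tuple[str, str]],
    nodes: Iterable[str],
    domain_of: Dict[str, str] | None = None,
) -> List[ReferenceComponent]:
    """Partition a node set into maximal connected components.

    Isolated nodes form singleton components. Components are returned sorted
    by (descending size, smallest member id) for determinism.
    """
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    domain_of = domain_of or {}
    comps = []
    for members in nx.connected_components(g):
        sub = g.subgraph(members)
        comps.append(
            ReferenceComponent(
                member_ids=frozenset(members),
                edges=frozenset(frozenset(e) for e in sub.edges()),
                domain_of={m: domain_of[m] for m in members if m in domain_of},
            )
        )
    comps.sort(key=lambda c: (-c.size, min(c.member_ids)))
    return comps


def domain_assortativity(component: ReferenceComponent) -> float:
    """Newman attribute assortativity of Domain labels over the edges.

    With mixing matrix e (fraction of edge ends joining Domain i to j),
    ``r = (sum_i e_ii - sum_i a_i b_i) / (1 - sum_i a_i b_i)``. A component
    whose members all share one label is perfectly assortative (r = 1).
    Raises ``ValueError`` on a component without edges.
    """
    if not component.edges:
        raise ValueError("assortativity undefined for a component without edges")
    labels = {component.domain_of.get(m) for m in component.member_ids}
    if len(labels) == 1:
        return 1.0
    g = nx.Graph()
    for e in component.edges:
        pair = tuple(e)
        if len(pair) == 1:  # self-loop guard
            continue
        g.add_edge(*pair)
    for m in component.member_ids:
        g.add_node(m)
    nx.set_node_attributes(g, {m: component.domain_of.get(m, "?") for m in g.nodes}, "domain")
    r = nx.attribute_assortativity_coefficient(g, "domain")
    if pd.isna(r):  # degenerate mixing matrix (all edge ends one label)
        return 1.0
    return float(r)


def select_seed_families(
    components: Sequence[ReferenceComponent],
    min_assortativity: float = 0.65,
    min_per_domain: int = 150,
) -> List[ReferenceComponent]:
    """Retain components with Domain assortativity >= ``min_assortativity``
    and at least ``min_per_domain`` archaeal AND bacterial members.

    Eukaryotic, viral and plasmidic members remain inside selected families
    but do not count toward the per-Domain minima. Edge-less components are
    skipped (they cannot satisfy the count thresholds anyway).
    """
    selected = []
    for comp in components:
        n_arc = comp.domain_count("Archaea")
        n_bac = comp.domain_count("Bacteria")
        if n_arc < min_per_domain or n_bac < min_per_domain:
            continue
        if not comp.edges:
            continue
        if domain_assortativity(comp) >= min_assortativity:
            selected.append(comp)
    logger.info(
        "seed-family selection: %d/%d components retained (r >= %s, >= %d per Domain)",
        len(selected), len(components), min_assortativity, min_per_domain,
    )
    return selected


def families_to_frame(families: Sequence[ReferenceComponent]) -> pd.DataFrame:
    """Family membership table (family_id, sequence_id)."""
    rows = []
    for i, fam in enumerate(families, start=1):
        fam_id = f"FAM{i:04d}"
        for m in sorted(fam.member_ids):
            rows.append({"family_id": fam_id, "sequence_id": m})
    return pd.DataFrame(rows, columns=["family_id", "sequence_id"])
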