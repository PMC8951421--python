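"""Functional similarity networks and their communities.

Genes become nodes; an edge joins two genes whose GO-based similarity
meets a threshold.  Communities are found by divisive edge-betweenness
removal (Girvan–Newman) with the dendrogram cut at maximum modularity,
and each community is summarised by its *same-TAD-belonging ratio*:
distinct TADs represented divided by community size, so 1 means every
member sits in its own TAD and small values mean co-localisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from tadfunc.genome_model import DomainPartition
from tadfunc.pair_analysis import InsufficientDataError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Community:
    members: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.members)


def build_fsn(
    sim_table: Mapping[tuple[str, str], float], threshold: float
) -> nx.Graph:
    """Build the functional similarity network: an edge per scored pair
    with similarity >= threshold (inclusive).  Genes appearing only in
    sub-threshold pairs are absent, not isolated."""
    g = nx.Graph()
    for (a, b), sim in sim_table.items():
        if a != b and sim >= threshold:
            g.add_edge(a, b, similarity=sim)
    return g


def detect_communities(network: nx.Graph) -> list[Community]:
    """Divisive Girvan–Newman communities, unweighted betweenness.

    The partition along the dendrogram with maximal modularity is
    returned; modularity ties break toward fewer communities.  Isolated
    nodes (if present) come back as singletons; connected components are
    the coarsest partition considered.
    """
    if network.number_of_nodes() == 0:
        return []
    if network.number_of_edges() == 0:
        return [Community(frozenset([n])) for n in network.nodes]
    best = [frozenset(c) for c in nx.connected_components(network)]
    best_q = nx.community.modularity(network, best)
    for partition in nx.community.girvan_newman(network):
        q = nx.community.modularity(network, partition)
        if q > best_q:
            best_q = q
            best = [frozenset(c) for c in partition]
    return [Community(frozenset(c)) for c in best]


def same_tad_ratio(community: Community | Iterable[str], partition: DomainPartition) -> float:
    """Distinct-TAD count over member count for one community.

    Members not assigned to any TAD are dropped (logged); an empty
    community (or one with no TAD-assigned member) is an error.
    """
    members = community.members if isinstance(community, Community) else set(community)
    if not members:
        raise InsufficientDataError("empty community")
    tads = []
    dropped = 0
    for gid in members:
        dom = partition.domain_of(gid)
        if dom is None or dom[0] != "tad":
            dropped += 1
            continue
        tads.append(dom[1])
    if dropped:
        logger.info("dropped %d community members without a TAD assignment", dropped)
    if not tads:
        raise InsufficientDataError("no TAD-assigned members")
    return len(set(tads)) / len(tads)


def random_communities(
    network: nx.Graph, sizes: Sequence[int], rng: np.random.Generator
) -> list[Community]:
    """Size-matched random communities: for each requested size, a
    uniform sample of network nodes without replacement."""
    nodes = sorted(network.nodes)
    out = []
    for size in sizes:
        if size > len(nodes):
            raise ValueError(f"community size {size} exceeds {len(nodes)} nodes")
        idx = rng.choice(len(nodes), size=size, replace=False)
        out.append(Community(frozenset(nodes[i] for i in idx)))
    return out


def size_ratio_correlation(
    communities: Sequence[Community], partition: DomainPartition
) -> tuple[float, float]:
    """Pearson correlation between community size and same-TAD ratio."""
    if len(communities) < 3:
        raise InsufficientDataError(f"{len(communities)} communities, need >= 3")
    sizes = [c.size for c in communities]
    ratios = [same_tad_ratio(c, partition) for c in communities]
    if len(set(ratios)) == 1 or len(set(sizes)) == 1:
        raise InsufficientDataError("constant sizes or ratios; r undefined")
    r, p = stats.pearsonr(sizes, ratios)
    return float(r), float(p)


def ratio_report(
    communities: Sequence[Community], partition: DomainPartition
):
    """Per-community table (community_id, size, ratio) sorted by size
    descending, the ordering used for the ratio bar plots."""
    import pandas as pd

    rows = []
    ordered = sorted(communities, key=lambda c: (-c.size, sorted(c.members)))
    for i, c in enumerate(ordered, start=1):
        rows.append(
            {"community_id": i, "size": c.size, "ratio": same_tad_ratio(c, partition)}
        )
    return pd.DataFrame(rows)
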