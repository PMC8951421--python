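"""Gene–gene spatial interaction (GGSI) networks from Hi-C contacts.

A binned contact matrix is aggregated to gene pairs (summing counts over
all bin pairs the two gene bodies overlap), and two network flavours are
built: HiC-GGSI, with an edge when both the contact count and the
genomic distance clear thresholds, and HiC-TAD-GGSI, which keeps every
HiC-GGSI edge and adds edges between same-TAD genes beyond the distance
threshold.  Edge provenance (contact / same-TAD / predicted) is kept so
reconstructed and union networks can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from tadfunc.genome_model import Gene, DomainPartition


@dataclass
class ContactMatrix:
    """Symmetric binned Hi-C contacts of one chromosome at a fixed
    resolution; entries keyed by unordered (bin_i, bin_j) index pairs."""

    chrom: str
    resolution: int
    entries: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError(f"resolution {self.resolution} must be positive")
        sym = {}
        for (i, j), c in self.entries.items():
            if c < 0:
                raise ValueError(f"negative contact count at ({i}, {j})")
            sym[(min(i, j), max(i, j))] = c
        self.entries = sym

    def get(self, i: int, j: int) -> float:
        return self.entries.get((min(i, j), max(i, j)), 0.0)

    def bins_overlapping(self, start: int, end: int) -> range:
        """Indices of resolution-sized bins overlapping [start, end) by
        at least 1 bp."""
        if end <= start:
            return range(0)
        return range(start // self.resolution, (end - 1) // self.resolution + 1)

    @classmethod
    def from_tsv(cls, path, chrom: str, resolution: int) -> "ContactMatrix":
        """Read TSV triples (bin1_start, bin2_start, count)."""
        df = pd.read_csv(
            path, sep="\t", header=None, names=["b1", "b2", "count"], comment="#"
        )
        entries = {}
        for r in df.itertuples():
            i, j = int(r.b1) // resolution, int(r.b2) // resolution
            key = (min(i, j), max(i, j))
            entries[key] = entries.get(key, 0.0) + float(r.count)
        return cls(chrom, resolution, entries)

    def to_tsv(self, path) -> None:
        rows = [
            (i * self.resolution, j * self.resolution, c)
            for (i, j), c in sorted(self.entries.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def gene_pair_contacts(
    matrix: ContactMatrix,
    genes: Iterable[Gene],
    aggregation: str = "sum",
) -> dict[tuple[str, str], float]:
    """Aggregate binned contacts to gene pairs.

    For genes A and B the value is the sum (or mean, with
    ``aggregation="mean"``) of matrix entries over all unordered bin
    pairs (b1, b2) where b1 overlaps A's body and b2 overlaps B's body
    by at least 1 bp, each unordered bin pair counted once.
    """
    genes = [g for g in genes if g.chrom == matrix.chrom]
    bins = {g.id: set(matrix.bins_overlapping(g.interval.start, g.interval.end)) for g in genes}
    out: dict[tuple[str, str], float] = {}
    ids = sorted(bins)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            seen: set[tuple[int, int]] = set()
            for ba in bins[a]:
                for bb in bins[b]:
                    seen.add((min(ba, bb), max(ba, bb)))
            total = sum(matrix.get(i1, j1) for i1, j1 in seen)
            if aggregation == "mean":
                total = total / len(seen) if seen else 0.0
            out[(a, b)] = total
    return out


@dataclass
class SpatialNetwork:
    """A gene-node graph of one of the spatial-network flavours."""

    kind: str  # HiC-GGSI | HiC-TAD-GGSI | reconstructed | union
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {(min(a, b), max(a, b)) for a, b in self.graph.edges}

    def to_edgelist(self, path) -> None:
        rows = [
            {"gene_a": min(a, b), "gene_b": max(a, b), **d}
            for a, b, d in self.graph.edges(data=True)
        ]
        pd.DataFrame(rows).sort_values(["gene_a", "gene_b"]).to_csv(
            path, sep="\t", index=False
        )


def build_hic_ggsi(
    contact_table: Mapping[tuple[str, str], float],
    genes: Mapping[str, Gene] | Iterable[Gene],
    contact_min: float,
    dist_min: int,
) -> SpatialNetwork:
    """HiC-GGSI: edge iff contacts >= contact_min AND genomic distance
    (midpoint to midpoint) >= dist_min, both inclusive.  Genes with no
    qualifying edge do not enter the network."""
    if not isinstance(genes, Mapping):
        genes = {g.id: g for g in genes}
    net = SpatialNetwork("HiC-GGSI")
    for (a, b), count in contact_table.items():
        if count < contact_min:
            continue
        ga, gb = genes[a], genes[b]
        if ga.chrom != gb.chrom:
            continue
        dist = abs(ga.midpoint - gb.midpoint)
        if dist < dist_min:
            continue
        net.graph.add_edge(a, b, provenance="contact", contacts=count)
    return net


def build_hic_tad_ggsi(
    ggsi: SpatialNetwork,
    partition: DomainPartition,
    dist_min: int,
) -> SpatialNetwork:
    """HiC-TAD-GGSI: every HiC-GGSI edge, plus an edge for each same-TAD
    gene pair at genomic distance >= dist_min."""
    net = SpatialNetwork("HiC-TAD-GGSI", ggsi.graph.copy())
    by_tad: dict[int, list[str]] = {}
    for gid in partition.assigned_genes("tad"):
        by_tad.setdefault(partition.assignment[gid].ordinal, []).append(gid)
    for members in by_tad.values():
        members = sorted(members)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                dist = abs(partition.genes[a].midpoint - partition.genes[b].midpoint)
                if dist < dist_min or net.graph.has_edge(a, b):
                    continue
                net.graph.add_edge(a, b, provenance="same-TAD")
    return net


def topology_metrics(network: SpatialNetwork | nx.Graph) -> dict:
    """Standard topology summaries on the undirected simple graph:
    per-node degree, clustering coefficient and closeness centrality
    (computed within connected components), plus the shortest-path-length
    histogram over all reachable node pairs."""
    g = network.graph if isinstance(network, SpatialNetwork) else network
    degree = dict(g.degree())
    clustering = nx.clustering(g)
    closeness = {}
    path_hist: dict[int, int] = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        closeness.update(nx.closeness_centrality(sub))
        for src, lengths in nx.all_pairs_shortest_path_length(sub):
            for dst, d in lengths.items():
                if src < dst and d > 0:
                    path_hist[d] = path_hist.get(d, 0) + 1
    return {
        "degree": degree,
        "clustering": clustering,
        "closeness": closeness,
        "shortest_path_histogram": dict(sorted(path_hist.items())),
    }
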