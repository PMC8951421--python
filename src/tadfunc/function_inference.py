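"""Gene function inference by neighbour voting on reconstructed networks.

The autoencoder's reconstruction Â gives every gene pair a confidence;
keeping pairs above a confidence threshold (0.6) yields a reconstructed
network.  For a central gene whose function is treated as unknown, every
GO term annotating a radius-one neighbour is a candidate, scored by the
number of neighbours carrying it (its *occurrence*).  Predictions are
evaluated by the best semantic similarity between the top-k ranked terms
and the gene's true terms, averaged over all genes used once as the
centre.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np

from tadfunc.ggsi_networks import SpatialNetwork
from tadfunc.go_similarity import GoDag, TermSimConfig, term_similarity

logger = logging.getLogger(__name__)


def threshold_reconstruction(
    A_hat: np.ndarray, nodes: Sequence[str], conf_min: float = 0.6
) -> SpatialNetwork:
    """Keep reconstructed edges with confidence strictly above
    *conf_min*; self-pairs excluded.  Node order maps matrix indices to
    gene ids."""
    A_hat = np.asarray(A_hat)
    net = SpatialNetwork("reconstructed")
    net.graph.add_nodes_from(nodes)
    n = len(nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if A_hat[i, j] > conf_min:
                net.graph.add_edge(
                    nodes[i], nodes[j],
                    provenance="predicted", confidence=float(A_hat[i, j]),
                )
    return net


def union_network(original: SpatialNetwork, reconstructed: SpatialNetwork) -> SpatialNetwork:
    """Union of nodes and edges of the original and reconstructed
    networks; edge attributes from the original win on overlap."""
    net = SpatialNetwork("union", reconstructed.graph.copy())
    net.graph.add_nodes_from(original.graph.nodes)
    for a, b, d in original.graph.edges(data=True):
        net.graph.add_edge(a, b, **d)
    return net


def infer_terms(
    network: SpatialNetwork,
    annotations: Mapping[str, set[str]],
    central_gene: str,
) -> list[tuple[str, int]]:
    """Rank candidate GO terms for *central_gene* by neighbour occurrence.

    Each term's score is the number of radius-one neighbours annotated
    with it (annotations de-duplicated per gene).  Ties break by the
    summed confidence of the edges to the neighbours carrying the term
    (descending), then by term id.  The central gene's own annotations
    are never consulted.
    """
    g = network.graph
    if central_gene not in g:
        raise KeyError(f"{central_gene} not in network")
    occurrence: dict[str, int] = {}
    conf_sum: dict[str, float] = {}
    for nb in g.neighbors(central_gene):
        conf = g.edges[central_gene, nb].get("confidence", 1.0)
        for term in set(annotations.get(nb, set())):
            occurrence[term] = occurrence.get(term, 0) + 1
            conf_sum[term] = conf_sum.get(term, 0.0) + conf
    ranked = sorted(
        occurrence.items(), key=lambda kv: (-kv[1], -conf_sum[kv[0]], kv[0])
    )
    return ranked


def evaluate_topk(
    network: SpatialNetwork,
    annotations: Mapping[str, set[str]],
    dag: GoDag,
    k: int = 1,
    config: TermSimConfig | None = None,
) -> float:
    """Mean best semantic similarity between top-k predictions and true
    terms, over every network gene used once as the central gene.

    Genes with no true terms or no predictions are excluded (logged).
    """
    config = config or TermSimConfig()
    per_gene: list[float] = []
    skipped = 0
    for gene in sorted(network.graph.nodes):
        true_terms = annotations.get(gene, set())
        predicted = [t for t, _s in infer_terms(network, annotations, gene)[:k]]
        if not true_terms or not predicted:
            skipped += 1
            continue
        best = 0.0
        for pt in predicted:
            for tt in true_terms:
                try:
                    best = max(best, term_similarity(dag, pt, tt, config))
                except Exception:
                    continue  # cross-namespace candidate: not comparable
        per_gene.append(best)
    if skipped:
        logger.info("excluded %d genes without terms or predictions", skipped)
    if not per_gene:
        raise ValueError("no evaluable genes")
    return float(np.mean(per_gene))
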