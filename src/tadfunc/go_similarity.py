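"""GO DAG handling, annotation filtering and functional similarity.

Term–term similarity follows the Wang hybrid semantic-value scheme: a
term's *semantic value* is accumulated over its ancestor closure with a
per-edge decay weight, and two terms are compared through the overlap of
their weighted ancestor sets.  Two weighting backends are provided:

``"wang"``
    fixed decay weights, is_a 0.8 / part_of 0.6;
``"topo"`` (default)
    topology-dependent weights ``1/(c + n_children(parent)) + w0`` so
    that edges into sparsely branching terms decay less — the scheme
    used by GOGO-style tools.

Gene-pair similarity is the best-match average (BMA) over the two genes'
filtered term sets within one namespace, in [0, 1] with 1 meaning the
genes carry identical functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import obonet

logger = logging.getLogger(__name__)

NAMESPACES = {
    "biological_process": "BPO",
    "cellular_component": "CCO",
    "molecular_function": "MFO",
}
ROOT_TERMS = {
    "BPO": "GO:0008150",
    "CCO": "GO:0005575",
    "MFO": "GO:0003674",
}
EXPERIMENTAL_CODES = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})


class NamespaceMismatchError(ValueError):
    """Similarity requested between terms of different GO namespaces."""


@dataclass(frozen=True)
class TermSimConfig:
    """Configuration of the term-similarity backend.

    measure: "topo" (GOGO-style topology-dependent weights) or "wang".
    w_is_a / w_part_of: decay weights for the "wang" backend, and the
    additive floor ``w0`` for the "topo" backend (where the weight is
    ``1/(c + n_children) + w0``, capped just below 1).
    aggregation: "bma" (best-match average) or "abm" (average of the two
    directional best-match means computed as max-then-mean; identical to
    bma here, kept for the configurable variant).
    """

    measure: str = "topo"
    w_is_a: float = 0.8
    w_part_of: float = 0.6
    topo_c: float = 0.67
    topo_w0_is_a: float = 0.4
    topo_w0_part_of: float = 0.3
    aggregation: str = "bma"


class GoDag:
    """A parsed GO DAG: term -> namespace, parents (is_a / part_of) and
    the transitive ancestor closure used by the Wang-style measures."""

    def __init__(
        self,
        parents: Mapping[str, Iterable[tuple[str, str]]],
        namespaces: Mapping[str, str],
        alt_ids: Mapping[str, str] | None = None,
    ) -> None:
        self.parents = {t: list(ps) for t, ps in parents.items()}
        self.namespace = dict(namespaces)
        self.alt_ids = dict(alt_ids or {})
        self._n_children: dict[str, int] = {t: 0 for t in self.parents}
        for t, ps in self.parents.items():
            for p, _rel in ps:
                self._n_children[p] = self._n_children.get(p, 0) + 1
        self._sv_cache: dict[tuple[str, int], dict[str, float]] = {}

    def resolve(self, term: str) -> str:
        return self.alt_ids.get(term, term)

    def __contains__(self, term: str) -> bool:
        return self.resolve(term) in self.namespace

    def n_children(self, term: str) -> int:
        return self._n_children.get(term, 0)

    def root_of(self, term: str) -> str:
        return ROOT_TERMS[self.namespace[self.resolve(term)]]

    @classmethod
    def from_obo(cls, path) -> "GoDag":
        """Load from an OBO 1.2 file via obonet.

        Obsolete terms are skipped; relationship types other than is_a /
        part_of are collapsed to is_a; alt_ids resolve to primary ids.
        """
        graph = obonet.read_obo(path, ignore_obsolete=True)
        parents: dict[str, list[tuple[str, str]]] = {}
        namespaces: dict[str, str] = {}
        alt_ids: dict[str, str] = {}
        for term, data in graph.nodes(data=True):
            ns = NAMESPACES.get(data.get("namespace", ""))
            if ns is None:
                continue
            namespaces[term] = ns
            parents[term] = []
            for alt in data.get("alt_id", []):
                alt_ids[alt] = term
        for child, parent, rel in graph.edges(keys=True):
            if child not in namespaces or parent not in namespaces:
                continue
            relation = "part_of" if rel == "part_of" else "is_a"
            parents[child].append((parent, relation))
        return cls(parents, namespaces, alt_ids)

    # -- semantic values ----------------------------------------------------

    def _edge_weight(self, parent: str, relation: str, config: TermSimConfig) -> float:
        if config.measure == "wang":
            return config.w_is_a if relation == "is_a" else config.w_part_of
        w0 = config.topo_w0_is_a if relation == "is_a" else config.topo_w0_part_of
        w = 1.0 / (config.topo_c + max(1, self.n_children(parent))) + w0
        return min(w, 0.999)

    def semantic_values(self, term: str, config: TermSimConfig) -> dict[str, float]:
        """S-values of *term* over its ancestor closure (term itself -> 1;
        each ancestor -> max over paths of the product of edge weights)."""
        term = self.resolve(term)
        key = (term, hash(config))
        cached = self._sv_cache.get(key)
        if cached is not None:
            return cached
        sv = {term: 1.0}
        # descending-value frontier relaxation; DAG so this terminates
        frontier = [term]
        while frontier:
            nxt: list[str] = []
            for t in frontier:
                for parent, rel in self.parents.get(t, []):
                    cand = sv[t] * self._edge_weight(parent, rel, config)
                    if cand > sv.get(parent, 0.0):
                        sv[parent] = cand
                        nxt.append(parent)
            frontier = nxt
        self._sv_cache[key] = sv
        return sv


@dataclass
class AnnotationSet:
    """Map gene id -> set of (term id, evidence code)."""

    annotations: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def add(self, gene: str, term: str, evidence: str) -> None:
        self.annotations.setdefault(gene, set()).add((term, evidence))

    def terms(self, gene: str, dag: GoDag | None = None, ontology: str | None = None) -> set[str]:
        """Term ids for *gene*, optionally restricted to one namespace."""
        out = {t for t, _e in self.annotations.get(gene, set())}
        if ontology is not None:
            if dag is None:
                raise ValueError("ontology filter requires a dag")
            out = {t for t in out if t in dag and dag.namespace[dag.resolve(t)] == ontology}
        return out

    def genes(self) -> list[str]:
        return sorted(self.annotations)

    @classmethod
    def from_gaf(cls, path) -> "AnnotationSet":
        """Read a GAF 2.x file (gene symbol, GO id, evidence code, aspect)."""
        from Bio.UniProt import GOA

        out = cls()
        with open(path) as fh:
            for rec in GOA.gafiterator(fh):
                out.add(rec["DB_Object_Symbol"], rec["GO_ID"], rec["Evidence"])
        return out


def filter_annotations(raw: AnnotationSet, dag: GoDag) -> AnnotationSet:
    """Keep experimental-evidence annotations (EXP, IDA, IPI, IMP, IGI,
    IEP), drop the three namespace roots and any term absent from the DAG
    (dropped unknowns are counted in a log message)."""
    out = AnnotationSet()
    roots = set(ROOT_TERMS.values())
    unknown = 0
    for gene, anns in raw.annotations.items():
        for term, code in anns:
            if code not in EXPERIMENTAL_CODES:
                continue
            if term not in dag:
                unknown += 1
                continue
            term = dag.resolve(term)
            if term in roots:
                continue
            out.add(gene, term, code)
    if unknown:
        logger.info("dropped %d annotations with unknown term ids", unknown)
    return out


def term_similarity(
    dag: GoDag, t1: str, t2: str, config: TermSimConfig | None = None
) -> float:
    """Wang-style similarity between two terms of the same namespace.

    Symmetric, in [0, 1], and exactly 1 for identical terms.
    """
    config = config or TermSimConfig()
    t1, t2 = dag.resolve(t1), dag.resolve(t2)
    if dag.namespace[t1] != dag.namespace[t2]:
        raise NamespaceMismatchError(
            f"{t1} ({dag.namespace[t1]}) vs {t2} ({dag.namespace[t2]})"
        )
    if t1 == t2:
        return 1.0
    sv1 = dag.semantic_values(t1, config)
    sv2 = dag.semantic_values(t2, config)
    common = set(sv1) & set(sv2)
    if not common:
        return 0.0
    num = sum(sv1[t] + sv2[t] for t in common)
    den = sum(sv1.values()) + sum(sv2.values())
    return num / den


def gene_pair_similarity(
    dag: GoDag,
    terms_a: Iterable[str],
    terms_b: Iterable[str],
    config: TermSimConfig | None = None,
) -> float | None:
    """Best-match-average similarity between two term sets.

    Returns None (undefined) when either set is empty; downstream code
    drops such pairs.  All terms must share one namespace.
    """
    config = config or TermSimConfig()
    ta = sorted({dag.resolve(t) for t in terms_a})
    tb = sorted({dag.resolve(t) for t in terms_b})
    if not ta or not tb:
        return None
    sims = [[term_similarity(dag, a, b, config) for b in tb] for a in ta]
    best_a = [max(row) for row in sims]
    best_b = [max(sims[i][j] for i in range(len(ta))) for j in range(len(tb))]
    if config.aggregation == "abm":
        # average of the two directional means
        return 0.5 * (sum(best_a) / len(best_a) + sum(best_b) / len(best_b))
    # bma: mean over all row- and column-wise best matches
    return (sum(best_a) + sum(best_b)) / (len(best_a) + len(best_b))


def pairwise_similarity_table(
    dag: GoDag,
    annotations: AnnotationSet,
    pairs: Iterable[tuple[str, str]],
    ontology: str,
    config: TermSimConfig | None = None,
) -> dict[tuple[str, str], float]:
    """Gene-pair similarities for *pairs* within one ontology; pairs where
    either gene lacks terms are omitted (logged)."""
    config = config or TermSimConfig()
    out: dict[tuple[str, str], float] = {}
    skipped = 0
    for a, b in pairs:
        s = gene_pair_similarity(
            dag,
            annotations.terms(a, dag, ontology),
            annotations.terms(b, dag, ontology),
            config,
        )
        if s is None:
            skipped += 1
            continue
        out[(a, b)] = s
    if skipped:
        logger.info("skipped %d pairs with no %s terms", skipped, ontology)
    return out
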