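"""Seeded generators for every input the pipeline consumes.

The generator emulates a single desk-scale chromosome organised into
TADs separated by gap regions (about half of which have zero length, as
real TAD calls do), with protein-coding genes dropped into the domains,
a random GO DAG whose *functional modules* are coherent term subtrees,
module-correlated annotations and expression, a distance-decay Hi-C
contact map with TAD enrichment and planted long-range loops, and a
planted set of duplicate gene pairs for the identity filter.

Planted structure and what it exercises:

* genes of one TAD draw their GO terms from that TAD's module with
  probability ``p_intra`` (background otherwise) — intra-TAD pairs end
  up functionally more similar than inter-TAD pairs;
* expected Hi-C counts follow ``c0 * d^(-alpha)``, multiplied by
  ``beta`` within a TAD, plus flat blocks between loop TAD pairs; raw
  counts are Poisson draws and the normalised map is a global rescale;
* loop TAD pairs share one functional module, so their long-range
  strong region pairs contain functionally similar gene groups;
* ``p_intra = p_inter`` together with ``beta = 1`` and no loops gives
  the matched negative control with no planted structure.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from tadfunc.genome_model import (
    Domain,
    DomainPartition,
    Gene,
    GenomicInterval,
    assign_genes,
    derive_gaps,
)
from tadfunc.ggsi_networks import ContactMatrix
from tadfunc.go_similarity import AnnotationSet, GoDag


def derive_seed(master: int, stage: str, repeat: int = 0) -> int:
    """Per-stage seed derived from the master seed (stable across runs)."""
    return (int(master) * 2654435761 + zlib.crc32(f"{stage}:{repeat}".encode())) % (2**31 - 1)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic chromosome.

    Defaults are the desk-scale positive control: a 10 Mbp-scale
    chromosome with 10 TADs of ~0.8 Mbp, ~300 genes, 40 kbp Hi-C bins,
    strong within-TAD annotation coherence and TAD-enriched contacts
    with two planted long-range loops.
    """

    seed: int = 0
    chrom: str = "chrS"
    n_tads: int = 10
    tad_length_mean: int = 800_000
    tad_length_sd: int = 150_000
    gap_length_mean: int = 150_000
    zero_gap_fraction: float = 0.5
    n_genes: int = 300
    gene_length_mean: int = 15_000
    boundary_gene_fraction: float = 0.04
    # ontology / annotation
    n_background_terms: int = 40
    terms_per_module: int = 6
    terms_per_gene: int = 3
    p_intra: float = 0.7
    p_inter: float = 0.15
    # "tad": a gene's module is its TAD's module (planted co-localisation);
    # "random": modules are assigned to genes independently of TADs, the
    # no-structure null in which intra and inter pairs are exchangeable
    module_coupling: str = "tad"
    nonexperimental_fraction: float = 0.15
    # Hi-C
    resolution: int = 40_000
    contact_base: float = 200.0
    alpha: float = 1.0
    beta: float = 4.0
    loops: tuple[tuple[int, int, float], ...] = ((2, 8, 400.0), (3, 9, 300.0))
    # expression
    expression_noise_sd: float = 0.25
    # duplicates
    duplicate_fraction: float = 0.03

    def __post_init__(self):
        for p in (self.zero_gap_fraction, self.p_intra, self.p_inter,
                  self.boundary_gene_fraction, self.duplicate_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.beta < 1.0:
            raise ValueError(f"TAD enrichment beta {self.beta} must be >= 1")

    def negative_control(self) -> "SimConfig":
        """The matched no-structure configuration: p_intra = p_inter,
        beta = 1, no loops, and module identity decoupled from TADs."""
        return replace(
            self, p_intra=self.p_inter, beta=1.0, loops=(),
            module_coupling="random",
        )


@dataclass
class GenomeData:
    chrom: str
    chrom_length: int
    tads: list[Domain]
    genes: list[Gene]


def make_genome(config: SimConfig, rng: np.random.Generator | None = None) -> GenomeData:
    """Sorted non-overlapping TADs separated by gaps (a configurable
    fraction of zero length), with genes placed fully inside domains
    plus a small boundary-spanning fraction that assignment must
    exclude."""
    rng = rng or np.random.default_rng(derive_seed(config.seed, "genome"))
    pos = 0
    tads: list[Domain] = []
    for i in range(1, config.n_tads + 1):
        if i == 1 or rng.random() >= config.zero_gap_fraction:
            gap_len = int(rng.exponential(config.gap_length_mean)) + 10_000
            pos += gap_len
        length = int(
            max(200_000, rng.normal(config.tad_length_mean, config.tad_length_sd))
        )
        tads.append(Domain("tad", i, GenomicInterval(config.chrom, pos, pos + length)))
        pos += length
    tail = int(rng.exponential(config.gap_length_mean)) + 10_000
    chrom_length = -(-(pos + tail) // config.resolution) * config.resolution

    gaps, _ = derive_gaps(tads)
    domains = tads + gaps
    lengths = np.array([len(d.interval) for d in domains], dtype=float)
    weights = lengths / lengths.sum()

    genes: list[Gene] = []
    n_boundary = int(round(config.boundary_gene_fraction * config.n_genes))
    n_inside = config.n_genes - n_boundary
    for k in range(n_inside):
        d = domains[rng.choice(len(domains), p=weights)]
        glen = int(max(1_000, rng.exponential(config.gene_length_mean)))
        glen = min(glen, len(d.interval) - 2)
        start = d.interval.start + int(rng.integers(0, len(d.interval) - glen))
        genes.append(
            Gene(f"G{k:04d}", GenomicInterval(config.chrom, start, start + glen))
        )
    # boundary-spanning genes centred on TAD starts (after gap 1)
    for k in range(n_boundary):
        tad = tads[int(rng.integers(0, len(tads)))]
        half = int(max(2_000, rng.exponential(config.gene_length_mean) / 2))
        start = max(0, tad.interval.start - half)
        genes.append(
            Gene(
                f"G{n_inside + k:04d}",
                GenomicInterval(config.chrom, start, tad.interval.start + half),
            )
        )
    return GenomeData(config.chrom, chrom_length, tads, genes)


def make_partition(config: SimConfig, genome: GenomeData) -> DomainPartition:
    gaps, dropped = derive_gaps(genome.tads)
    partition = DomainPartition(
        genome.chrom, genome.tads, gaps, dropped_zero_gaps=dropped
    )
    return assign_genes(genome.genes, partition)


_NS_PREFIX = {"BPO": 1, "CCO": 2, "MFO": 3}
_NS_LONG = {
    "BPO": "biological_process",
    "CCO": "cellular_component",
    "MFO": "molecular_function",
}
_ROOTS = {"BPO": "GO:0008150", "CCO": "GO:0005575", "MFO": "GO:0003674"}


@dataclass
class OntologyData:
    dag: GoDag
    module_terms: dict[int, list[str]]  # module id -> coherent term clique (BPO)
    background_terms: list[str]
    module_of_tad: dict[int, int]
    module_of_gene: dict[str, int | None]
    annotations: AnnotationSet  # raw, pre-filtering


def _term_id(ns: str, i: int) -> str:
    return f"GO:{_NS_PREFIX[ns]}{i:06d}"


def make_ontology_and_annotations(
    config: SimConfig,
    genome: GenomeData,
    partition: DomainPartition,
    rng: np.random.Generator | None = None,
) -> OntologyData:
    """Random rooted DAG per namespace with one coherent term subtree
    per functional module; each gene draws terms from its TAD's module
    with probability p_intra, else from the background.

    Loop TAD pairs share a module so planted long-range partners are
    functionally similar.  Evidence codes mix experimental codes with an
    IEA fraction that the annotation filter must drop.
    """
    rng = rng or np.random.default_rng(derive_seed(config.seed, "ontology"))
    parents: dict[str, list[tuple[str, str]]] = {}
    namespaces: dict[str, str] = {}
    for ns, root in _ROOTS.items():
        namespaces[root] = ns
        parents[root] = []

    def add_term(ns: str, i: int, parent: str, relation: str) -> str:
        t = _term_id(ns, i)
        namespaces[t] = ns
        parents[t] = [(parent, relation)]
        return t

    # background BPO terms: a random tree under the root with occasional
    # extra part_of parents (a DAG, not a tree)
    background: list[str] = []
    counter = 1
    for _ in range(config.n_background_terms):
        parent = _ROOTS["BPO"] if not background or rng.random() < 0.25 else (
            background[int(rng.integers(0, len(background)))]
        )
        rel = "part_of" if rng.random() < 0.2 else "is_a"
        background.append(add_term("BPO", counter, parent, rel))
        counter += 1

    # module subtrees: one parent term per module, terms_per_module leaves
    module_of_tad = {t.ordinal: t.ordinal for t in genome.tads}
    for a, b, _s in config.loops:
        if a in module_of_tad and b in module_of_tad:
            module_of_tad[b] = module_of_tad[a]
    module_ids = sorted(set(module_of_tad.values()))
    module_terms: dict[int, list[str]] = {}
    for m in module_ids:
        parent = add_term("BPO", counter, _ROOTS["BPO"], "is_a")
        counter += 1
        leaves = []
        for _ in range(config.terms_per_module):
            leaves.append(add_term("BPO", counter, parent, "is_a"))
            counter += 1
        module_terms[m] = leaves

    # small CCO / MFO trees so all three namespaces exist
    for ns in ("CCO", "MFO"):
        prev = _ROOTS[ns]
        for i in range(1, 9):
            prev_parent = _ROOTS[ns] if rng.random() < 0.5 else prev
            prev = add_term(ns, i, prev_parent, "is_a")

    dag = GoDag(parents, namespaces)

    annotations = AnnotationSet()
    module_of_gene: dict[str, int | None] = {}
    exp_codes = ["EXP", "IDA", "IPI", "IMP", "IGI", "IEP"]
    for gene in genome.genes:
        if config.module_coupling == "random":
            module = module_ids[int(rng.integers(0, len(module_ids)))]
        else:
            dom = partition.domain_of(gene.id)
            module = module_of_tad.get(dom[1]) if dom and dom[0] == "tad" else None
        module_of_gene[gene.id] = module
        for _ in range(config.terms_per_gene):
            use_module = module is not None and rng.random() < config.p_intra
            if use_module:
                pool = module_terms[module]
            elif module is None and rng.random() < config.p_inter:
                # unassigned/gap genes can still hit a random module
                pool = module_terms[module_ids[int(rng.integers(0, len(module_ids)))]]
            else:
                pool = background
            term = pool[int(rng.integers(0, len(pool)))]
            code = (
                "IEA"
                if rng.random() < config.nonexperimental_fraction
                else exp_codes[int(rng.integers(0, len(exp_codes)))]
            )
            annotations.add(gene.id, term, code)
    return OntologyData(
        dag, module_terms, background, module_of_tad, module_of_gene, annotations
    )


def make_contacts(
    config: SimConfig,
    genome: GenomeData,
    rng: np.random.Generator | None = None,
) -> tuple[ContactMatrix, ContactMatrix]:
    """Raw (Poisson) and globally rescaled normalised contact matrices.

    Expected counts decay as contact_base * d^(-alpha) in bin units,
    multiplied by beta within a TAD, plus a flat block of the loop
    strength between each planted loop TAD pair.  The normalised matrix
    divides raw counts by the mean nonzero raw count.
    """
    rng = rng or np.random.default_rng(derive_seed(config.seed, "contacts"))
    res = config.resolution
    n_bins = genome.chrom_length // res
    tad_of_bin = np.zeros(n_bins, dtype=int)  # 0 = no TAD
    for tad in genome.tads:
        b0 = tad.interval.start // res
        b1 = (tad.interval.end - 1) // res + 1
        tad_of_bin[b0:b1] = tad.ordinal

    i, j = np.triu_indices(n_bins, k=1)
    d = (j - i).astype(float)
    mu = config.contact_base * d ** (-config.alpha)
    same_tad = (tad_of_bin[i] == tad_of_bin[j]) & (tad_of_bin[i] > 0)
    mu[same_tad] *= config.beta
    for ta, tb, strength in config.loops:
        in_a = tad_of_bin[i] == ta
        in_b = tad_of_bin[j] == tb
        in_a2 = tad_of_bin[i] == tb
        in_b2 = tad_of_bin[j] == ta
        block = (in_a & in_b) | (in_a2 & in_b2)
        mu[block] += strength
    raw_counts = rng.poisson(mu)
    nz = raw_counts > 0
    raw_entries = {
        (int(a), int(b)): float(c) for a, b, c in zip(i[nz], j[nz], raw_counts[nz])
    }
    raw = ContactMatrix(config.chrom, res, raw_entries)
    scale = 1.0 / float(np.mean(raw_counts[nz])) if nz.any() else 1.0
    norm = ContactMatrix(
        config.chrom, res, {k: c * scale for k, c in raw_entries.items()}
    )
    return raw, norm


def make_expression(
    config: SimConfig,
    ontology: OntologyData,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Mean normalised expression counts: a module-specific base level
    times lognormal noise, so same-module pairs have systematically
    higher GESS than cross-module pairs."""
    rng = rng or np.random.default_rng(derive_seed(config.seed, "expression"))
    modules = sorted(set(ontology.module_of_tad.values()))
    base = {
        m: float(2.0 ** rng.uniform(3.0, 10.0)) for m in modules
    }
    background_base = {
        None: float(2.0 ** rng.uniform(3.0, 10.0))
    }
    out = {}
    for gene, module in sorted(ontology.module_of_gene.items()):
        b = base.get(module) or background_base[None]
        out[gene] = b * float(rng.lognormal(0.0, config.expression_noise_sd))
    return out


def make_identity_table(
    config: SimConfig,
    genome: GenomeData,
    rng: np.random.Generator | None = None,
) -> tuple[dict[tuple[str, str], tuple[float, float]], set[tuple[str, str]]]:
    """Identity/e-value table with planted duplicate pairs (identity >
    90, e-value < 0.01) and sub-threshold background pairs.

    Returns (table, planted duplicate keys)."""
    rng = rng or np.random.default_rng(derive_seed(config.seed, "identity"))
    ids = [g.id for g in genome.genes]
    n_dup = int(round(config.duplicate_fraction * len(ids)))
    perm = rng.permutation(len(ids))
    table: dict[tuple[str, str], tuple[float, float]] = {}
    planted: set[tuple[str, str]] = set()
    for k in range(n_dup):
        a, b = ids[perm[2 * k]], ids[perm[2 * k + 1]]
        key = (a, b) if a <= b else (b, a)
        table[key] = (float(rng.uniform(90.5, 100.0)), float(10.0 ** rng.uniform(-50, -3)))
        planted.add(key)
    n_bg = 4 * n_dup + 20
    for _ in range(n_bg):
        a, b = (ids[int(x)] for x in rng.integers(0, len(ids), size=2))
        if a == b:
            continue
        key = (a, b) if a <= b else (b, a)
        if key in table:
            continue
        table[key] = (float(rng.uniform(10.0, 80.0)), float(10.0 ** rng.uniform(-2, 1)))
    return table, planted


@dataclass
class SyntheticDataset:
    """All generated inputs plus the planted truth, in memory."""

    config: SimConfig
    genome: GenomeData
    partition: DomainPartition
    ontology: OntologyData
    raw_contacts: ContactMatrix
    norm_contacts: ContactMatrix
    expression: dict[str, float]
    identity_table: dict[tuple[str, str], tuple[float, float]]
    planted_duplicates: set[tuple[str, str]]

    @property
    def dag(self) -> GoDag:
        return self.ontology.dag

    @property
    def annotations(self) -> AnnotationSet:
        return self.ontology.annotations

    def pathway_map(self) -> dict[str, set[str]]:
        """Module membership rendered as pathways (module id -> genes)."""
        out: dict[str, set[str]] = {}
        for gene, m in self.ontology.module_of_gene.items():
            if m is not None:
                out.setdefault(f"MODULE_{m}", set()).add(gene)
        return out

    # -- file emission ------------------------------------------------------

    def write(self, out_dir) -> dict[str, Path]:
        """Emit every input in the on-disk formats the readers consume."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}

        tad_path = out / "tads.bed"
        with open(tad_path, "w") as fh:
            for t in self.genome.tads:
                fh.write(f"{t.interval.chrom}\t{t.interval.start}\t{t.interval.end}\n")
        paths["tads"] = tad_path

        gene_path = out / "genes.bed"
        with open(gene_path, "w") as fh:
            for g in self.genome.genes:
                fh.write(
                    f"{g.interval.chrom}\t{g.interval.start}\t{g.interval.end}\t{g.id}\n"
                )
        paths["genes"] = gene_path

        paths["obo"] = obo_path = out / "ontology.obo"
        write_obo(self.dag, obo_path)
        paths["gaf"] = gaf_path = out / "annotations.gaf"
        write_gaf(self.annotations, gaf_path)

        paths["raw_contacts"] = rc = out / "contacts_raw.tsv"
        self.raw_contacts.to_tsv(rc)
        paths["norm_contacts"] = nc = out / "contacts_norm.tsv"
        self.norm_contacts.to_tsv(nc)

        paths["expression"] = ep = out / "expression.tsv"
        with open(ep, "w") as fh:
            for gene, ec in sorted(self.expression.items()):
                fh.write(f"{gene}\t{ec:.6f}\n")

        paths["identity"] = ip = out / "identity.tsv"
        with open(ip, "w") as fh:
            for (a, b), (ident, ev) in sorted(self.identity_table.items()):
                fh.write(f"{a}\t{b}\t{ident:.2f}\t{ev:.3e}\n")

        paths["pathways"] = pp = out / "pathways.gmt"
        with open(pp, "w") as fh:
            for name, members in sorted(self.pathway_map().items()):
                fh.write("\t".join([name, "synthetic module"] + sorted(members)) + "\n")
        return paths


def write_obo(dag: GoDag, path) -> None:
    """Write the DAG as a minimal OBO 1.2 file obonet can read back."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(dag.namespace):
            fh.write(f"\n[Term]\nid: {term}\nname: synthetic {term}\n")
            fh.write(f"namespace: {_NS_LONG[dag.namespace[term]]}\n")
            for parent, rel in dag.parents.get(term, []):
                if rel == "is_a":
                    fh.write(f"is_a: {parent} ! parent\n")
                else:
                    fh.write(f"relationship: part_of {parent} ! parent\n")


def write_gaf(annotations: AnnotationSet, path) -> None:
    """Write annotations as GAF 2.1."""
    aspect = {"BPO": "P", "CCO": "C", "MFO": "F"}
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for gene in annotations.genes():
            for term, code in sorted(annotations.annotations[gene]):
                ns = term[3]  # namespace digit of the synthetic id scheme
                asp = {"1": "P", "2": "C", "3": "F"}.get(ns, "P")
                row = [
                    "SYN", gene, gene, "", term, "SYN:0000001", code, "",
                    asp, "", "", "gene", "taxon:0", "20240101", "SYN", "", "",
                ]
                fh.write("\t".join(row) + "\n")


def simulate(config: SimConfig | None = None, seed: int | None = None) -> SyntheticDataset:
    """Generate the full synthetic dataset for one configuration."""
    config = config or SimConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    genome = make_genome(config)
    partition = make_partition(config, genome)
    ontology = make_ontology_and_annotations(config, genome, partition)
    raw, norm = make_contacts(config, genome)
    expression = make_expression(config, ontology)
    identity, planted = make_identity_table(config, genome)
    return SyntheticDataset(
        config, genome, partition, ontology, raw, norm, expression, identity, planted
    )
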