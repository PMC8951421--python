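"""Gene-pair enumeration and scoring: intra/inter domain pairs, duplicate
filtering, distance binning, rank-sum comparison, expression similarity
(GESS), score correlation and mutual pathways.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from tadfunc.genome_model import DomainPartition, DomainKind


class InsufficientPairsError(ValueError):
    """Fewer eligible pairs than requested."""


class InsufficientDataError(ValueError):
    """Too few observations for the statistic."""


class DegenerateRangeError(ValueError):
    """Expression range max == min; GESS undefined."""


def _key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class GenePair:
    """An unordered pair of distinct genes.

    ``genomic_distance`` is |midpoint A - midpoint B| and is defined only
    for same-chromosome pairs (None otherwise).
    """

    gene_a: str
    gene_b: str
    genomic_distance: int | None = None
    relation: str | None = None

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-pair {self.gene_a}")

    @property
    def key(self) -> tuple[str, str]:
        return _key(self.gene_a, self.gene_b)


def _distance(partition: DomainPartition, a: str, b: str, anchor: str = "midpoint") -> int | None:
    ga, gb = partition.genes[a], partition.genes[b]
    if ga.chrom != gb.chrom:
        return None
    if anchor == "start":
        return abs(ga.interval.start - gb.interval.start)
    return abs(ga.midpoint - gb.midpoint)


def enumerate_intra_pairs(
    partition: DomainPartition, kind: DomainKind, relation: str | None = None
) -> list[GenePair]:
    """All unordered pairs of assigned genes sharing one domain of *kind*."""
    relation = relation or f"intra-{kind}"
    by_domain: dict[int, list[str]] = {}
    for gid in partition.assigned_genes(kind):
        by_domain.setdefault(partition.assignment[gid].ordinal, []).append(gid)
    pairs = []
    for members in by_domain.values():
        members = sorted(members)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                pairs.append(GenePair(a, b, _distance(partition, a, b), relation))
    return pairs


def sample_inter_pairs(
    partition: DomainPartition,
    kind: DomainKind,
    n: int,
    rng: np.random.Generator,
    scope: str = "same-chromosome",
) -> list[GenePair]:
    """Sample *n* unordered pairs of genes assigned to *different* domains
    of the given kind, without replacement.

    With scope "same-chromosome" all pairs are on the partition's
    chromosome (a single-chromosome partition makes the genome scope
    identical); pairs are drawn uniformly over the eligible set, seeded
    through *rng*.
    """
    genes = sorted(partition.assigned_genes(kind))
    eligible = []
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            if partition.assignment[a].ordinal != partition.assignment[b].ordinal:
                eligible.append((a, b))
    if n > len(eligible):
        raise InsufficientPairsError(
            f"requested {n} inter-{kind} pairs, only {len(eligible)} eligible"
        )
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [
        GenePair(*eligible[i], _distance(partition, *eligible[i]), f"inter-{kind}")
        for i in sorted(idx)
    ]


def sample_baseline_pairs(
    partition: DomainPartition, n: int, rng: np.random.Generator
) -> list[GenePair]:
    """Sample pairs uniformly over all assigned genes, ignoring domain
    labels (the "random regardless of TADs or gaps" baseline)."""
    genes = sorted(partition.assigned_genes())
    eligible = [
        (a, b) for i, a in enumerate(genes) for b in genes[i + 1:]
    ]
    if n > len(eligible):
        raise InsufficientPairsError(f"requested {n}, only {len(eligible)} pairs exist")
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [
        GenePair(*eligible[i], _distance(partition, *eligible[i]), "baseline")
        for i in sorted(idx)
    ]


def filter_duplicates(
    pairs: Iterable[GenePair],
    identity_table: Mapping[tuple[str, str], tuple[float, float]],
    identity_min: float = 90.0,
    evalue_max: float = 0.01,
) -> list[GenePair]:
    """Drop likely gene-duplicate pairs: identity strictly greater than
    90% AND e-value below 0.01.  Pairs absent from the table are kept."""
    out = []
    for p in pairs:
        rec = identity_table.get(p.key)
        if rec is not None and rec[0] > identity_min and rec[1] < evalue_max:
            continue
        out.append(p)
    return out


def rebalance(
    intra: Sequence[GenePair],
    inter: Sequence[GenePair],
    rng: np.random.Generator,
) -> tuple[list[GenePair], list[GenePair]]:
    """Down-sample the larger set so intra and inter have equal size."""
    n = min(len(intra), len(inter))

    def _sub(pairs: Sequence[GenePair]) -> list[GenePair]:
        if len(pairs) == n:
            return list(pairs)
        idx = rng.choice(len(pairs), size=n, replace=False)
        return [pairs[i] for i in sorted(idx)]

    return _sub(intra), _sub(inter)


def bin_pairs_by_distance(
    pairs: Iterable[GenePair], bin_size: int
) -> dict[int, list[GenePair]]:
    """Group same-chromosome pairs into half-open distance bins
    [k*bin_size, (k+1)*bin_size): bin index = floor(d / bin_size)."""
    out: dict[int, list[GenePair]] = {}
    for p in pairs:
        if p.genomic_distance is None:
            continue
        out.setdefault(p.genomic_distance // bin_size, []).append(p)
    return out


def significance_tier(p: float) -> str:
    """Map a p-value to the ***, **, *, ns tiers (cutoffs 0.0001, 0.001,
    0.05)."""
    if p < 0.0001:
        return "***"
    if p < 0.001:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_distributions(x: Sequence[float], y: Sequence[float]) -> tuple[float, str]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) comparison of two
    score samples, normal approximation with tie correction.

    Returns (p-value, significance tier).
    """
    if len(x) == 0 or len(y) == 0:
        raise InsufficientDataError("empty sample")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue), significance_tier(float(res.pvalue))


def gess(ec_a: float, ec_b: float, ec_max: float, ec_min: float) -> float:
    """Gene expression similarity score.

    1 - |log2(ecA+1) - log2(ecB+1)| / (log2(max+1) - log2(min+1)),
    clipped to [0, 1]: 1 for identical mean counts, 0 for the
    (max, min) pair.
    """
    if ec_max <= ec_min:
        raise DegenerateRangeError(f"max {ec_max} <= min {ec_min}")
    span = math.log2(ec_max + 1) - math.log2(ec_min + 1)
    diff = abs(math.log2(ec_a + 1) - math.log2(ec_b + 1))
    return min(1.0, max(0.0, 1.0 - diff / span))


def correlate_scores(
    sim_scores: Sequence[float],
    gess_scores: Sequence[float],
    sim_threshold: float = 0.2,
) -> tuple[float, float]:
    """Pearson correlation between functional and expression similarity
    over pairs whose functional similarity exceeds *sim_threshold*."""
    sim = np.asarray(sim_scores, dtype=float)
    ges = np.asarray(gess_scores, dtype=float)
    keep = sim > sim_threshold
    if keep.sum() < 3:
        raise InsufficientDataError(
            f"only {int(keep.sum())} pairs above threshold {sim_threshold}"
        )
    r, p = stats.pearsonr(sim[keep], ges[keep])
    return float(r), float(p)


def mutual_pathways(
    gene_a: str, gene_b: str, pathway_map: Mapping[str, set[str]]
) -> list[str]:
    """Pathways containing both genes; a pair may share several."""
    return sorted(
        pw for pw, members in pathway_map.items()
        if gene_a in members and gene_b in members
    )


def read_identity_table(path) -> dict[tuple[str, str], tuple[float, float]]:
    """Read a TSV of geneA, geneB, %identity, e-value into a map keyed by
    the unordered pair."""
    import pandas as pd

    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["gene_a", "gene_b", "identity", "evalue"], comment="#",
    )
    return {
        _key(str(r.gene_a), str(r.gene_b)): (float(r.identity), float(r.evalue))
        for r in df.itertuples()
    }


def read_expression(path) -> dict[str, float]:
    """Read gene mean normalized expression counts (TSV gene_id, mean)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "ec"], comment="#")
    return {str(r.gene_id): float(r.ec) for r in df.itertuples()}


def read_gmt(path) -> dict[str, set[str]]:
    """Read GMT pathway membership: name, description, members..."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            out[parts[0]] = set(parts[2:])
    return out
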