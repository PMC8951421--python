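"""Genomic data model: intervals, TADs, gap regions and gene assignment.

Coordinates are held internally as 0-based half-open ``[start, end)``
(the BED convention).  Files printed in 1-based inclusive style can be
read with ``coords="inclusive"`` and rendered back with
:func:`to_inclusive`.

A chromosome is partitioned into TADs and the *gap regions* between them
(plus the region before the first TAD).  Genes are assigned to the single
domain that entirely contains their body; genes straddling a domain
boundary are excluded from all downstream analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import pandas as pd


class InvalidIntervalError(ValueError):
    """An interval with end < start or a negative start."""


class InvalidPartitionError(ValueError):
    """TADs overlap or are unsorted."""


DomainKind = Literal["tad", "gap"]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise InvalidIntervalError(
                f"end < start for {self.chrom}:{self.start}-{self.end}"
            )
        if self.start < 0:
            raise InvalidIntervalError(f"negative start {self.start}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """True when *other* lies entirely inside this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlap(self, other: "GenomicInterval") -> int:
        """Length of the intersection in bp (0 when disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def to_inclusive(interval: GenomicInterval) -> tuple[int, int]:
    """Render a half-open interval in 1-unit inclusive style (start, end-1)."""
    return interval.start, interval.end - 1


def from_inclusive(chrom: str, start: int, end: int) -> GenomicInterval:
    """Build an interval from inclusive coordinates (end becomes end+1)."""
    return GenomicInterval(chrom, start, end + 1)


@dataclass(frozen=True)
class Gene:
    id: str
    interval: GenomicInterval

    @property
    def midpoint(self) -> int:
        """Midpoint of the gene body, rounded down; the default anchor for
        gene-to-gene genomic distance."""
        return (self.interval.start + self.interval.end) // 2

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class Domain:
    """A TAD or gap region with its 1-based ordinal along the chromosome."""

    kind: DomainKind
    ordinal: int
    interval: GenomicInterval


@dataclass(frozen=True)
class Assignment:
    """Where a gene landed: a domain, or excluded with a reason."""

    status: Literal["assigned", "excluded"]
    kind: DomainKind | None = None
    ordinal: int | None = None
    reason: str | None = None


@dataclass
class DomainPartition:
    """Ordered TADs and derived gaps of one chromosome, with the map from
    gene id to its containing domain."""

    chrom: str
    tads: list[Domain]
    gaps: list[Domain]
    genes: dict[str, Gene] = field(default_factory=dict)
    assignment: dict[str, Assignment] = field(default_factory=dict)
    dropped_zero_gaps: int = 0

    def domains(self, kind: DomainKind) -> list[Domain]:
        return self.tads if kind == "tad" else self.gaps

    def assigned_genes(self, kind: DomainKind | None = None) -> list[str]:
        out = []
        for gid, a in self.assignment.items():
            if a.status == "assigned" and (kind is None or a.kind == kind):
                out.append(gid)
        return out

    def domain_of(self, gene_id: str) -> tuple[DomainKind, int] | None:
        a = self.assignment.get(gene_id)
        if a is None or a.status != "assigned":
            return None
        return (a.kind, a.ordinal)


def _check_sorted_disjoint(tads: Iterable[Domain]) -> list[Domain]:
    tads = sorted(tads, key=lambda d: d.interval.start)
    for a, b in zip(tads, tads[1:]):
        if a.interval.end > b.interval.start:
            raise InvalidPartitionError(
                f"overlapping TADs {a.interval} and {b.interval}"
            )
    return tads


def derive_gaps(
    tads: list[Domain],
    chrom_origin: int = 0,
    include_tail: bool = False,
    chrom_end: int | None = None,
) -> tuple[list[Domain], int]:
    """Derive gap regions as the complement of the TADs.

    Gap 1 is the region from *chrom_origin* to the first TAD start; each
    subsequent gap sits between two consecutive TADs.  Zero-length gaps
    (abutting TADs) are dropped and do not consume an ordinal; the number
    dropped is returned alongside the retained gaps.  The region after
    the last TAD is not a gap unless *include_tail* is set (then
    *chrom_end* must be given).

    Returns
    -------
    (gaps, n_dropped)
    """
    tads = _check_sorted_disjoint(tads)
    if not tads:
        return [], 0
    chrom = tads[0].interval.chrom
    bounds: list[tuple[int, int]] = []
    prev_end = chrom_origin
    for tad in tads:
        bounds.append((prev_end, tad.interval.start))
        prev_end = tad.interval.end
    if include_tail:
        if chrom_end is None:
            raise ValueError("include_tail requires chrom_end")
        bounds.append((prev_end, chrom_end))
    gaps: list[Domain] = []
    dropped = 0
    for start, end in bounds:
        if end <= start:
            dropped += 1
            continue
        gaps.append(
            Domain("gap", len(gaps) + 1, GenomicInterval(chrom, start, end))
        )
    return gaps, dropped


def assign_genes(genes: Iterable[Gene], partition: DomainPartition) -> DomainPartition:
    """Assign each gene to the unique TAD or gap that contains its body.

    A gene is assigned iff its interval is a subset of exactly one
    domain; genes overlapping two or more domains, straddling a domain
    boundary, or lying wholly outside every domain are excluded with a
    recorded reason.
    """
    partition.genes = {}
    partition.assignment = {}
    domains = partition.tads + partition.gaps
    for gene in genes:
        if gene.chrom != partition.chrom:
            raise ValueError(
                f"gene {gene.id} on {gene.chrom}, partition is {partition.chrom}"
            )
        partition.genes[gene.id] = gene
        hits = [d for d in domains if d.interval.contains(gene.interval)]
        touched = [d for d in domains if d.interval.overlap(gene.interval) > 0]
        if len(hits) == 1:
            partition.assignment[gene.id] = Assignment(
                "assigned", hits[0].kind, hits[0].ordinal
            )
        elif len(touched) >= 2:
            partition.assignment[gene.id] = Assignment(
                "excluded", reason="spans_multiple_domains"
            )
        else:
            partition.assignment[gene.id] = Assignment(
                "excluded", reason="outside_or_boundary"
            )
    return partition


# ---------------------------------------------------------------------------
# readers / writers


def read_tads(
    path, chrom: str | None = None, coords: str = "bed"
) -> list[Domain]:
    """Read TADs from a 3-column BED-like file (chrom, start, end)."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"], comment="#",
    )
    if chrom is not None:
        df = df[df["chrom"] == chrom]
    tads = []
    for i, row in enumerate(df.sort_values("start").itertuples(), start=1):
        iv = (
            from_inclusive(row.chrom, int(row.start), int(row.end))
            if coords == "inclusive"
            else GenomicInterval(row.chrom, int(row.start), int(row.end))
        )
        tads.append(Domain("tad", i, iv))
    return tads


def read_genes_bed(path, chrom: str | None = None, coords: str = "bed") -> list[Gene]:
    """Read genes from a 4+-column BED file (chrom, start, end, id)."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "id"], comment="#",
    )
    if chrom is not None:
        df = df[df["chrom"] == chrom]
    genes = []
    for row in df.itertuples():
        iv = (
            from_inclusive(row.chrom, int(row.start), int(row.end))
            if coords == "inclusive"
            else GenomicInterval(row.chrom, int(row.start), int(row.end))
        )
        genes.append(Gene(str(row.id), iv))
    return genes


def read_genes_gff3(path, chrom: str | None = None) -> list[Gene]:
    """Read gene features (type ``gene``, ``ID=`` attribute) from GFF3.

    GFF3 is 1-based inclusive; converted on read.
    """
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            if chrom is not None and parts[0] != chrom:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID") or attrs.get("gene_id")
            if gid is None:
                continue
            genes.append(
                Gene(gid, from_inclusive(parts[0], int(parts[3]) - 1, int(parts[4]) - 1))
            )
    return genes


def write_assignment(partition: DomainPartition, path) -> None:
    """Write the gene assignment as TSV: gene_id, kind, ordinal, status."""
    rows = []
    for gid, a in sorted(partition.assignment.items()):
        rows.append(
            {
                "gene_id": gid,
                "kind": a.kind or "",
                "ordinal": a.ordinal if a.ordinal is not None else "",
                "status": a.status if a.status == "assigned" else f"excluded:{a.reason}",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
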