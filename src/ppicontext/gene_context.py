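"""Gene-cluster propensity (GCM) and minimum-distance (MDM) scores.

Both methods read gene order off (usually circular) prokaryotic chromosomes.
A gene cluster is a maximal run of consecutive co-directional genes whose
intergenic gaps do not exceed a cutoff (default 100 nt) - an operational
operon.  GCM scores a protein pair by the fraction of reference genomes in
which the two orthologs sit in one cluster.  MDM converts the circular
distance ``d`` between the orthologs' translation start sites into the chance
probability ``min(1, 2d/N)`` that two uniform points on a circle of
circumference ``N`` lie that close, and keeps the minimum over genomes;
smaller is stronger linkage.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass
from functools import cached_property
from typing import IO, Iterable, Mapping, Sequence

from .orthology import OrthologTable

__all__ = [
    "Gene",
    "GenomeAnnotation",
    "GeneClusterSet",
    "find_gene_clusters",
    "gcm_score",
    "circular_distance",
    "mdm_score",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene with 1-based inclusive coordinates."""

    gene_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not 1 <= self.start <= self.end:
            raise ValueError(f"need 1 <= start <= end, got [{self.start}, {self.end}]")

    @property
    def tss(self) -> int:
        """Translation start site: ``start`` on '+', ``end`` on '-'."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class GenomeAnnotation:
    """Ordered gene coordinates on one chromosome."""

    genome_id: str
    length: int
    genes: tuple[Gene, ...]
    circular: bool = True

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("chromosome length must be >= 1")
        ordered = tuple(sorted(self.genes, key=lambda g: (g.start, g.end, g.gene_id)))
        object.__setattr__(self, "genes", ordered)
        ids = [g.gene_id for g in ordered]
        if len(set(ids)) != len(ids):
            raise ValueError("gene ids must be unique within a genome")
        for gene in ordered:
            if gene.end > self.length:
                raise ValueError(
                    f"gene {gene.gene_id} ends at {gene.end} beyond length {self.length}"
                )

    @cached_property
    def _by_id(self) -> dict[str, Gene]:
        return {g.gene_id: g for g in self.genes}

    def gene(self, gene_id: str) -> Gene:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in genome {self.genome_id}") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def to_tsv(self, path: str | os.PathLike | IO[str]) -> None:
        own = isinstance(path, (str, os.PathLike))
        handle = open(path, "w") if own else path
        try:
            handle.write(
                f"#genome_id={self.genome_id}\tlength={self.length}\t"
                f"circular={int(self.circular)}\n"
            )
            handle.write("gene_id\tstart\tend\tstrand\n")
            for gene in self.genes:
                handle.write(f"{gene.gene_id}\t{gene.start}\t{gene.end}\t{gene.strand}\n")
        finally:
            if own:
                handle.close()

    @classmethod
    def from_tsv(cls, path: str | os.PathLike | IO[str]) -> "GenomeAnnotation":
        own = isinstance(path, (str, os.PathLike))
        handle = open(path) if own else path
        try:
            header = handle.readline().strip()
            match = re.match(
                r"#genome_id=(\S+)\tlength=(\d+)\tcircular=([01])", header
            )
            if not match:
                raise ValueError(f"bad annotation header: {header!r}")
            genome_id, length, circular = match.group(1), int(match.group(2)), match.group(3) == "1"
            genes = []
            for line in handle:
                if line.startswith("gene_id") or not line.strip():
                    continue
                gene_id, start, end, strand = line.rstrip("\n").split("\t")
                genes.append(Gene(gene_id, int(start), int(end), strand))
        finally:
            if own:
                handle.close()
        return cls(genome_id, length, tuple(genes), circular)

    @classmethod
    def from_gff3(cls, path: str | os.PathLike | IO[str]) -> "GenomeAnnotation":
        """Read gene features from a minimal single-sequence GFF3 file.

        Chromosome length is taken from the ``##sequence-region`` pragma;
        topology from an optional ``#!circular`` pragma (default circular).
        """
        own = isinstance(path, (str, os.PathLike))
        handle = open(path) if own else path
        genome_id, length, circular = None, None, True
        genes = []
        try:
            for line in handle:
                if line.startswith("##sequence-region"):
                    _, seqid, _, end = line.split()
                    genome_id, length = seqid, int(end)
                    continue
                if line.startswith("#!circular"):
                    circular = line.split()[-1].lower() in ("1", "true", "yes")
                    continue
                if line.startswith("#") or not line.strip():
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 9 or fields[2] != "gene":
                    continue
                attrs = dict(
                    item.split("=", 1) for item in fields[8].split(";") if "=" in item
                )
                gene_id = attrs.get("ID") or attrs.get("Name")
                if gene_id is None:
                    raise ValueError(f"gene feature without ID attribute: {line!r}")
                genes.append(Gene(gene_id, int(fields[3]), int(fields[4]), fields[6]))
        finally:
            if own:
                handle.close()
        if genome_id is None or length is None:
            raise ValueError("GFF3 input lacks a ##sequence-region pragma")
        return cls(genome_id, length, tuple(genes), circular)


@dataclass(frozen=True)
class GeneClusterSet:
    """Disjoint co-directional gene clusters of one genome, each ordered
    along the chromosome (wrap-around clusters cross the origin)."""

    genome_id: str
    clusters: tuple[tuple[str, ...], ...]

    @cached_property
    def cluster_of(self) -> dict[str, int]:
        mapping: dict[str, int] = {}
        for idx, cluster in enumerate(self.clusters):
            for gene_id in cluster:
                mapping[gene_id] = idx
        return mapping

    def same_cluster(self, gene_a: str, gene_b: str) -> bool:
        ca = self.cluster_of.get(gene_a)
        return ca is not None and ca == self.cluster_of.get(gene_b)


def _gap(upstream: Gene, downstream: Gene) -> int:
    gap = downstream.start - upstream.end - 1
    if gap < 0:
        logger.debug(
            "overlapping genes %s/%s treated as gap 0", upstream.gene_id, downstream.gene_id
        )
        return 0
    return gap


def find_gene_clusters(genome: GenomeAnnotation, idc: int = 100) -> GeneClusterSet:
    """Maximal runs of consecutive same-strand genes with gaps <= ``idc``.

    On circular chromosomes the last->first adjacency across the origin is
    also tested and wrap-around runs are merged.  Singleton runs are retained
    as clusters of size 1.  Overlapping genes count as gap 0.
    """
    if idc < 0:
        raise ValueError("intergenic distance cutoff must be >= 0")
    genes = genome.genes
    if not genes:
        return GeneClusterSet(genome.genome_id, ())
    runs: list[list[Gene]] = [[genes[0]]]
    for prev, cur in zip(genes, genes[1:]):
        if cur.strand == prev.strand and _gap(prev, cur) <= idc:
            runs[-1].append(cur)
        else:
            runs.append([cur])
    if genome.circular and len(runs) > 1:
        first, last = runs[0], runs[-1]
        wrap_gap = (genes[0].start - 1) + (genome.length - genes[-1].end)
        if last[-1].strand == first[0].strand and wrap_gap <= idc:
            runs = [last + first] + runs[1:-1]
    return GeneClusterSet(
        genome.genome_id, tuple(tuple(g.gene_id for g in run) for run in runs)
    )


def _canon(pair: tuple[str, str]) -> tuple[str, str]:
    a, b = pair
    return (a, b) if a <= b else (b, a)


def gcm_score(
    pair: tuple[str, str],
    table: OrthologTable,
    clusters: Mapping[str, GeneClusterSet],
    n: int | None = None,
) -> float:
    """Fraction of the reference set in which the pair's orthologs co-cluster.

    ``clusters`` maps genome id to its :class:`GeneClusterSet`; ``n`` defaults
    to the number of genomes in ``clusters``.  Genomes missing either ortholog
    contribute 0.
    """
    x, y = pair
    n = len(clusters) if n is None else n
    if n < 1:
        raise ValueError("reference-set size must be >= 1")
    hits = 0
    for genome_id, cluster_set in clusters.items():
        ox = table.ortholog(x, genome_id)
        oy = table.ortholog(y, genome_id)
        if ox is None or oy is None:
            continue
        if cluster_set.same_cluster(ox[0], oy[0]):
            hits += 1
    return hits / n


def circular_distance(
    gene_a: str | Gene, gene_b: str | Gene, genome: GenomeAnnotation
) -> int:
    """Minimum of clockwise and anti-clockwise distances between start sites.

    Distances are measured between translation start sites (``start`` on the
    '+' strand, ``end`` on '-').  On linear chromosomes the plain absolute
    difference is returned.
    """
    a = genome.gene(gene_a) if isinstance(gene_a, str) else gene_a
    b = genome.gene(gene_b) if isinstance(gene_b, str) else gene_b
    delta = abs(a.tss - b.tss)
    if not genome.circular:
        return delta
    return min(delta, genome.length - delta)


def mdm_score(
    pair: tuple[str, str],
    table: OrthologTable,
    genomes: Iterable[GenomeAnnotation] | Mapping[str, GenomeAnnotation],
) -> float | None:
    """Minimum over genomes of the chance probability ``min(1, 2d/N)``.

    ``d`` is the circular distance between the orthologs' translation start
    sites and ``N`` the chromosome length of that genome.  Genomes lacking
    either ortholog are skipped; if no genome holds both, ``None`` is
    returned (no evidence).  Smaller scores mean stronger predicted linkage;
    evaluation must rank this method ascending.
    """
    x, y = pair
    annotations = genomes.values() if isinstance(genomes, Mapping) else genomes
    best: float | None = None
    for genome in annotations:
        ox = table.ortholog(x, genome.genome_id)
        oy = table.ortholog(y, genome.genome_id)
        if ox is None or oy is None:
            continue
        if ox[0] not in genome or oy[0] not in genome:
            continue
        d = circular_distance(ox[0], oy[0], genome)
        prob = min(1.0, 2.0 * d / genome.length)
        best = prob if best is None else min(best, prob)
    return best
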