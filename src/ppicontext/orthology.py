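"""Reciprocal-best-hit orthology from tabular homology-search output.

Orthologs of each query-genome protein are defined operationally: gene *q* in
reference genome *g* is the ortholog of query protein *p* iff *q* is *p*'s
top-scoring hit in *g*, *p* is *q*'s top-scoring hit back in the query genome,
and both hits pass the e-value filter (default 1e-4).  Hits are ranked by bit
score; the e-value is used only as the filter.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "HitRecord",
    "HitTableError",
    "OrthologTable",
    "parse_hit_table",
    "read_genome_map",
    "reciprocal_best_hits",
    "phyletic_count",
]


class HitTableError(ValueError):
    """Raised when a tabular hit file cannot be parsed; names the line."""


@dataclass(frozen=True)
class HitRecord:
    """One homology-search hit (one line of 12-column tabular output)."""

    query_id: str
    subject_id: str
    e_value: float
    bit_score: float
    subject_genome: str | None = None

    def __post_init__(self) -> None:
        if not self.query_id or not self.subject_id:
            raise ValueError("hit identifiers must be non-empty")
        if self.e_value < 0:
            raise ValueError(f"e-value must be >= 0, got {self.e_value}")
        if self.bit_score <= 0:
            raise ValueError(f"bit score must be > 0, got {self.bit_score}")


def _iter_lines(source: str | os.PathLike | IO[str] | Iterable[str]):
    if isinstance(source, (str, os.PathLike)):
        with open(source) as handle:
            yield from handle
    else:
        yield from source


def parse_hit_table(
    source: str | os.PathLike | IO[str] | Iterable[str],
    genome_map: Mapping[str, str] | None = None,
) -> list[HitRecord]:
    """Parse 12-column tab-separated homology output into :class:`HitRecord`s.

    Columns follow the standard tabular convention (query, subject, %identity,
    alignment length, mismatches, gap opens, qstart, qend, sstart, send,
    e-value, bit score); only columns 1, 2, 11 and 12 are retained.  Blank
    lines and ``#`` comments are skipped.  ``genome_map`` optionally maps
    subject ids to genome ids, filling ``subject_genome``.
    """
    records: list[HitRecord] = []
    for lineno, line in enumerate(_iter_lines(source), start=1):
        stripped = line.rstrip("\n")
        if not stripped.strip() or stripped.startswith("#"):
            continue
        fields = stripped.split("\t")
        if len(fields) < 12:
            raise HitTableError(
                f"line {lineno}: expected >=12 tab-separated fields, got {len(fields)}"
            )
        try:
            e_value = float(fields[10])
            bit_score = float(fields[11])
        except ValueError as exc:
            raise HitTableError(f"line {lineno}: unparseable numeric field: {exc}") from exc
        genome = genome_map.get(fields[1]) if genome_map is not None else None
        try:
            records.append(
                HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    e_value=e_value,
                    bit_score=bit_score,
                    subject_genome=genome,
                )
            )
        except ValueError as exc:
            raise HitTableError(f"line {lineno}: {exc}") from exc
    return records


def read_genome_map(source: str | os.PathLike | IO[str]) -> dict[str, str]:
    """Read a two-column TSV mapping subject gene id -> genome id."""
    frame = pd.read_csv(source, sep="\t", header=None, names=["subject", "genome"], dtype=str)
    return dict(zip(frame["subject"], frame["genome"]))


class OrthologTable:
    """Best reciprocal hits per (query protein, reference genome).

    Parameters
    ----------
    entries
        Mapping ``(protein, genome) -> (ortholog_id, bit_score)``.
    genomes, proteins
        Ordered label lists.  Every entry's genome must appear in ``genomes``;
        proteins may include query proteins with no ortholog anywhere.
    """

    def __init__(
        self,
        entries: Mapping[tuple[str, str], tuple[str, float]],
        genomes: Sequence[str],
        proteins: Sequence[str],
    ) -> None:
        self.genomes = list(genomes)
        self.proteins = list(proteins)
        genome_set = set(self.genomes)
        protein_set = set(self.proteins)
        self.entries: dict[tuple[str, str], tuple[str, float]] = {}
        for (protein, genome), (ortholog, bit_score) in entries.items():
            if genome not in genome_set:
                raise ValueError(f"entry genome {genome!r} not in genome list")
            if protein not in protein_set:
                raise ValueError(f"entry protein {protein!r} not in protein list")
            if bit_score <= 0:
                raise ValueError(f"bit score must be > 0 for ({protein}, {genome})")
            self.entries[(protein, genome)] = (ortholog, float(bit_score))

    @classmethod
    def from_entries(
        cls, entries: Mapping[tuple[str, str], tuple[str, float]]
    ) -> "OrthologTable":
        genomes = sorted({g for (_, g) in entries})
        proteins = sorted({p for (p, _) in entries})
        return cls(entries, genomes, proteins)

    def ortholog(self, protein: str, genome: str) -> tuple[str, float] | None:
        return self.entries.get((protein, genome))

    def presence(self, protein: str, genome: str) -> bool:
        return (protein, genome) in self.entries

    def ortholog_count(self, genome: str) -> int:
        """Number of query proteins with an ortholog in ``genome``."""
        return sum(1 for (_, g) in self.entries if g == genome)

    def ortholog_set(self, genome: str) -> set[str]:
        """Query proteins with an ortholog in ``genome``."""
        return {p for (p, g) in self.entries if g == genome}

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with columns protein, genome, ortholog, bit_score."""
        rows = [
            (p, g, o, bs) for (p, g), (o, bs) in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["protein", "genome", "ortholog", "bit_score"])

    def to_tsv(self, path: str | os.PathLike | IO[str]) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike | IO[str]) -> "OrthologTable":
        frame = pd.read_csv(path, sep="\t", dtype={"protein": str, "genome": str, "ortholog": str})
        entries = {
            (row.protein, row.genome): (row.ortholog, float(row.bit_score))
            for row in frame.itertuples()
        }
        return cls.from_entries(entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OrthologTable):
            return NotImplemented
        return (
            self.entries == other.entries
            and self.genomes == other.genomes
            and self.proteins == other.proteins
        )

    def __repr__(self) -> str:
        return (
            f"OrthologTable({len(self.entries)} entries, "
            f"{len(self.proteins)} proteins x {len(self.genomes)} genomes)"
        )


def _better(candidate: HitRecord, incumbent: HitRecord | None) -> bool:
    """Bit-score ranking with lexicographic subject-id tie-break."""
    if incumbent is None:
        return True
    if candidate.bit_score != incumbent.bit_score:
        return candidate.bit_score > incumbent.bit_score
    return candidate.subject_id < incumbent.subject_id


def _first_hsp_only(hits: Iterable[HitRecord]) -> list[HitRecord]:
    seen: set[tuple[str, str]] = set()
    kept = []
    for hit in hits:
        key = (hit.query_id, hit.subject_id)
        if key not in seen:
            seen.add(key)
            kept.append(hit)
    return kept


def reciprocal_best_hits(
    forward: Iterable[HitRecord],
    reverse: Iterable[HitRecord],
    e_threshold: float = 1e-4,
    genome_map: Mapping[str, str] | None = None,
) -> OrthologTable:
    """Build an :class:`OrthologTable` from forward and reverse hit lists.

    ``forward`` hits run query-genome protein -> reference-genome gene and must
    carry ``subject_genome`` (either on the records or via ``genome_map``);
    ``reverse`` hits run reference gene -> query-genome protein.  An entry
    ``(p, g)`` is created iff p's bit-score-best hit in g is some gene q, q's
    best hit back is p, and both hits have e-value <= ``e_threshold``.  The
    stored bit score is the forward one.  Multi-HSP inputs keep only the first
    line per query-subject pair.
    """
    if e_threshold <= 0:
        raise ValueError("e_threshold must be > 0")
    fwd = _first_hsp_only(forward)
    rev = _first_hsp_only(reverse)
    if genome_map is not None:
        fwd = [
            hit if hit.subject_genome is not None
            else HitRecord(hit.query_id, hit.subject_id, hit.e_value, hit.bit_score,
                           genome_map.get(hit.subject_id))
            for hit in fwd
        ]

    best_forward: dict[tuple[str, str], HitRecord] = {}
    for hit in fwd:
        if hit.subject_genome is None:
            raise ValueError(
                f"forward hit {hit.query_id}->{hit.subject_id} has no subject genome; "
                "provide a genome_map"
            )
        key = (hit.query_id, hit.subject_genome)
        if _better(hit, best_forward.get(key)):
            best_forward[key] = hit

    best_reverse: dict[str, HitRecord] = {}
    for hit in rev:
        if _better(hit, best_reverse.get(hit.query_id)):
            best_reverse[hit.query_id] = hit

    entries: dict[tuple[str, str], tuple[str, float]] = {}
    for (protein, genome), hit in best_forward.items():
        if hit.e_value > e_threshold:
            continue
        back = best_reverse.get(hit.subject_id)
        if back is None or back.subject_id != protein or back.e_value > e_threshold:
            continue
        entries[(protein, genome)] = (hit.subject_id, hit.bit_score)

    genomes = sorted({hit.subject_genome for hit in fwd if hit.subject_genome is not None})
    proteins = sorted({hit.query_id for hit in fwd})
    return OrthologTable(entries, genomes, proteins)


def phyletic_count(protein: str, table: OrthologTable) -> int:
    """Number of reference genomes in which ``protein`` has an ortholog."""
    if protein not in set(table.proteins):
        raise KeyError(f"unknown protein {protein!r}")
    return sum(1 for (p, _) in table.entries if p == protein)
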