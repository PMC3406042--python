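"""Phylogenetic profile matrices and profile-correlation interaction scores.

Two profile flavours are supported: binary presence/absence (BPPM scoring)
and homology bit scores with a two-stage normalization (SPPM scoring).  The
normalization divides each row by its maximum bit score (removing per-protein
divergence scale) and then each column's nonzero cells by the column's
minimum nonzero value (removing per-genome species divergence).  Pairs are
scored by the Pearson correlation of their profile rows over all genomes;
a profile with zero variance yields no score (``None``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .orthology import OrthologTable

__all__ = [
    "ProfileMatrix",
    "build_binary_profiles",
    "build_bitscore_profiles",
    "normalize_profiles",
    "profile_score",
    "score_pairs",
]

MODES = ("binary", "bitscore_raw", "bitscore_normalized")


@dataclass
class ProfileMatrix:
    """Proteins x genomes matrix of non-negative reals.

    ``mode`` is one of ``binary``, ``bitscore_raw``, ``bitscore_normalized``.
    Absent orthologs are exactly 0 in every mode.  ``excluded`` lists proteins
    dropped during normalization (all-zero rows).
    """

    values: pd.DataFrame
    mode: str
    excluded: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("row/column labels must be unique")
        arr = self.values.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValueError("profile values must be non-negative")
        if self.mode == "binary" and not np.isin(arr, (0.0, 1.0)).all():
            raise ValueError("binary profiles may contain only 0 and 1")

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def genomes(self) -> list[str]:
        return list(self.values.columns)

    def row(self, protein: str) -> np.ndarray:
        return self.values.loc[protein].to_numpy(dtype=float)

    def to_tsv(self, path: str | os.PathLike | IO[str]) -> None:
        self.values.to_csv(path, sep="\t", index_label="protein")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike | IO[str], mode: str) -> "ProfileMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="protein")
        return cls(frame, mode)


def _resolve_genomes(table: OrthologTable, genomes: Sequence[str] | None) -> list[str]:
    if genomes is None:
        return list(table.genomes)
    unknown = set(genomes) - set(table.genomes)
    if unknown:
        raise KeyError(f"unknown genomes requested: {sorted(unknown)}")
    return list(genomes)


def build_binary_profiles(
    table: OrthologTable, genomes: Sequence[str] | None = None
) -> ProfileMatrix:
    """Presence/absence matrix: 1 where the table has an entry, else 0."""
    genomes = _resolve_genomes(table, genomes)
    data = np.zeros((len(table.proteins), len(genomes)))
    gidx = {g: j for j, g in enumerate(genomes)}
    pidx = {p: i for i, p in enumerate(table.proteins)}
    for (protein, genome) in table.entries:
        j = gidx.get(genome)
        if j is not None:
            data[pidx[protein], j] = 1.0
    return ProfileMatrix(
        pd.DataFrame(data, index=table.proteins, columns=genomes), "binary"
    )


def build_bitscore_profiles(
    table: OrthologTable, genomes: Sequence[str] | None = None
) -> ProfileMatrix:
    """Raw bit-score matrix: stored bit score where present, 0 where absent."""
    genomes = _resolve_genomes(table, genomes)
    data = np.zeros((len(table.proteins), len(genomes)))
    gidx = {g: j for j, g in enumerate(genomes)}
    pidx = {p: i for i, p in enumerate(table.proteins)}
    for (protein, genome), (_, bit_score) in table.entries.items():
        j = gidx.get(genome)
        if j is not None:
            data[pidx[protein], j] = bit_score
    return ProfileMatrix(
        pd.DataFrame(data, index=table.proteins, columns=genomes), "bitscore_raw"
    )


def normalize_profiles(raw: ProfileMatrix) -> ProfileMatrix:
    """Two-stage normalization of a raw bit-score matrix.

    Stage 1 divides each row by its maximum (all row maxima become 1); stage 2
    divides each nonzero cell by the minimum nonzero value in its column,
    computed on the stage-1 values.  Zeros stay zero throughout.  Rows that
    are entirely zero are excluded and recorded in ``excluded``.
    """
    if raw.mode != "bitscore_raw":
        raise ValueError(f"expected bitscore_raw matrix, got {raw.mode!r}")
    values = raw.values.to_numpy(dtype=float)
    row_max = values.max(axis=1)
    keep = row_max > 0
    excluded = tuple(p for p, k in zip(raw.proteins, keep) if not k)
    values = values[keep]
    stage1 = values / values.max(axis=1, keepdims=True)
    masked = np.where(stage1 > 0, stage1, np.inf)
    col_min = masked.min(axis=0)
    col_min = np.where(np.isfinite(col_min), col_min, 1.0)  # all-zero columns
    stage2 = np.where(stage1 > 0, stage1 / col_min, 0.0)
    frame = pd.DataFrame(
        stage2, index=[p for p, k in zip(raw.proteins, keep) if k], columns=raw.genomes
    )
    return ProfileMatrix(frame, "bitscore_normalized", excluded=excluded)


def profile_score(x: np.ndarray, y: np.ndarray) -> float | None:
    """Pearson correlation of two profile rows over all genome positions.

    Zeros (absences) are included as signal.  Returns ``None`` when either
    vector is constant (the correlation is undefined); such pairs rank last in
    evaluation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("profiles must be 1-D vectors of equal length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    r = float(np.corrcoef(x, y)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def score_pairs(
    matrix: ProfileMatrix, pairs: Iterable[tuple[str, str]]
) -> dict[tuple[str, str], float | None]:
    """Score unordered protein pairs against a profile matrix.

    Pairs are returned keyed in canonical (sorted) order.  A pair with a
    protein excluded during normalization (or missing from the matrix) gets
    ``None``.
    """
    index = set(matrix.values.index)
    scores: dict[tuple[str, str], float | None] = {}
    for a, b in pairs:
        key: tuple[str, str] = (a, b) if a <= b else (b, a)
        if a not in index or b not in index:
            scores[key] = None
        else:
            scores[key] = profile_score(matrix.row(a), matrix.row(b))
    return scores
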