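"""Mirrortree-family co-evolution scores from ortholog distance matrices.

The mirrortree statistic is the Pearson correlation between two protein
families' inter-ortholog distance matrices, restricted to their shared
reference genomes (at least 15 by default) and taken over the strict upper
triangle.  Because all families evolve on the same species tree, raw scores
carry a large speciation background.  Two corrections subtract a reference
matrix after rescaling both matrices by a "scaling factor" (the maximum
correlation between the reference matrix and any protein family):

* Tol-mirrortree - the reference is a 16S rRNA distance matrix;
* GD-mirrortree - the reference is a genome-distance matrix, one minus the
  Tanimoto similarity of the genomes' shared ortholog complements.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .orthology import OrthologTable
from .reference_sets import tanimoto

__all__ = [
    "DistanceMatrix",
    "msa_to_distance_matrix",
    "common_submatrix",
    "matrix_correlation",
    "genome_distance_matrix",
    "genome_distance_from_table",
    "scaling_factor",
    "correct_matrix",
    "coevolution_score",
]

GAP_CHARS = frozenset("-.")
#: distance assigned when the Kimura correction diverges (p too large)
KIMURA_CAP = 10.0
DEFAULT_MIN_COMMON = 15


@dataclass(frozen=True)
class DistanceMatrix:
    """Genome-labeled symmetric distance matrix with zero diagonal.

    ``kind`` records provenance: ``protein`` (inter-ortholog sequence
    distances), ``rrna`` (16S-like reference), ``genome_distance`` (one minus
    Tanimoto, entries in [0, 1]) or ``corrected``.  Corrected matrices may
    hold negative entries.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    kind: str = "protein"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if values.shape != (n, n):
            raise ValueError(f"matrix shape {values.shape} does not match {n} labels")
        if len(set(self.labels)) != n:
            raise ValueError("labels must be unique")
        if n and np.abs(values - values.T).max() > 1e-12:
            raise ValueError("matrix must be symmetric within 1e-12")
        if n and np.abs(np.diag(values)).max() != 0:
            raise ValueError("diagonal must be exactly zero")
        if self.kind == "genome_distance" and n and (
            values.min() < 0 or values.max() > 1
        ):
            raise ValueError("genome distances must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.labels)

    def restrict(self, labels: Sequence[str]) -> "DistanceMatrix":
        """Submatrix over ``labels`` (which must all be present), in order."""
        index = {lab: i for i, lab in enumerate(self.labels)}
        try:
            idx = [index[lab] for lab in labels]
        except KeyError as exc:
            raise KeyError(f"label {exc.args[0]!r} not in matrix") from None
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)], self.kind)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path: str | os.PathLike | IO[str]) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="genome")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike | IO[str], kind: str = "protein") -> "DistanceMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="genome")
        return cls(tuple(frame.index), frame.to_numpy(dtype=float), kind)

    def to_phylip(self, path: str | os.PathLike | IO[str]) -> None:
        """Write square PHYLIP distance format."""
        own = isinstance(path, (str, os.PathLike))
        handle = open(path, "w") if own else path
        try:
            handle.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.values):
                cells = " ".join(f"{v:.6f}" for v in row)
                handle.write(f"{label}  {cells}\n")
        finally:
            if own:
                handle.close()

    @classmethod
    def from_phylip(cls, path: str | os.PathLike | IO[str], kind: str = "protein") -> "DistanceMatrix":
        own = isinstance(path, (str, os.PathLike))
        handle = open(path) if own else path
        try:
            n = int(handle.readline().split()[0])
            labels, rows = [], []
            for _ in range(n):
                parts = handle.readline().split()
                labels.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        finally:
            if own:
                handle.close()
        values = np.array(rows)
        # round-trip symmetry can be off at printed precision; re-symmetrize
        values = (values + values.T) / 2.0
        np.fill_diagonal(values, 0.0)
        return cls(tuple(labels), values, kind)


def _as_labeled_rows(msa) -> tuple[list[str], np.ndarray]:
    labels, seqs = [], []
    for record in msa:
        if isinstance(record, tuple):
            label, seq = record
        else:  # Bio.SeqRecord from an AlignIO/SeqIO parse
            label, seq = record.id, str(record.seq)
        labels.append(label)
        seqs.append(seq.upper())
    if len(seqs) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1 or lengths == {0}:
        raise ValueError("sequences must be aligned to equal nonzero length")
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype="S1").reshape(
        len(seqs), -1
    )
    return labels, arr


def msa_to_distance_matrix(msa, model: str = "p_distance") -> DistanceMatrix:
    """Pairwise distances from an aligned protein family.

    ``msa`` is an iterable of ``(genome_label, sequence)`` tuples or Biopython
    ``SeqRecord`` objects of equal length.  ``p_distance`` is the fraction of
    mismatched columns among columns where neither sequence has a gap; the
    ``kimura`` model applies the correction ``-ln(1 - p - p^2/5)`` (capped at
    ``KIMURA_CAP`` where it diverges).  A pair with no ungapped overlap is an
    error naming the pair.
    """
    if model not in ("p_distance", "kimura"):
        raise ValueError(f"unknown distance model {model!r}")
    labels, arr = _as_labeled_rows(msa)
    gap = np.isin(arr, [b"-", b"."])
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[i] & ~gap[j]
            overlap = int(ok.sum())
            if overlap == 0:
                raise ValueError(
                    f"no ungapped overlap between {labels[i]!r} and {labels[j]!r}"
                )
            p = float(((arr[i] != arr[j]) & ok).sum()) / overlap
            if model == "kimura":
                adjusted = 1.0 - p - p * p / 5.0
                d = -np.log(adjusted) if adjusted > 0 else KIMURA_CAP
            else:
                d = p
            values[i, j] = values[j, i] = d
    return DistanceMatrix(tuple(labels), values, "protein")


def common_submatrix(
    dx: DistanceMatrix,
    dy: DistanceMatrix,
    min_common: int = DEFAULT_MIN_COMMON,
) -> tuple[DistanceMatrix, DistanceMatrix] | None:
    """Restrict both matrices to their shared genome labels (sorted).

    Returns ``None`` (insufficient overlap) when fewer than ``min_common``
    genomes are shared.
    """
    if min_common < 2:
        raise ValueError("min_common must be >= 2")
    shared = sorted(set(dx.labels) & set(dy.labels))
    if len(shared) < min_common:
        return None
    return dx.restrict(shared), dy.restrict(shared)


def matrix_correlation(dx: DistanceMatrix, dy: DistanceMatrix) -> float | None:
    """Pearson correlation over strict-upper-triangle entries.

    The always-zero diagonal is excluded.  Returns ``None`` when either
    triangle is constant (correlation undefined).
    """
    if dx.labels != dy.labels:
        raise ValueError("matrices must share identical label order")
    x = dx.upper_triangle()
    y = dy.upper_triangle()
    if x.size < 1:
        raise ValueError("matrices too small to correlate")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    r = float(np.corrcoef(x, y)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def genome_distance_matrix(
    proteome_sizes: Mapping[str, int],
    shared_counts: Mapping[tuple[str, str], int],
) -> DistanceMatrix:
    """Genome distances GD(A,B) = 1 - Tanimoto(n_A, n_B, n_shared).

    ``shared_counts`` may key the pair in either order.  The diagonal is 0 and
    entries lie in [0, 1].  A missing pair count is an error.
    """
    labels = tuple(sorted(proteome_sizes))
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = labels[i], labels[j]
            shared = shared_counts.get((a, b), shared_counts.get((b, a)))
            if shared is None:
                raise KeyError(f"missing shared-ortholog count for ({a}, {b})")
            gd = 1.0 - tanimoto(proteome_sizes[a], proteome_sizes[b], shared)
            values[i, j] = values[j, i] = gd
    return DistanceMatrix(labels, values, "genome_distance")


def genome_distance_from_table(table: OrthologTable) -> DistanceMatrix:
    """Genome distances from shared query-protein ortholog complements.

    Genomes with no orthologs at all are dropped (their Tanimoto similarity
    is undefined).
    """
    sets = {g: table.ortholog_set(g) for g in table.genomes}
    sets = {g: s for g, s in sets.items() if s}
    sizes = {g: len(s) for g, s in sets.items()}
    shared = {
        (a, b): len(sets[a] & sets[b])
        for i, a in enumerate(sorted(sets))
        for b in sorted(sets)[i + 1:]
    }
    return genome_distance_matrix(sizes, shared)


def scaling_factor(
    ref: DistanceMatrix,
    protein_matrices: Iterable[DistanceMatrix],
    min_common: int = DEFAULT_MIN_COMMON,
) -> float:
    """Maximum correlation between the reference matrix and any protein family.

    Families with insufficient genome overlap with the reference, or with a
    constant distance triangle, are skipped.  An error is raised when no
    family is eligible.
    """
    best: float | None = None
    for dm in protein_matrices:
        pair = common_submatrix(ref, dm, min_common=min_common)
        if pair is None:
            continue
        r = matrix_correlation(*pair)
        if r is None:
            continue
        best = r if best is None else max(best, r)
    if best is None:
        raise ValueError("no protein matrix has sufficient overlap with the reference")
    return best


def correct_matrix(
    dx: DistanceMatrix, ref: DistanceMatrix, factor: float
) -> DistanceMatrix:
    """Rescale both matrices by ``factor`` and subtract the reference.

    ``corrected(i,j) = dx(i,j)/factor - ref(i,j)/factor`` on dx's labels,
    which the reference must cover.  Entries may be negative; symmetry and
    the zero diagonal are preserved.
    """
    if factor <= 0:
        raise ValueError("scaling factor must be > 0")
    missing = set(dx.labels) - set(ref.labels)
    if missing:
        raise ValueError(f"reference matrix lacks labels: {sorted(missing)}")
    sub = ref.restrict(dx.labels)
    return DistanceMatrix(dx.labels, (dx.values - sub.values) / factor, "corrected")


def coevolution_score(
    dx: DistanceMatrix,
    dy: DistanceMatrix,
    variant: str = "mirrortree",
    ref: DistanceMatrix | None = None,
    factor: float | None = None,
    min_common: int = DEFAULT_MIN_COMMON,
) -> float | None:
    """Score one pair under ``mirrortree``, ``tol`` or ``gd``.

    Plain mirrortree correlates the common submatrices directly; the ``tol``
    and ``gd`` variants first apply :func:`correct_matrix` with the given
    reference matrix and its scaling factor.  Returns ``None`` on
    insufficient genome overlap or a degenerate (constant) matrix.
    """
    if variant not in ("mirrortree", "tol", "gd"):
        raise ValueError(f"unknown variant {variant!r}")
    pair = common_submatrix(dx, dy, min_common=min_common)
    if pair is None:
        return None
    sub_x, sub_y = pair
    if variant != "mirrortree":
        if ref is None or factor is None:
            raise ValueError(f"variant {variant!r} requires ref and factor")
        if set(sub_x.labels) - set(ref.labels):
            return None  # reference does not cover the shared genomes
        sub_x = correct_matrix(sub_x, ref, factor)
        sub_y = correct_matrix(sub_y, ref, factor)
    return matrix_correlation(sub_x, sub_y)
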