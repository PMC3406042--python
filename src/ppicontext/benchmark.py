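"""Gold-standard assembly and ROC / precision-recall evaluation.

Positive interaction pairs come from physical-interaction and pathway
resources; the high-quality set (HQG) requires physical AND functional
evidence plus a phyletic-spread floor, the low-quality set (LQG) is the union
of sources with a single-pathway filter on pathway co-membership pairs.
Negatives are sampled from pairs with different subcellular localization and
different functional category, at a fixed positive:negative ratio (default
1:5).  Method scores are ranked (with a per-method orientation flag and
no-score pairs strictly last) and summarized as ROC and PR curves and the
trapezoidal AUC.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field
from itertools import combinations, groupby
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .orthology import OrthologTable, phyletic_count

__all__ = [
    "LabeledPair",
    "ProteinAnnotation",
    "jaccard_pathway",
    "build_hqg",
    "build_lqg",
    "build_negatives",
    "roc_points",
    "pr_points",
    "auc",
    "evaluate",
    "read_pairs",
    "write_labeled_pairs",
    "read_labeled_pairs",
    "read_annotations",
    "write_annotations",
    "read_scores",
    "write_scores",
    "plot_roc",
]

LOCALIZATIONS = ("cytosolic", "secretory", "membrane", "ambiguous")
#: fraction of the reference set a protein must cover to enter HQG
DEFAULT_MIN_FRACTION = 200 / 565


def canonical(a: str, b: str) -> tuple[str, str]:
    if a == b:
        raise ValueError(f"self-pair {a!r} is not allowed")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class LabeledPair:
    """An unordered protein pair with an interact/non-interact label."""

    protein_a: str
    protein_b: str
    label: str
    sources: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        a, b = canonical(self.protein_a, self.protein_b)
        object.__setattr__(self, "protein_a", a)
        object.__setattr__(self, "protein_b", b)
        if self.label not in ("positive", "negative"):
            raise ValueError(f"label must be positive|negative, got {self.label!r}")
        object.__setattr__(self, "sources", frozenset(self.sources))

    @property
    def key(self) -> tuple[str, str]:
        return (self.protein_a, self.protein_b)


@dataclass(frozen=True)
class ProteinAnnotation:
    """Pathway membership, functional categories and localization tag.

    Proteins assigned to more than one functional category are ambiguous for
    negative-set construction, as are proteins with the ``ambiguous``
    localization tag (e.g. conflicting signal-peptide / transmembrane calls).
    """

    pathways: frozenset = field(default_factory=frozenset)
    categories: tuple[str, ...] = ()
    localization: str = "cytosolic"

    def __post_init__(self) -> None:
        if self.localization not in LOCALIZATIONS:
            raise ValueError(f"unknown localization {self.localization!r}")
        object.__setattr__(self, "pathways", frozenset(self.pathways))
        object.__setattr__(self, "categories", tuple(self.categories))

    @property
    def unambiguous(self) -> bool:
        return self.localization != "ambiguous" and len(self.categories) == 1


def jaccard_pathway(pathways_x: Iterable[str], pathways_y: Iterable[str]) -> float:
    """Jaccard coefficient |X & Y| / |X | Y|; 0 when the union is empty."""
    x, y = set(pathways_x), set(pathways_y)
    union = x | y
    if not union:
        return 0.0
    return len(x & y) / len(union)


def _canon_set(pairs: Iterable[tuple[str, str]]) -> set[tuple[str, str]]:
    return {canonical(a, b) for a, b in pairs}


def build_hqg(
    dip: Iterable[tuple[str, str]],
    complexes: Iterable[tuple[str, str]],
    kegg_pairs: Iterable[tuple[str, str]],
    ecocyc_functional: Iterable[tuple[str, str]],
    table: OrthologTable,
    min_genomes: int | None = None,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> list[LabeledPair]:
    """High-quality positives: physical AND functional evidence, wide spread.

    A pair is positive iff it appears in the physical resources (dip or
    complexes) AND in the functional ones (pathway co-membership or curated
    functional pairs), and both proteins have orthologs in at least
    ``min_genomes`` reference genomes (default: ``min_fraction`` of the
    table's genome count, rounded up).
    """
    if min_genomes is None:
        min_genomes = math.ceil(min_fraction * len(table.genomes))
    dip_set = _canon_set(dip)
    cplx_set = _canon_set(complexes)
    kegg_set = _canon_set(kegg_pairs)
    eco_set = _canon_set(ecocyc_functional)
    physical = dip_set | cplx_set
    functional = kegg_set | eco_set
    counts: dict[str, int] = {}

    def spread_ok(protein: str) -> bool:
        if protein not in counts:
            counts[protein] = phyletic_count(protein, table)
        return counts[protein] >= min_genomes

    positives = []
    for pair in sorted(physical & functional):
        if spread_ok(pair[0]) and spread_ok(pair[1]):
            sources = {
                tag
                for tag, pool in (
                    ("dip", dip_set),
                    ("complex", cplx_set),
                    ("kegg", kegg_set),
                    ("ecocyc", eco_set),
                )
                if pair in pool
            }
            positives.append(LabeledPair(*pair, "positive", frozenset(sources)))
    return positives


def build_lqg(
    dip: Iterable[tuple[str, str]],
    complexes: Iterable[tuple[str, str]],
    kegg_pathway_counts: Mapping[tuple[str, str], int],
) -> list[LabeledPair]:
    """Low-quality positives: union of sources, single-pathway pairs only.

    ``kegg_pathway_counts`` maps each pathway co-membership pair to the number
    of pathways the pair shares; only pairs sharing exactly one pathway enter
    through the pathway resource.  The union is de-duplicated, with source
    tags merged.
    """
    dip_set = _canon_set(dip)
    cplx_set = _canon_set(complexes)
    kegg_single = {
        canonical(*pair) for pair, count in kegg_pathway_counts.items() if count == 1
    }
    union = dip_set | cplx_set | kegg_single
    positives = []
    for pair in sorted(union):
        sources = {
            tag
            for tag, pool in (
                ("dip", dip_set),
                ("complex", cplx_set),
                ("kegg", kegg_single),
            )
            if pair in pool
        }
        positives.append(LabeledPair(*pair, "positive", frozenset(sources)))
    return positives


def build_negatives(
    proteins: Iterable[str],
    annotations: Mapping[str, ProteinAnnotation],
    positives: Iterable[LabeledPair],
    ratio: int = 5,
    seed: int = 0,
) -> list[LabeledPair]:
    """Sample non-interacting pairs at ``ratio`` negatives per positive.

    Candidates are unordered pairs of unambiguous proteins with different
    localization tags AND different functional categories that are not in the
    positive set.  Sampling is uniform without replacement and deterministic
    given ``seed``.  If the pool is smaller than requested, the whole pool is
    returned with a warning.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    positive_keys = {p.key for p in positives}
    eligible = [
        p
        for p in sorted(set(proteins))
        if p in annotations and annotations[p].unambiguous
    ]
    candidates = []
    for a, b in combinations(eligible, 2):
        ann_a, ann_b = annotations[a], annotations[b]
        if ann_a.localization == ann_b.localization:
            continue
        if ann_a.categories[0] == ann_b.categories[0]:
            continue
        pair = canonical(a, b)
        if pair in positive_keys:
            continue
        candidates.append(pair)
    wanted = ratio * len(positive_keys)
    rng = np.random.default_rng(seed)
    if len(candidates) < wanted:
        warnings.warn(
            f"negative pool has {len(candidates)} pairs, fewer than the "
            f"requested {wanted}; returning the full pool",
            RuntimeWarning,
        )
        chosen = candidates
    else:
        idx = rng.choice(len(candidates), size=wanted, replace=False)
        chosen = [candidates[i] for i in sorted(idx)]
    return [LabeledPair(*pair, "negative") for pair in chosen]


def _sweep(
    scores: Mapping[tuple[str, str], float | None],
    labels: Sequence[LabeledPair],
    orientation: str,
) -> tuple[list[tuple[int, int]], int, int]:
    """Cumulative (TP, FP) after each distinct threshold, ties grouped.

    Scores are oriented so larger means more interacting; no-score pairs
    (``None``/NaN) form a final strictly-worst group.
    """
    if orientation not in ("higher_better", "lower_better"):
        raise ValueError(f"unknown orientation {orientation!r}")
    items: list[tuple[float, bool]] = []
    n_pos = n_neg = 0
    for pair in labels:
        is_pos = pair.label == "positive"
        n_pos += is_pos
        n_neg += not is_pos
        score = scores.get(pair.key)
        if score is None or (isinstance(score, float) and math.isnan(score)):
            rank = -math.inf
        else:
            rank = -score if orientation == "lower_better" else float(score)
        items.append((rank, is_pos))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("labels must contain both positive and negative pairs")
    items.sort(key=lambda t: -t[0])
    levels = []
    tp = fp = 0
    for _, group in groupby(items, key=lambda t: t[0]):
        for _, is_pos in group:
            tp += is_pos
            fp += not is_pos
        levels.append((tp, fp))
    return levels, n_pos, n_neg


def roc_points(
    scores: Mapping[tuple[str, str], float | None],
    labels: Sequence[LabeledPair],
    orientation: str = "higher_better",
) -> list[tuple[float, float]]:
    """(FPR, TPR) points over the threshold sweep, from (0,0) to (1,1)."""
    levels, n_pos, n_neg = _sweep(scores, labels, orientation)
    return [(0.0, 0.0)] + [(fp / n_neg, tp / n_pos) for tp, fp in levels]


def pr_points(
    scores: Mapping[tuple[str, str], float | None],
    labels: Sequence[LabeledPair],
    orientation: str = "higher_better",
) -> list[tuple[float, float]]:
    """(recall, precision) points over the same threshold sweep.

    The degenerate pre-threshold state with TP+FP=0 is omitted.
    """
    levels, n_pos, _ = _sweep(scores, labels, orientation)
    return [(tp / n_pos, tp / (tp + fp)) for tp, fp in levels]


def auc(points: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal area under a curve of (x, y) points.

    On ROC points this equals the Mann-Whitney probability that a random
    positive outranks a random negative, with half credit for ties.
    """
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    return float(np.trapezoid(ys, xs))


def evaluate(
    scores_by_method: Mapping[str, Mapping[tuple[str, str], float | None]],
    labels: Sequence[LabeledPair],
    orientations: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """AUC summary per method; ``orientations`` overrides per method
    (default ``higher_better``)."""
    orientations = dict(orientations or {})
    rows = []
    for method, scores in scores_by_method.items():
        orientation = orientations.get(method, "higher_better")
        points = roc_points(scores, labels, orientation)
        rows.append((method, orientation, auc(points)))
    return pd.DataFrame(rows, columns=["method", "orientation", "auc"])


# ---------------------------------------------------------------------------
# TSV I/O


def read_pairs(path: str | os.PathLike | IO[str]) -> list[tuple[str, str]]:
    """Read a pair list TSV with columns a, b (extra columns ignored)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return [canonical(row.a, row.b) for row in frame.itertuples()]


def write_labeled_pairs(
    pairs: Iterable[LabeledPair], path: str | os.PathLike | IO[str]
) -> None:
    rows = [
        (p.protein_a, p.protein_b, p.label, ";".join(sorted(p.sources)))
        for p in pairs
    ]
    pd.DataFrame(rows, columns=["a", "b", "label", "sources"]).to_csv(
        path, sep="\t", index=False
    )


def read_labeled_pairs(path: str | os.PathLike | IO[str]) -> list[LabeledPair]:
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        LabeledPair(
            row.a, row.b, row.label,
            frozenset(s for s in row.sources.split(";") if s),
        )
        for row in frame.itertuples()
    ]


def write_annotations(
    annotations: Mapping[str, ProteinAnnotation], path: str | os.PathLike | IO[str]
) -> None:
    rows = [
        (
            protein,
            ";".join(sorted(ann.pathways)),
            ";".join(ann.categories),
            ann.localization,
        )
        for protein, ann in sorted(annotations.items())
    ]
    pd.DataFrame(
        rows, columns=["protein", "pathways", "categories", "localization"]
    ).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | os.PathLike | IO[str]) -> dict[str, ProteinAnnotation]:
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    table = {}
    for row in frame.itertuples():
        table[row.protein] = ProteinAnnotation(
            pathways=frozenset(p for p in row.pathways.split(";") if p),
            categories=tuple(c for c in row.categories.split(";") if c),
            localization=row.localization,
        )
    return table


def write_scores(
    scores: Mapping[tuple[str, str], float | None],
    path: str | os.PathLike | IO[str],
    method: str,
) -> None:
    """Pair-score TSV; no-score pairs get an empty score field."""
    rows = [
        (a, b, method, "" if s is None else repr(float(s)))
        for (a, b), s in sorted(scores.items())
    ]
    pd.DataFrame(rows, columns=["protein_a", "protein_b", "method", "score"]).to_csv(
        path, sep="\t", index=False
    )


def read_scores(
    path: str | os.PathLike | IO[str],
) -> dict[tuple[str, str], float | None]:
    frame = pd.read_csv(path, sep="\t", dtype={"protein_a": str, "protein_b": str})
    scores: dict[tuple[str, str], float | None] = {}
    for row in frame.itertuples():
        value = row.score
        scores[canonical(row.protein_a, row.protein_b)] = (
            None if pd.isna(value) else float(value)
        )
    return scores


def plot_roc(
    curves: Mapping[str, Sequence[tuple[float, float]]],
    path: str | os.PathLike,
    title: str = "ROC",
) -> None:
    """Basic ROC plot, one line per method."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for method, points in curves.items():
        xs = [p[0] for p in points]
        ys = [p[1] for p in points]
        ax.plot(xs, ys, label=f"{method} (AUC={auc(points):.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
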