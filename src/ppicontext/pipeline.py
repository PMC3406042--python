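"""End-to-end orchestration: score a corpus with every method and evaluate.

Thin glue over the scoring modules, used by the CLI and by benchmarking
scripts.  Method names: ``bppm``, ``sppm``, ``gcm``, ``mdm``, ``mirrortree``,
``tol_mirrortree``, ``gd_mirrortree``.  MDM is a smaller-is-stronger score;
:data:`ORIENTATIONS` carries the per-method orientation flags the evaluator
needs.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import benchmark, coevolution, gene_context, profiles
from .benchmark import LabeledPair
from .coevolution import DistanceMatrix
from .gene_context import GenomeAnnotation
from .orthology import OrthologTable
from .synthetic_data import Corpus

__all__ = [
    "ORIENTATIONS",
    "profile_scores",
    "gcm_scores",
    "mdm_scores",
    "family_matrices",
    "mirrortree_scores",
    "score_all_methods",
    "build_gold",
    "corpus_aucs",
]

ORIENTATIONS = {"mdm": "lower_better"}

Pairs = Iterable[tuple[str, str]]
Scores = dict[tuple[str, str], float | None]


def profile_scores(table: OrthologTable, pairs: Pairs, mode: str = "binary") -> Scores:
    """BPPM (``mode='binary'``) or SPPM (``mode='bitscore'``) pair scores."""
    if mode == "binary":
        matrix = profiles.build_binary_profiles(table)
    elif mode == "bitscore":
        matrix = profiles.normalize_profiles(profiles.build_bitscore_profiles(table))
    else:
        raise ValueError(f"unknown profile mode {mode!r}")
    return profiles.score_pairs(matrix, pairs)


def gcm_scores(
    table: OrthologTable,
    annotations: Mapping[str, GenomeAnnotation],
    pairs: Pairs,
    idc: int = 100,
) -> Scores:
    clusters = {
        genome: gene_context.find_gene_clusters(annotation, idc=idc)
        for genome, annotation in annotations.items()
    }
    n = len(clusters)
    return {
        benchmark.canonical(a, b): gene_context.gcm_score((a, b), table, clusters, n)
        for a, b in pairs
    }


def mdm_scores(
    table: OrthologTable,
    annotations: Mapping[str, GenomeAnnotation],
    pairs: Pairs,
) -> Scores:
    return {
        benchmark.canonical(a, b): gene_context.mdm_score((a, b), table, annotations)
        for a, b in pairs
    }


def family_matrices(
    families: Mapping[str, Sequence[tuple[str, str]]],
    model: str = "p_distance",
    min_sequences: int = 2,
) -> dict[str, DistanceMatrix]:
    """Distance matrices from aligned families (families too small are skipped)."""
    matrices = {}
    for protein, records in families.items():
        if len(records) >= min_sequences:
            matrices[protein] = coevolution.msa_to_distance_matrix(records, model=model)
    return matrices


def mirrortree_scores(
    matrices: Mapping[str, DistanceMatrix],
    pairs: Pairs,
    variant: str = "mirrortree",
    ref: DistanceMatrix | None = None,
    min_common: int = coevolution.DEFAULT_MIN_COMMON,
) -> Scores:
    """Score pairs under one mirrortree variant.

    For ``tol``/``gd`` the scaling factor is computed once, as the maximum
    correlation between the reference matrix and any available family.
    """
    factor = None
    if variant != "mirrortree":
        if ref is None:
            raise ValueError(f"variant {variant!r} requires a reference matrix")
        factor = coevolution.scaling_factor(ref, matrices.values(), min_common=min_common)
    scores: Scores = {}
    for a, b in pairs:
        key = benchmark.canonical(a, b)
        dx, dy = matrices.get(a), matrices.get(b)
        if dx is None or dy is None:
            scores[key] = None
            continue
        scores[key] = coevolution.coevolution_score(
            dx, dy, variant=variant, ref=ref, factor=factor, min_common=min_common
        )
    return scores


def score_all_methods(
    corpus: Corpus,
    pairs: Pairs,
    idc: int = 100,
    min_common: int = coevolution.DEFAULT_MIN_COMMON,
    include_coevolution: bool = True,
) -> dict[str, Scores]:
    """Every method's scores for the given pairs on one corpus."""
    pairs = list(pairs)
    scores: dict[str, Scores] = {
        "bppm": profile_scores(corpus.table, pairs, "binary"),
        "sppm": profile_scores(corpus.table, pairs, "bitscore"),
        "gcm": gcm_scores(corpus.table, corpus.annotations, pairs, idc=idc),
        "mdm": mdm_scores(corpus.table, corpus.annotations, pairs),
    }
    if include_coevolution:
        matrices = family_matrices(corpus.families)
        ref_16s = coevolution.msa_to_distance_matrix(corpus.reference_alignment)
        gd = coevolution.genome_distance_from_table(corpus.table)
        scores["mirrortree"] = mirrortree_scores(
            matrices, pairs, "mirrortree", min_common=min_common
        )
        scores["tol_mirrortree"] = mirrortree_scores(
            matrices, pairs, "tol", ref=ref_16s, min_common=min_common
        )
        scores["gd_mirrortree"] = mirrortree_scores(
            matrices, pairs, "gd", ref=gd, min_common=min_common
        )
    return scores


def build_gold(
    corpus: Corpus,
    ratio: int = 5,
    seed: int = 0,
    min_fraction: float = benchmark.DEFAULT_MIN_FRACTION,
) -> list[LabeledPair]:
    """Gold standard from a corpus: high-quality positives plus sampled
    negatives at 1:``ratio``.

    Negatives are drawn among the proteins that constitute the positive
    pairs, so positives and negatives share the same phyletic-spread
    distribution and only genomic signal separates them.
    """
    sources = corpus.gold_sources
    positives = benchmark.build_hqg(
        sources["dip"],
        sources["complexes"],
        sources["kegg_pairs"],
        sources["ecocyc_functional"],
        corpus.table,
        min_fraction=min_fraction,
    )
    positive_proteins = {p.protein_a for p in positives} | {
        p.protein_b for p in positives
    }
    negatives = benchmark.build_negatives(
        positive_proteins,
        corpus.protein_annotations,
        positives,
        ratio=ratio,
        seed=seed,
    )
    return positives + negatives


def corpus_aucs(
    corpus: Corpus,
    ratio: int = 5,
    seed: int = 0,
    idc: int = 100,
    min_common: int = coevolution.DEFAULT_MIN_COMMON,
    include_coevolution: bool = True,
) -> pd.DataFrame:
    """Per-method AUC on the corpus's own gold standard."""
    labels = build_gold(corpus, ratio=ratio, seed=seed)
    scores = score_all_methods(
        corpus,
        [pair.key for pair in labels],
        idc=idc,
        min_common=min_common,
        include_coevolution=include_coevolution,
    )
    return benchmark.evaluate(scores, labels, ORIENTATIONS)
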