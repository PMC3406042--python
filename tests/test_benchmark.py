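import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ppicontext.benchmark import (
    LabeledPair,
    ProteinAnnotation,
    auc,
    build_hqg,
    build_lqg,
    build_negatives,
    jaccard_pathway,
    pr_points,
    read_labeled_pairs,
    read_scores,
    roc_points,
    write_labeled_pairs,
    write_scores,
)
from ppicontext.orthology import OrthologTable


class TestJaccard:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ({"p1", "p2"}, {"p1", "p2"}, 1.0),
            ({"p1"}, {"p2"}, 0.0),
            ({"p1", "p2"}, {"p2", "p3", "p4"}, 0.25),
            (set(), set(), 0.0),
        ],
    )
    def test_values(self, x, y, expected):
        assert jaccard_pathway(x, y) == pytest.approx(expected)

    @given(st.sets(st.integers(0, 20)), st.sets(st.integers(0, 20)))
    def test_symmetric_and_bounded(self, x, y):
        sx = {str(i) for i in x}
        sy = {str(i) for i in y}
        value = jaccard_pathway(sx, sy)
        assert value == jaccard_pathway(sy, sx)
        assert 0.0 <= value <= 1.0


def _spread_table(counts, n_genomes=10):
    """Table where each protein appears in its requested number of genomes."""
    genomes = [f"g{i}" for i in range(n_genomes)]
    entries = {}
    for protein, count in counts.items():
        for g in genomes[:count]:
            entries[(protein, g)] = (f"{protein}_{g}", 50.0)
    return OrthologTable(entries, genomes, sorted(counts))


class TestGoldStandard:
    def test_hqg_requires_physical_and_functional_evidence(self):
        table = _spread_table({"a": 8, "b": 8, "c": 8, "d": 8})
        positives = build_hqg(
            dip=[("a", "b")],
            complexes=[],
            kegg_pairs=[("a", "b"), ("c", "d")],
            ecocyc_functional=[],
            table=table,
            min_genomes=5,
        )
        assert [p.key for p in positives] == [("a", "b")]
        assert positives[0].sources == {"dip", "kegg"}

    def test_hqg_enforces_phyletic_spread_on_both_proteins(self):
        table = _spread_table({"a": 8, "b": 3})
        positives = build_hqg([("a", "b")], [], [("a", "b")], [], table, min_genomes=5)
        assert positives == []

    def test_hqg_default_threshold_is_a_fraction_of_the_set(self):
        # 200/565 of 10 genomes -> ceil(3.54) = 4
        table = _spread_table({"a": 4, "b": 4, "c": 3, "d": 8})
        positives = build_hqg(
            [("a", "b"), ("c", "d")], [], [("a", "b"), ("c", "d")], [], table
        )
        assert [p.key for p in positives] == [("a", "b")]

    def test_lqg_union_with_single_pathway_filter(self):
        positives = build_lqg(
            dip=[("a", "b")],
            complexes=[("c", "d")],
            kegg_pathway_counts={("e", "f"): 1, ("g", "h"): 2, ("a", "b"): 1},
        )
        keys = [p.key for p in positives]
        assert keys == [("a", "b"), ("c", "d"), ("e", "f")]
        # de-duplicated pair keeps both source tags
        assert positives[0].sources == {"dip", "kegg"}

    def test_hqg_positives_subsumed_by_lqg(self):
        table = _spread_table({"a": 9, "b": 9, "c": 9, "d": 9})
        dip = [("a", "b"), ("c", "d")]
        kegg = {("a", "b"): 1, ("c", "d"): 1}
        hq = build_hqg(dip, [], list(kegg), [], table, min_genomes=2)
        lq = build_lqg(dip, [], kegg)
        assert {p.key for p in hq} <= {p.key for p in lq}


def _annotations():
    locs = ["cytosolic", "secretory", "membrane"]
    ann = {}
    for i in range(12):
        ann[f"p{i:02d}"] = ProteinAnnotation(
            pathways=frozenset({f"pw{i % 4}"}),
            categories=(f"cat{i % 5}",),
            localization=locs[i % 3],
        )
    ann["amb_loc"] = ProteinAnnotation((), ("catx",), "ambiguous")
    ann["multi_cat"] = ProteinAnnotation((), ("cat1", "cat2"), "cytosolic")
    return ann


class TestBuildNegatives:
    def test_ratio_is_honoured_when_pool_is_large(self):
        ann = _annotations()
        positives = [LabeledPair("p00", "p01", "positive")]
        negatives = build_negatives(ann, ann, positives, ratio=5, seed=3)
        assert len(negatives) == 5
        assert all(n.label == "negative" for n in negatives)

    def test_same_localization_pool_is_empty(self):
        ann = {
            "a": ProteinAnnotation((), ("c1",), "cytosolic"),
            "b": ProteinAnnotation((), ("c2",), "cytosolic"),
        }
        with pytest.warns(RuntimeWarning):
            negatives = build_negatives(ann, ann, [LabeledPair("x", "y", "positive")],
                                        ratio=1, seed=0)
        assert negatives == []

    def test_ambiguous_proteins_are_excluded(self):
        ann = _annotations()
        positives = [LabeledPair("p00", "p01", "positive")]
        negatives = build_negatives(ann, ann, positives, ratio=5, seed=1)
        used = {p for n in negatives for p in n.key}
        assert "amb_loc" not in used and "multi_cat" not in used

    def test_never_emits_a_positive_pair(self):
        ann = _annotations()
        positives = [
            LabeledPair(a, b, "positive")
            for a in ("p00", "p01") for b in ("p04", "p05")
        ]
        negatives = build_negatives(ann, ann, positives, ratio=2, seed=5)
        assert {n.key for n in negatives}.isdisjoint({p.key for p in positives})

    def test_fixed_seed_reruns_identically(self):
        ann = _annotations()
        positives = [LabeledPair("p00", "p01", "positive")]
        first = build_negatives(ann, ann, positives, ratio=5, seed=9)
        second = build_negatives(ann, ann, positives, ratio=5, seed=9)
        assert first == second
        different = build_negatives(ann, ann, positives, ratio=5, seed=10)
        assert first != different  # overwhelmingly likely for this pool


def _labels(scored):
    return [LabeledPair(a, b, label) for (a, b), label in scored]


class TestRocAndAuc:
    def test_perfect_separation_passes_through_zero_one(self):
        labels = _labels([(("a", "b"), "positive"), (("c", "d"), "negative")])
        scores = {("a", "b"): 0.9, ("c", "d"): 0.1}
        points = roc_points(scores, labels)
        assert (0.0, 1.0) in points
        assert auc(points) == 1.0

    def test_all_tied_scores_give_the_diagonal(self):
        labels = _labels(
            [(("a", "b"), "positive"), (("c", "d"), "negative"),
             (("e", "f"), "negative")]
        )
        scores = {k.key: 0.5 for k in labels}
        assert roc_points(scores, labels) == [(0.0, 0.0), (1.0, 1.0)]
        assert auc(roc_points(scores, labels)) == pytest.approx(0.5)

    def test_lower_better_orientation_flips_ranking(self):
        labels = _labels([(("a", "b"), "positive"), (("c", "d"), "negative")])
        scores = {("a", "b"): 0.01, ("c", "d"): 0.9}
        assert auc(roc_points(scores, labels, "lower_better")) == 1.0
        assert auc(roc_points(scores, labels, "higher_better")) == 0.0

    def test_matches_exhaustive_threshold_oracle(self, rng):
        labels = _labels(
            [((f"a{i}", f"b{i}"), "positive" if i % 3 else "negative")
             for i in range(1, 21)]
        )
        scores = {l.key: float(rng.choice([0.1, 0.3, 0.5, 0.7])) for l in labels}
        points = roc_points(scores, labels)
        n_pos = sum(l.label == "positive" for l in labels)
        n_neg = len(labels) - n_pos
        expected = {(0.0, 0.0)}
        for threshold in sorted(set(scores.values())):
            tp = sum(scores[l.key] >= threshold and l.label == "positive" for l in labels)
            fp = sum(scores[l.key] >= threshold and l.label == "negative" for l in labels)
            expected.add((fp / n_neg, tp / n_pos))
        assert set(points) == expected

    def test_auc_invariant_under_monotone_transform(self, rng):
        labels = _labels(
            [((f"a{i}", f"b{i}"), "positive" if rng.random() < 0.4 else "negative")
             for i in range(1, 31)]
        )
        scores = {l.key: float(rng.normal()) for l in labels}
        base = auc(roc_points(scores, labels))
        warped = {k: float(np.exp(3 * v) + 7) for k, v in scores.items()}
        assert auc(roc_points(warped, labels)) == pytest.approx(base, abs=1e-12)

    def test_reversed_orientation_complements_auc_without_ties(self, rng):
        labels = _labels(
            [((f"a{i}", f"b{i}"), "positive" if i % 2 else "negative")
             for i in range(1, 21)]
        )
        scores = {l.key: float(i) for i, l in enumerate(labels)}
        up = auc(roc_points(scores, labels, "higher_better"))
        down = auc(roc_points(scores, labels, "lower_better"))
        assert up + down == pytest.approx(1.0)

    def test_single_class_labels_rejected(self):
        labels = _labels([(("a", "b"), "positive")])
        with pytest.raises(ValueError):
            roc_points({("a", "b"): 1.0}, labels)

    def test_agrees_with_sklearn_on_random_fixtures(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(10):
            labels = _labels(
                [((f"a{i}", f"b{i}"), "positive" if rng.random() < 0.5 else "negative")
                 for i in range(1, 41)]
            )
            if len({l.label for l in labels}) < 2:
                continue
            scores = {l.key: float(rng.choice([0.2, 0.4, 0.6, 0.8])) for l in labels}
            y = [l.label == "positive" for l in labels]
            s = [scores[l.key] for l in labels]
            assert auc(roc_points(scores, labels)) == pytest.approx(
                roc_auc_score(y, s), abs=1e-12
            )


class TestPrPoints:
    def test_perfect_scores_hold_precision_one(self):
        labels = _labels(
            [(("a", "b"), "positive"), (("c", "d"), "positive"),
             (("e", "f"), "negative")]
        )
        scores = {("a", "b"): 0.9, ("c", "d"): 0.8, ("e", "f"): 0.1}
        points = pr_points(scores, labels)
        # precision stays 1.0 until every positive is recalled
        assert points[0] == (0.5, 1.0)
        assert points[1] == (1.0, 1.0)

    def test_single_positive_ranked_last(self):
        labels = _labels(
            [(("a", "b"), "positive"), (("c", "d"), "negative"),
             (("e", "f"), "negative")]
        )
        scores = {("a", "b"): 0.0, ("c", "d"): 0.9, ("e", "f"): 0.8}
        assert pr_points(scores, labels)[-1] == (1.0, 1 / 3)

    def test_no_score_pairs_rank_strictly_last(self):
        labels = _labels(
            [(("a", "b"), "positive"), (("c", "d"), "negative"),
             (("e", "f"), "negative")]
        )
        scores = {("a", "b"): None, ("c", "d"): 0.2, ("e", "f"): 0.4}
        assert auc(roc_points(scores, labels)) == 0.0


class TestScoreIO:
    def test_labeled_pairs_round_trip(self, tmp_path):
        pairs = [
            LabeledPair("b", "a", "positive", frozenset({"dip"})),
            LabeledPair("c", "d", "negative"),
        ]
        path = tmp_path / "labels.tsv"
        write_labeled_pairs(pairs, path)
        assert read_labeled_pairs(path) == pairs

    def test_scores_round_trip_preserves_no_score(self, tmp_path):
        scores = {("a", "b"): 0.25, ("c", "d"): None}
        path = tmp_path / "scores.tsv"
        write_scores(scores, path, "bppm")
        assert read_scores(path) == scores
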