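import itertools

import numpy as np
import pytest

from conftest import random_alignment_sets
from hlatrees.caller import (
    CallerConfig,
    assign_ambiguous_trees,
    call_haplotypes,
    estimate_expression,
    filter_genes_by_coverage,
    select_primary,
    select_secondary,
    sum_evidence,
)
from hlatrees.readtree import build_read_tree, iter_paths_at_level
from test_readtree import make_set


def forest(*alleles_per_read):
    return [
        build_read_tree(make_set(f"r{i}", alleles))
        for i, alleles in enumerate(alleles_per_read)
    ]


class TestSumEvidence:
    def test_unit_weight_counting(self):
        trees = forest(*[{"A*01:01": ()}] * 3, {"A*02:01": ()})
        ev = sum_evidence(trees, 2)
        assert ev.scores[("A", ("01",))] == pytest.approx(3.0)
        assert ev.scores[("A", ("02",))] == pytest.approx(1.0)

    def test_empty_collection(self):
        assert sum_evidence([], 2).scores == {}

    def test_constraint_restricts_paths(self):
        trees = forest({"A*01:01": (), "A*02:01": (), "B*07:02": ()})
        ev = sum_evidence(trees, 3, constraint={"A": ("01",)})
        assert set(ev.scores) == {("A", ("01", "01"))}

    def test_matches_independent_traversal(self):
        # brute force: walk every tree separately, summing node weights
        rng = np.random.default_rng(11)
        trees = [build_read_tree(s) for s in random_alignment_sets(rng, 20)]
        for level in (2, 3, 4):
            ev = sum_evidence(trees, level)
            brute = {}
            for t in trees:
                for path, w in iter_paths_at_level(t, level):
                    brute[path] = brute.get(path, 0.0) + w
            assert set(ev.scores) == set(brute)
            for path in brute:
                assert ev.scores[path] == pytest.approx(brute[path], rel=1e-12)


class TestSelectPrimary:
    def test_argmax_per_gene(self):
        trees = forest(*[{"A*01:01": ()}] * 3, {"A*02:01": ()},
                       *[{"B*07:02": ()}] * 2)
        got = select_primary(sum_evidence(trees, 2))
        assert got == {"A": ("A", ("01",)), "B": ("B", ("07",))}

    def test_tie_breaks_lexicographically(self):
        trees = forest(*[{"A*02:01": ()}] * 2, *[{"A*01:01": ()}] * 2)
        assert select_primary(sum_evidence(trees, 2))["A"] == ("A", ("01",))

    def test_single_candidate(self):
        trees = forest({"B*44:02": ()})
        assert select_primary(sum_evidence(trees, 2))["B"] == ("B", ("44",))

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            select_primary(sum_evidence([], 2))


class TestSelectSecondary:
    def test_pruning_reveals_second_group(self):
        # two unambiguous trees on A*01, one ambiguous A*01/A*02, one on
        # A*02: after temporary pruning to the primary, the ambiguous
        # tree's weight moves entirely to A*01 and the secondary group's
        # score is exactly the one unambiguous A*02 tree
        trees = forest({"A*01:01": ()}, {"A*01:01": ()},
                       {"A*01:01": (), "A*02:01": ()}, {"A*02:01": ()})
        primaries = select_primary(sum_evidence(trees, 2))
        assert primaries["A"] == ("A", ("01",))
        secondaries, scores = select_secondary(trees, primaries, 2)
        assert secondaries["A"] == ("A", ("02",))
        assert scores["A"][0] == pytest.approx(3.0)  # 2 + reassigned 1
        assert scores["A"][1] == pytest.approx(1.0)

    def test_single_group_is_homozygous(self):
        trees = forest({"A*01:01": ()}, {"A*01:02": ()})
        primaries = select_primary(sum_evidence(trees, 2))
        secondaries, _ = select_secondary(trees, primaries, 2)
        assert secondaries["A"] == primaries["A"]

    def test_five_percent_rule_within_shared_parent(self):
        # at the peptide level, a candidate sharing the primary's allele
        # group needs >= 5% of the primary's evidence
        trees = forest(*[{"A*01:01": ()}] * 96, *[{"A*01:02": ()}] * 4)
        primaries = {"A": ("A", ("01", "01"))}
        secondaries, _ = select_secondary(trees, primaries, 3,
                                          CallerConfig(seed=0))
        assert secondaries["A"] == primaries["A"]  # 4/96 < 5%: homozygous
        trees = forest(*[{"A*01:01": ()}] * 90, *[{"A*01:02": ()}] * 10)
        secondaries, _ = select_secondary(trees, primaries, 3,
                                          CallerConfig(seed=0))
        assert secondaries["A"] == ("A", ("01", "02"))


class TestAssignAmbiguousTrees:
    def test_greater_weight_wins(self):
        # one mismatch (q10) on A*02 makes A*01 the heavier side
        trees = forest({"A*01:01": (), "A*02:01": (10,)})
        rng = np.random.default_rng(0)
        out = assign_ambiguous_trees(
            trees, {"A": ("A", ("01",))}, {"A": ("A", ("02",))}, rng
        )
        assert [str(l.leaf_allele) for l in out[0].leaves()] == ["A*01:01"]
        assert next(iter(out[0].leaves())).w == pytest.approx(1.0)

    def test_equal_weights_split_deterministically_under_seed(self):
        def run(seed):
            trees = forest(*[{"A*01:01": (), "A*02:01": ()}] * 20)
            rng = np.random.default_rng(seed)
            out = assign_ambiguous_trees(
                trees, {"A": ("A", ("01",))}, {"A": ("A", ("02",))}, rng
            )
            return tuple(str(next(iter(t.leaves())).leaf_allele) for t in out)

        assert run(1) == run(1)
        both = set(run(1))
        assert both == {"A*01:01", "A*02:01"}  # coin flips land both ways

    def test_tree_count_conserved_and_nonsupporting_untouched(self):
        trees = forest({"A*01:01": ()}, {"B*07:02": ()})
        rng = np.random.default_rng(0)
        out = assign_ambiguous_trees(
            trees, {"A": ("A", ("01",))}, {"A": ("A", ("01",))}, rng
        )
        assert len(out) == 2
        assert out[1] is trees[1]  # no evidence for any call: unchanged


class TestCallHaplotypes:
    def test_clean_diploid_recovery(self):
        trees = forest(*[{"SYN1*01:01:01": ()}] * 60,
                       *[{"SYN1*02:01:01": ()}] * 40)
        result = call_haplotypes(trees, CallerConfig(seed=0))
        (call,) = result.calls
        assert str(call.primary) == "SYN1*01:01:01"
        assert str(call.secondary) == "SYN1*02:01:01"
        assert not call.homozygous
        assert call.per_level_scores[2] == (pytest.approx(60.0),
                                            pytest.approx(40.0))

    def test_homozygous_truth_gives_homozygous_call(self):
        trees = forest(*[{"SYN1*01:01:01": ()}] * 50)
        (call,) = call_haplotypes(trees, CallerConfig(seed=0)).calls
        assert call.homozygous
        assert str(call.secondary) == str(call.primary) == "SYN1*01:01:01"

    def test_five_percent_rule_across_peptide_coverage(self):
        # same allele group, different peptide: 30% coverage ratio is
        # called heterozygous, 3% collapses to homozygous
        def run(n_secondary):
            trees = forest(*[{"SYN1*01:01:01": ()}] * 100,
                           *[{"SYN1*01:02:01": ()}] * n_secondary)
            return call_haplotypes(trees, CallerConfig(seed=0)).calls[0]

        het = run(30)
        assert {str(het.primary), str(het.secondary)} \
            == {"SYN1*01:01:01", "SYN1*01:02:01"}
        homo = run(3)
        assert homo.homozygous and str(homo.primary) == "SYN1*01:01:01"

    def test_greedy_call_extends_level2_argmax(self):
        rng = np.random.default_rng(21)
        for trial in range(20):
            sets = random_alignment_sets(rng, 12, max_alleles=4)
            trees = [build_read_tree(s) for s in sets]
            primaries = select_primary(sum_evidence(trees, 2))
            result = call_haplotypes(trees, CallerConfig(seed=trial))
            for call in result.calls:
                assert call.primary.fields[:1] == primaries[call.gene][1][:1]

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(33)
        sets = random_alignment_sets(rng, 30)
        trees1 = [build_read_tree(s) for s in sets]
        trees2 = [build_read_tree(s) for s in sets]
        r1 = call_haplotypes(trees1, CallerConfig(seed=5))
        r2 = call_haplotypes(trees2, CallerConfig(seed=5))
        assert [(c.gene, str(c.primary), str(c.secondary)) for c in r1.calls] \
            == [(c.gene, str(c.primary), str(c.secondary)) for c in r2.calls]

    def test_repruned_trees_keep_root_weight(self):
        rng = np.random.default_rng(4)
        sets = random_alignment_sets(rng, 40)
        trees = [build_read_tree(s) for s in sets]
        result = call_haplotypes(trees, CallerConfig(seed=0))
        for tree in result.forest:
            total = sum(c.w for c in tree.root.children.values())
            assert total == pytest.approx(tree.root_weight, rel=1e-9)

    def test_empty_forest_rejected(self):
        with pytest.raises(ValueError):
            call_haplotypes([], CallerConfig())

    # Seeded forests (generator below) on which the greedy caller picks a
    # pair outside the exhaustive enumeration's argmax set.  Currently
    # empty: dominant-support secondary selection makes greedy and
    # exhaustive agree on all 150 seeded forests.  Any future algorithm
    # change that introduces a divergence must be recorded here rather
    # than silently tolerated.
    KNOWN_GREEDY_DIVERGENT = frozenset()

    def test_agrees_with_exhaustive_pair_enumeration(self):
        # oracle: score every unordered allele pair by assigning each tree
        # to its better-supported member; outside the frozen divergence
        # fixtures the greedy call must be among the top-scoring pairs
        pool = ["A*01:01:01", "A*01:02:01", "A*02:01:01", "A*02:02:01"]
        group = {p: p.split("*")[1][:2] for p in pool}
        rng = np.random.default_rng(2025)
        divergent = set()
        for trial in range(150):
            t1, t2 = rng.choice(4, size=2, replace=True)
            n_trees = int(rng.integers(4, 11))
            reads = []
            for _ in range(n_trees):
                src = pool[t1 if rng.random() < 0.6 else t2]
                d = {src: ()}
                for other in pool:
                    if other == src:
                        continue
                    same_group = group[other] == group[src]
                    if rng.random() < (0.5 if same_group else 0.15):
                        n_mm = 1 if same_group else 2
                        d[other] = tuple(
                            int(q) for q in rng.integers(20, 41, size=n_mm)
                        )
                reads.append(d)
            trees = forest(*reads)

            def support(tree, raw):
                from hlatrees.reference import parse_allele_name
                node = tree.node_at(parse_allele_name(raw).path)
                return node.w if node is not None else 0.0

            best_score = -1.0
            best_pairs = set()
            for a, b in itertools.combinations_with_replacement(pool, 2):
                s = sum(max(support(t, a), support(t, b)) for t in trees)
                if s > best_score * (1 + 1e-9) + 1e-12:
                    best_score, best_pairs = s, {frozenset((a, b))}
                elif abs(s - best_score) <= 1e-9 * best_score + 1e-12:
                    best_pairs.add(frozenset((a, b)))
            (call,) = call_haplotypes(trees, CallerConfig(seed=trial)).calls
            got = frozenset((str(call.primary), str(call.secondary)))
            if got not in best_pairs:
                divergent.add(trial)
        assert divergent == set(self.KNOWN_GREEDY_DIVERGENT)


class TestExpression:
    def test_fully_assigned_counts(self):
        trees = forest(*[{"A*01:01": ()}] * 10, *[{"B*07:02": ()}] * 5)
        expr = estimate_expression(trees)
        assert expr == {"A": pytest.approx(10.0), "B": pytest.approx(5.0)}

    def test_unassigned_tree_weight_stays_split(self):
        trees = forest({"A*01:01": (), "B*07:02": ()})
        expr = estimate_expression(trees)
        assert expr["A"] == pytest.approx(0.5)
        assert expr["B"] == pytest.approx(0.5)
        assert sum(expr.values()) == pytest.approx(1.0)

    def test_proportions_invariant_under_root_weight_scaling(self):
        sets = random_alignment_sets(np.random.default_rng(8), 20)
        e1 = estimate_expression([build_read_tree(s, 1.0) for s in sets])
        e2 = estimate_expression([build_read_tree(s, 2.0) for s in sets])
        for gene in e1:
            assert e2[gene] == pytest.approx(2 * e1[gene], rel=1e-9)


class TestCoverageFilter:
    def test_threshold(self):
        assert filter_genes_by_coverage({"A": 50, "E": 0.5}, 1000, 0.01) \
            == {"A"}

    def test_zero_fraction_keeps_all(self):
        assert filter_genes_by_coverage({"A": 1, "E": 0.0}, 1000, 0.0) \
            == {"A", "E"}

    def test_boundary_kept(self):
        assert filter_genes_by_coverage({"A": 10.0}, 1000, 0.01) == {"A"}
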