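import random

import pytest

from fixiscan.aggregate import (
    GenomeSummary,
    bin_copy_number,
    collapse_to_rank,
    prune_tree,
    summarize_genome,
    summarize_order,
)
from fixiscan.architecture import Variant, VariantCall
from fixiscan.errors import ValidationError
from fixiscan.io import tree_from_string
from fixiscan.records import Lineage, TaxonomyMap


def vc(variant, pid="p"):
    return VariantCall(protein_id=pid, variant=variant)


def taxonomy_for(orders: dict[str, str]) -> TaxonomyMap:
    return TaxonomyMap(
        {
            gid: Lineage((("domain", "Bacteria"), ("order", order)))
            for gid, order in orders.items()
        }
    )


class TestSummarizeGenome:
    def test_counts_per_variant(self):
        calls = [vc(Variant.ONE_DOMAIN), vc(Variant.ONE_DOMAIN), vc(Variant.TWO_DOMAIN)]
        s = summarize_genome("G1", calls, cbb3_present=True)
        assert s.copy_number == {"ONE_DOMAIN": 2, "TWO_DOMAIN": 1}

    def test_no_calls_all_zero(self):
        s = summarize_genome("G1", [], cbb3_present=False)
        assert s.copy_number == {"ONE_DOMAIN": 0, "TWO_DOMAIN": 0}

    def test_none_calls_excluded_and_no_binning_yet(self):
        calls = [vc(Variant.ONE_DOMAIN)] * 9 + [vc(Variant.NONE)]
        s = summarize_genome("G1", calls, cbb3_present=False)
        assert s.copy_number["ONE_DOMAIN"] == 9


class TestSummarizeOrder:
    def make(self, copies, cbb3=None, order="O1"):
        cbb3 = cbb3 or [False] * len(copies)
        genomes = [
            GenomeSummary(
                genome_id=f"G{i}",
                copy_number={"ONE_DOMAIN": c, "TWO_DOMAIN": 0},
                cbb3_present=b,
            )
            for i, (c, b) in enumerate(zip(copies, cbb3))
        ]
        tax = taxonomy_for({f"G{i}": order for i in range(len(copies))})
        return genomes, tax

    def test_proportions_from_counts(self):
        genomes, tax = self.make([0, 1, 1, 2])
        (s,) = summarize_order(genomes, tax)
        assert s.copy_dist["ONE_DOMAIN"] == (0.25, 0.5, 0.25, 0, 0, 0, 0, 0)

    def test_empty_genome_is_bin_zero(self):
        genomes, tax = self.make([0], cbb3=[False])
        (s,) = summarize_order(genomes, tax)
        assert s.copy_dist["ONE_DOMAIN"][0] == 1.0
        assert s.cbb3_proportion == 0.0

    def test_high_copy_number_lands_in_top_bin(self):
        genomes, tax = self.make([9])
        (s,) = summarize_order(genomes, tax)
        assert s.copy_dist["ONE_DOMAIN"][7] == 1.0
        assert bin_copy_number(9) == 7
        assert bin_copy_number(7) == 7
        assert bin_copy_number(6) == 6

    def test_missing_taxonomy_is_error(self):
        genomes, _ = self.make([1])
        tax = taxonomy_for({"other": "O1"})
        with pytest.raises(ValidationError):
            summarize_order(genomes, tax)

    def test_distributions_sum_to_one(self):
        rnd = random.Random(23)
        genomes = []
        orders = {}
        for i in range(60):
            gid = f"G{i}"
            orders[gid] = f"O{rnd.randint(1, 5)}"
            genomes.append(
                GenomeSummary(
                    genome_id=gid,
                    copy_number={
                        "ONE_DOMAIN": rnd.randint(0, 10),
                        "TWO_DOMAIN": rnd.randint(0, 3),
                    },
                    cbb3_present=rnd.random() < 0.5,
                )
            )
        for s in summarize_order(genomes, taxonomy_for(orders)):
            for dist in s.copy_dist.values():
                assert abs(sum(dist) - 1.0) < 1e-9

    def test_permutation_invariance(self):
        genomes, tax = self.make([0, 1, 2, 3, 7, 9])
        ref = summarize_order(genomes, tax)
        rnd = random.Random(1)
        for _ in range(5):
            shuffled = genomes[:]
            rnd.shuffle(shuffled)
            assert summarize_order(shuffled, tax) == ref


NEWICK4 = "((A:1,B:2):3,(C:4,D:5):6):0;"


class TestPruneTree:
    def test_keep_all_is_identity_topology(self):
        t = tree_from_string(NEWICK4)
        pruned = prune_tree(t, {"A", "B", "C", "D"})
        assert {lf.taxon.label for lf in pruned.leaf_node_iter()} == {"A", "B", "C", "D"}

    def test_keep_two_sisters_gives_cherry(self):
        pruned = prune_tree(tree_from_string(NEWICK4), {"A", "B"})
        labels = {lf.taxon.label for lf in pruned.leaf_node_iter()}
        assert labels == {"A", "B"}
        lengths = {lf.taxon.label: lf.edge.length for lf in pruned.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 2.0}

    def test_single_leaf_prune_sums_path_lengths(self):
        pruned = prune_tree(tree_from_string(NEWICK4), {"C"})
        (leaf,) = pruned.leaf_node_iter()
        # root-to-C path: 0 (root) + 6 + 4
        assert leaf.edge.length == pytest.approx(10.0)

    def test_unknown_leaf_in_keep_set_is_error(self):
        with pytest.raises(ValidationError, match="Z"):
            prune_tree(tree_from_string(NEWICK4), {"A", "Z"})

    def test_idempotence(self):
        t = tree_from_string(NEWICK4)
        once = prune_tree(t, {"A", "C"})
        twice = prune_tree(once, {"A", "C"})
        assert once.as_string(schema="newick") == twice.as_string(schema="newick")


class TestCollapseToRank:
    def test_all_leaves_one_order_single_leaf(self):
        tax = taxonomy_for({x: "Caulobacterales" for x in "ABCD"})
        collapsed = collapse_to_rank(tree_from_string(NEWICK4), tax)
        labels = [lf.taxon.label for lf in collapsed.leaf_node_iter()]
        assert labels == ["Caulobacterales"]

    def test_two_monophyletic_orders_two_leaves(self):
        tax = taxonomy_for({"A": "O1", "B": "O1", "C": "O2", "D": "O2"})
        collapsed = collapse_to_rank(tree_from_string(NEWICK4), tax)
        labels = {lf.taxon.label for lf in collapsed.leaf_node_iter()}
        assert labels == {"O1", "O2"}

    def test_split_order_gets_suffixed_names(self, caplog):
        # O1 = {A, C} is not monophyletic on ((A,B),(C,D))
        tax = taxonomy_for({"A": "O1", "B": "O2", "C": "O1", "D": "O2"})
        collapsed = collapse_to_rank(tree_from_string(NEWICK4), tax)
        labels = {lf.taxon.label for lf in collapsed.leaf_node_iter()}
        assert {"O1", "O1_2"} <= labels
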