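"""Circular signed gene orders, breakpoint distance, translocation detection."""

import itertools
import random

import pytest

from mitochar import (ANCESTRAL_INSECT_ORDER, LEPIDOPTERAN_ORDER, AnnotatedGenome,
                      FeatureRecord, GeneOrder, adjacency_set, breakpoint_distance,
                      detect_translocated_genes, extract_gene_order)


def brute_force_breakpoints(a: GeneOrder, b: GeneOrder) -> int:
    """Independent oracle: scan every consecutive pair of `a` and look for
    it among the consecutive pairs of `b` position by position."""
    la, lb = a.labels, b.labels
    missing = 0
    for i in range(len(la)):
        pair = (la[i], la[(i + 1) % len(la)])
        found = any((lb[j], lb[(j + 1) % len(lb)]) == pair for j in range(len(lb)))
        missing += not found
    return missing


def random_signed_order(rng: random.Random, n: int) -> GeneOrder:
    labels = [f"g{i}" for i in range(n)]
    rng.shuffle(labels)
    return GeneOrder(tuple((l, rng.choice([1, -1])) for l in labels), anchor="g0")


class TestGeneOrderObject:
    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="dup"):
            GeneOrder((("a", 1), ("b", 1), ("a", -1)))

    def test_rotation_to_anchor(self):
        o = GeneOrder.from_tokens(["a", "-b", "CR", "c"], anchor="CR")
        assert o.rotated_to_anchor().labels[0] == ("CR", 1)

    def test_string_form_carries_signs(self):
        o = GeneOrder.from_tokens(["CR", "a", "-b"], anchor="CR")
        assert str(o) == "CR a -b"


class TestExtractGeneOrder:
    def test_toy_annotation(self):
        g = AnnotatedGenome("t", "A" * 30, [
            FeatureRecord("a", "other", "F", 1, 10),
            FeatureRecord("b", "other", "R", 11, 20),
            FeatureRecord("c", "other", "F", 21, 30)])
        assert extract_gene_order(g, anchor="a").labels == \
            (("a", 1), ("b", -1), ("c", 1))

    def test_reference_genome_matches_derived_template(self, ar_genome):
        """The published arrangement starts trnM, trnI, -trnQ, nad2 and is
        adjacency-identical to the derived lepidopteran template."""
        order = extract_gene_order(ar_genome)
        assert order.labels[:4] == (("trnM", 1), ("trnI", 1), ("trnQ", -1), ("nad2", 1))
        assert adjacency_set(order) == adjacency_set(LEPIDOPTERAN_ORDER)

    def test_ancestral_template_contains_ancestral_cluster(self):
        from mitochar import SyntheticSpec, generate_genome
        genome, _ = generate_genome(SyntheticSpec(seed=2, gene_order_template="ancestral_insect"))
        labels = extract_gene_order(genome).labels
        idx = labels.index(("trnI", 1))
        assert labels[idx:idx + 3] == (("trnI", 1), ("trnQ", -1), ("trnM", 1))
        assert labels[idx + 3] == ("nad2", 1)


class TestAdjacencySet:
    def test_triangle(self):
        o = GeneOrder.from_tokens(["a", "b", "c"], anchor="a")
        assert adjacency_set(o) == {(("a", 1), ("b", 1)), (("b", 1), ("c", 1)),
                                    (("c", 1), ("a", 1))}

    def test_rearranged_cluster_has_five_pairs(self):
        o = GeneOrder.from_tokens(["CR", "trnI", "-trnQ", "trnM", "nad2"], anchor="CR")
        pairs = adjacency_set(o)
        assert len(pairs) == 5
        assert (("nad2", 1), ("CR", 1)) in pairs

    def test_rotation_invariance(self):
        o = GeneOrder.from_tokens(["a", "-b", "c", "d"], anchor="a")
        for k in range(4):
            rot = GeneOrder(o.labels[k:] + o.labels[:k], anchor="a")
            assert adjacency_set(rot) == adjacency_set(o)

    def test_singleton_rejected(self):
        with pytest.raises(ValueError):
            adjacency_set(GeneOrder((("a", 1),)))


class TestBreakpointDistance:
    def test_identity_is_zero(self):
        assert breakpoint_distance(LEPIDOPTERAN_ORDER, LEPIDOPTERAN_ORDER) == 0

    def test_trnm_cluster_distance_is_three(self):
        anc = GeneOrder.from_tokens(["CR", "trnI", "-trnQ", "trnM", "nad2"], anchor="CR")
        der = GeneOrder.from_tokens(["CR", "trnM", "trnI", "-trnQ", "nad2"], anchor="CR")
        assert breakpoint_distance(anc, der) == 3
        assert breakpoint_distance(der, anc) == 3

    def test_sign_flip_registers_as_breakpoints(self):
        a = GeneOrder.from_tokens(["a", "b", "c"], anchor="a")
        b = GeneOrder.from_tokens(["a", "-b", "c"], anchor="a")
        assert breakpoint_distance(a, b) == 2

    def test_label_set_mismatch_reports_difference(self):
        a = GeneOrder.from_tokens(["a", "b"], anchor="a")
        b = GeneOrder.from_tokens(["a", "c"], anchor="a")
        with pytest.raises(ValueError, match="c"):
            breakpoint_distance(a, b)

    def test_rotations_have_zero_distance(self):
        rng = random.Random(7)
        for n in (3, 5, 8, 12):
            o = random_signed_order(rng, n)
            for k in range(n):
                rot = GeneOrder(o.labels[k:] + o.labels[:k], anchor=o.anchor)
                assert breakpoint_distance(o, rot) == 0

    def test_exhaustive_oracle_small_orders(self):
        """All pairs of signed circular orders on 3 labels."""
        labels = ["g0", "g1", "g2"]
        orders = [GeneOrder(tuple(zip(perm, signs)), anchor="g0")
                  for perm in itertools.permutations(labels)
                  for signs in itertools.product((1, -1), repeat=3)]
        for a in orders:
            for b in orders:
                assert breakpoint_distance(a, b) == brute_force_breakpoints(a, b)

    def test_random_oracle_medium_orders(self):
        rng = random.Random(13)
        for _ in range(200):
            n = rng.randint(4, 8)
            a, b = random_signed_order(rng, n), random_signed_order(rng, n)
            assert breakpoint_distance(a, b) == brute_force_breakpoints(a, b)


class TestDetectTranslocatedGenes:
    def test_headline_rearrangement_is_trnm(self):
        """The derived lepidopteran order differs from the ancestral insect
        order by a single trnM translocation."""
        assert detect_translocated_genes(LEPIDOPTERAN_ORDER,
                                         ANCESTRAL_INSECT_ORDER) == {"trnM"}

    def test_identical_orders_give_empty_set(self):
        assert detect_translocated_genes(ANCESTRAL_INSECT_ORDER,
                                         ANCESTRAL_INSECT_ORDER) == set()

    def test_adjacent_swap_reports_both_candidates(self):
        # for a transposition of neighbours, removing either gene alone
        # reconciles the orders, so both are minimal explanations
        ref_o = GeneOrder.from_tokens(["a", "b", "c", "d", "e", "f"], anchor="a")
        obs = GeneOrder.from_tokens(["a", "c", "b", "d", "e", "f"], anchor="a")
        assert detect_translocated_genes(obs, ref_o) == {"b", "c"}

    def test_long_range_move_reports_only_the_mover(self):
        ref_o = GeneOrder.from_tokens(["a", "b", "c", "d", "e", "f"], anchor="a")
        obs = GeneOrder.from_tokens(["a", "b", "c", "e", "f", "d"], anchor="a")
        assert detect_translocated_genes(obs, ref_o) == {"d"}

    def test_synthetic_pipeline_recovery(self, synthetic_pair):
        genome, _ = synthetic_pair
        order = extract_gene_order(genome)
        assert detect_translocated_genes(order, ANCESTRAL_INSECT_ORDER) == {"trnM"}
        assert detect_translocated_genes(order, LEPIDOPTERAN_ORDER) == set()
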