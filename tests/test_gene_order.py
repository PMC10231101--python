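"""Signed gene orders: extraction, rotation invariance, breakpoints,
inversion/translocation detection."""

import numpy as np
import pytest

from mitocomp import (SignedGeneOrder, breakpoint_distance, compare_orders,
                      extract_gene_order)
from mitocomp.gene_order import adjacency_set, rotations
from mitocomp.vocab import ANCESTRAL_ORDER, PCGS


def swap_adjacent(order, gene):
    """Swap a gene with its successor, keeping signs."""
    toks = list(order.tokens)
    i = [t[0] for t in toks].index(gene)
    toks[i], toks[i + 1] = toks[i + 1], toks[i]
    return SignedGeneOrder(tuple(toks))


def oracle_breakpoints(a, b):
    """Independent adjacency-set implementation (reference for the tests)."""
    def adjacencies(order):
        g = order.genes
        pairs = set()
        for x, y in zip(g, g[1:] + g[:1]):
            fwd = (x, y)
            rev = ((y[0], -y[1]), (x[0], -x[1]))   # same junction, read back
            pairs.add(frozenset({fwd, rev}))
        return pairs
    return len(adjacencies(a) - adjacencies(b))


class TestAncestralOrder:
    def test_strand_partition_of_pcgs(self, anc):
        j = {n for n, s in anc.tokens if n in PCGS and s > 0}
        n_ = {n for n, s in anc.tokens if n in PCGS and s < 0}
        assert j == {"ATP6", "ATP8", "COX1", "COX2", "COX3", "CYTB",
                     "ND2", "ND3", "ND6"}
        assert n_ == {"ND1", "ND4", "ND4L", "ND5"}

    def test_contains_contiguous_arns1ef_block(self, anc):
        names = [n for n, _ in anc.tokens]
        i = names.index("trnA")
        assert names[i:i + 6] == ["trnA", "trnR", "trnN", "trnS1",
                                  "trnE", "trnF"]

    def test_has_37_genes_and_one_cr(self, anc):
        assert len(anc.genes) == 37
        assert [n for n, _ in anc.tokens if n == "CR"] == ["CR"]


class TestExtraction:
    def test_zero_event_generator_output_is_ancestral(self, default_genome,
                                                      anc):
        g, _ = default_genome
        assert extract_gene_order(g) == anc

    def test_rotation_of_the_genome_changes_nothing(self, default_genome,
                                                    anc):
        g, _ = default_genome
        assert extract_gene_order(g.rotated(5000)) == anc

    def test_duplicate_gene_rejected(self, default_genome):
        import dataclasses
        g, _ = default_genome
        dup = g.features[5]
        feats = list(g.features) + [dataclasses.replace(
            dup, start=dup.start + 7000, end=dup.end + 7000)]
        from mitocomp.model import AnnotatedMitogenome
        g2 = AnnotatedMitogenome(g.id, g.sequence, True, feats)
        with pytest.raises(ValueError, match="duplicate"):
            extract_gene_order(g2)

    def test_split_cr_extraction_interleaves_markers(self, cohort):
        g = next(g for g, _ in cohort if "CR1" in g)
        tokens = extract_gene_order(g).tokens
        names = [n for n, _ in tokens]
        i = names.index("CR1")
        assert names[i:i + 3] == ["CR1", "trnI", "CR2"]
        assert dict(tokens)["trnI"] == -1
        assert names[(i - 1) % len(names)] == "rrnS"
        assert names[(i + 3) % len(names)] == "trnQ"


class TestEquality:
    def test_rotation_invariant_equality_and_hash(self, anc):
        for rot in list(rotations(anc))[::7]:
            assert rot == anc
            assert hash(rot) == hash(anc)

    def test_serialisation_round_trip(self, anc):
        assert SignedGeneOrder.from_line(anc.to_line()) == anc

    def test_line_starts_at_trnI_with_sign_prefixes(self, anc):
        line = anc.to_line()
        assert line.startswith("trnI -trnQ trnM ND2 ")
        assert " -ND1 " in line


class TestBreakpoints:
    def test_identical_orders_have_zero(self, anc):
        assert breakpoint_distance(anc, anc) == 0

    def test_adjacent_swap_against_enumeration_oracle(self, anc):
        swapped = swap_adjacent(anc, "trnA")
        assert breakpoint_distance(anc, swapped) == \
            oracle_breakpoints(anc, swapped) == 3

    def test_random_shuffles_match_oracle_and_symmetry(self, anc):
        rng = np.random.default_rng(23)
        for _ in range(100):
            genes = list(anc.genes)
            perm = rng.permutation(len(genes))
            toks = tuple((genes[i][0], int(rng.choice([-1, 1])))
                         for i in perm)
            other = SignedGeneOrder(toks)
            d = breakpoint_distance(anc, other)
            assert d == oracle_breakpoints(anc, other)
            assert d == breakpoint_distance(other, anc)

    def test_gene_set_mismatch_rejected(self, anc):
        smaller = SignedGeneOrder(anc.tokens[:-2])
        with pytest.raises(ValueError, match="gene sets differ"):
            breakpoint_distance(anc, smaller)

    def test_sign_flip_breaks_two_adjacencies(self, anc):
        toks = tuple((n, -s if n == "trnI" else s) for n, s in anc.tokens)
        assert breakpoint_distance(SignedGeneOrder(toks), anc) == 2


class TestCompareOrders:
    def test_identical(self, anc):
        report = compare_orders(anc, anc)
        assert report.identical
        assert report.breakpoints == 0
        assert report.inverted == [] and report.translocated == []

    def test_trnA_trnR_swap(self, anc):
        swapped = swap_adjacent(anc, "trnA")
        report = compare_orders(swapped, anc)
        assert not report.identical
        assert report.inverted == []
        assert set(report.translocated_genes) <= {"trnA", "trnR"}
        assert report.translocated_genes
        assert report.affected_cluster == "ARNS1EF"

    def test_inverted_translocated_trnI(self, anc):
        toks = [t for t in anc.tokens if t[0] != "trnI"]
        cr = [t[0] for t in toks].index("CR")
        toks[cr:cr + 1] = [("CR1", 1), ("trnI", -1), ("CR2", 1)]
        observed = SignedGeneOrder(tuple(toks))
        report = compare_orders(observed, anc)
        assert report.inverted == ["trnI"]
        assert report.translocated_genes == ["trnI"]
        assert report.affected_cluster == "IQM"
        gene, old, new = report.translocated[0]
        assert (old, new) == ("CR|trnQ", "CR|CR")

    def test_in_place_inversion_is_not_a_translocation(self, anc):
        toks = tuple((n, -s if n == "trnV" else s) for n, s in anc.tokens)
        report = compare_orders(SignedGeneOrder(toks), anc)
        assert report.inverted == ["trnV"]
        assert report.translocated == []

    def test_report_invariant_identical_iff_empty(self, anc):
        report = compare_orders(anc, anc)
        assert report.identical == (
            not report.inverted and not report.translocated
            and report.breakpoints == 0)

    def test_rotation_never_changes_the_report(self, anc):
        swapped = swap_adjacent(anc, "trnA")
        base = compare_orders(swapped, anc).to_json()
        for rot in list(rotations(swapped))[::9]:
            assert compare_orders(rot, anc).to_json() == base


def test_adjacency_set_is_rotation_invariant(anc):
    base = adjacency_set(anc)
    for rot in list(rotations(anc))[::5]:
        assert adjacency_set(rot) == base
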