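"""Skews, junction accounting, codon classification, RSCU and NCR homology."""

import numpy as np
import pytest
from Bio.Seq import reverse_complement
from hypothesis import given, settings, strategies as st

from mitocomp import (AnnotatedMitogenome, GeneFeature, classify_codons,
                      codon_usage, composition_stats, gene_junctions,
                      ncr_homology_scan, rscu_from_counts, strandwise_stats)
from mitocomp.composition import CODON_FAMILIES

dna = st.text(alphabet="ACGT", min_size=1, max_size=300)


class TestCompositionStats:
    @pytest.mark.parametrize("seq,at_skew", [
        ("AATT", 0.0),
        ("AAAT", 0.5),
        ("TTTA", -0.5),
    ])
    def test_at_skew_examples(self, seq, at_skew):
        assert composition_stats(seq).at_skew == pytest.approx(at_skew)

    def test_skew_undefined_when_denominator_empty(self):
        stats = composition_stats("GGCC")
        assert stats.at_skew is None
        assert stats.gc_skew == pytest.approx(0.0)

    def test_n_bases_ignored(self):
        assert composition_stats("AANN").at_skew == pytest.approx(1.0)

    def test_percentages_sum_to_100(self):
        stats = composition_stats("ACGTACGGGTTTAA")
        assert sum(stats.pct_each_base.values()) == pytest.approx(100.0)

    @settings(derandomize=True, max_examples=200)
    @given(dna)
    def test_skew_antisymmetry_under_reverse_complement(self, seq):
        fwd, rev = composition_stats(seq), composition_stats(
            reverse_complement(seq))
        if fwd.at_skew is None:
            assert rev.at_skew is None
        else:
            assert rev.at_skew == pytest.approx(-fwd.at_skew)
            assert -1.0 <= fwd.at_skew <= 1.0
        if fwd.gc_skew is None:
            assert rev.gc_skew is None
        else:
            assert rev.gc_skew == pytest.approx(-fwd.gc_skew)


class TestStrandwiseStats:
    def test_single_feature_subset_equals_plain_stats(self, default_genome):
        g, _ = default_genome
        f = g.get("ND2")
        pooled = strandwise_stats(g, [f])["subset"]
        assert pooled.to_json() == composition_stats(g.feature_seq(f)).to_json()

    def test_n_strand_feature_uses_coding_strand(self):
        gene = "ATGAAACCCGGGTTTTAA"
        seq = "AAAA" + reverse_complement(gene) + "AAAA"
        g = AnnotatedMitogenome(
            "x", seq, True,
            [GeneFeature("ND1", "PCG", "N", 4, 4 + len(gene))])
        pooled = strandwise_stats(g, [g.get("ND1")])["subset"]
        assert pooled.to_json() == composition_stats(gene).to_json()

    def test_empty_subset_rejected(self, default_genome):
        g, _ = default_genome
        with pytest.raises(ValueError):
            strandwise_stats(g, [])

    def test_class_strand_asymmetry_of_generated_cohort(self, cohort):
        # J-strand PCGs: positive AT-skew, negative GC-skew; rRNAs opposite
        for g, _ in cohort:
            by_class = strandwise_stats(g)
            assert by_class["J-PCG"].at_skew > 0
            assert by_class["J-PCG"].gc_skew < 0
            assert by_class["rRNA"].at_skew < 0
            assert by_class["rRNA"].gc_skew > 0


class TestGeneJunctions:
    def test_abutting_features_have_zero_gap(self):
        g = AnnotatedMitogenome(
            "x", "ACGT" * 50, True,
            [GeneFeature("trnA", "tRNA", "J", 0, 66),
             GeneFeature("trnR", "tRNA", "J", 66, 132)])
        table = gene_junctions(g)
        assert table.gap_bp.iloc[0] == 0

    def test_planted_overlaps_recovered(self, default_genome):
        g, _ = default_genome
        table = gene_junctions(g).set_index(["upstream", "downstream"])
        assert table.loc[("ATP8", "ATP6"), "gap_bp"] == -4
        assert table.loc[("ATP8", "ATP6"), "overlap_seq"] == "ATAA"
        assert table.loc[("trnW", "trnC"), "gap_bp"] == -8
        assert table.loc[("trnW", "trnC"), "overlap_seq"] == "AAGCCTTA"

    def test_circular_closure_identity(self, cohort):
        for g, _ in cohort:
            table = gene_junctions(g)
            total = sum(f.length for f in g.features) + table.gap_bp.sum()
            assert total == len(g.sequence)

    def test_planted_ncr_appears_as_positive_gap(self, cohort):
        g = next(g for g, t in cohort if t.ncr)
        table = gene_junctions(g).set_index(["upstream", "downstream"])
        assert table.loc[("trnS2", "NCR"), "gap_bp"] == 0
        assert g.get("NCR").length == 198

    def test_nested_features_rejected(self):
        g = AnnotatedMitogenome(
            "x", "ACGT" * 50, True,
            [GeneFeature("rrnL", "rRNA", "J", 0, 150),
             GeneFeature("trnV", "tRNA", "J", 10, 80)])
        with pytest.raises(ValueError, match="nested"):
            gene_junctions(g)


class TestClassifyCodons:
    def _one_gene_genome(self, coding, strand="J", trailer=40):
        seq = coding + "A" * trailer
        if strand == "N":
            seq = reverse_complement(coding) + "A" * trailer
        return AnnotatedMitogenome(
            "x", seq, True,
            [GeneFeature("ND2", "PCG", strand, 0, len(coding)),
             GeneFeature("trnW", "tRNA", "J", len(coding), len(coding) + 30)])

    def test_complete_standard_gene(self):
        g = self._one_gene_genome("ATG" + "AAA" * 5 + "TAA")
        row = classify_codons(g).iloc[0]
        assert (row.start_codon, row.stop_codon) == ("ATG", "TAA")
        assert row.start_standard and row.stop_complete

    def test_incomplete_stop_requires_abutting_neighbor(self):
        g = self._one_gene_genome("ATA" + "AAA" * 5 + "T")
        row = classify_codons(g).iloc[0]
        assert row.stop_codon == "T"
        assert row.stop_incomplete and not row.stop_complete

    def test_trailing_t_far_from_next_gene_not_a_stop(self):
        coding = "ATA" + "AAA" * 5 + "T"
        g = AnnotatedMitogenome(
            "x", coding + "G" * 50 + "A" * 30, True,
            [GeneFeature("ND2", "PCG", "J", 0, len(coding)),
             GeneFeature("trnW", "tRNA", "J", len(coding) + 50,
                         len(coding) + 80)])
        row = classify_codons(g).iloc[0]
        assert row.stop_codon == ""

    def test_nonstandard_start_flagged(self):
        g = self._one_gene_genome("CCC" + "AAA" * 5 + "TAA")
        row = classify_codons(g).iloc[0]
        assert not row.start_standard

    def test_n_strand_gene_read_on_coding_strand(self):
        g = self._one_gene_genome("TTG" + "GCA" * 10 + "TAG", strand="N")
        row = classify_codons(g).iloc[0]
        assert (row.start_codon, row.stop_codon) == ("TTG", "TAG")

    def test_generated_genome_defaults(self, default_genome):
        g, _ = default_genome
        table = classify_codons(g).set_index("gene")
        assert table.loc["ND1", "start_codon"] == "TTG"
        assert table.loc["COX1", "stop_codon"] == "T"
        assert table.loc["COX2", "stop_codon"] == "T"
        assert not table.loc["COX1", "stop_complete"]
        assert table.loc["ND2", "stop_complete"]
        assert table.start_standard.all()

    def test_short_pcg_rejected(self):
        g = AnnotatedMitogenome(
            "x", "ATGTT" + "A" * 60, True,
            [GeneFeature("ND2", "PCG", "J", 0, 5)])
        with pytest.raises(ValueError, match="shorter"):
            classify_codons(g)


class TestCodonUsage:
    def _genome_from_codons(self, codons):
        coding = "ATG" + "".join(codons) + "TAA"
        return AnnotatedMitogenome(
            "x", coding + "A" * 40, True,
            [GeneFeature("ND2", "PCG", "J", 0, len(coding))])

    def test_exclusive_uua_gives_rscu_six(self):
        g = self._genome_from_codons(["TTA"] * 10 + ["GGA"] * 3)
        usage = codon_usage(g)
        assert usage.rscu["TTA"] == pytest.approx(6.0)

    def test_uniform_family_gives_rscu_one(self):
        leu = ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"]
        g = self._genome_from_codons(leu * 4)
        usage = codon_usage(g)
        for codon in leu:
            assert usage.rscu[codon] == pytest.approx(1.0)

    def test_family_sums_equal_family_size(self, default_genome):
        g, _ = default_genome
        usage = codon_usage(g)
        for aa, family in CODON_FAMILIES.items():
            total = sum(usage.counts.get(c, 0) for c in family)
            if total:
                assert sum(usage.rscu[c] for c in family) == \
                    pytest.approx(len(family), abs=1e-9)

    def test_amino_acid_percentages_sum_to_100(self, default_genome):
        g, _ = default_genome
        usage = codon_usage(g)
        assert sum(usage.aa_percent.values()) == pytest.approx(100.0, abs=0.1)

    def test_internal_stop_warned(self):
        g = self._genome_from_codons(["AAA", "TAA", "AAA"])
        usage = codon_usage(g)
        assert any("internal stop" in w for w in usage.warnings)

    def test_met_family_merges_ata_and_atg(self):
        assert set(CODON_FAMILIES["M"]) == {"ATA", "ATG"}
        assert set(CODON_FAMILIES["L"]) == {"TTA", "TTG", "CTT", "CTC",
                                            "CTA", "CTG"}
        assert len(CODON_FAMILIES["S"]) == 8   # AGN serine under table 5


class TestNcrHomology:
    def test_exact_substring_scores_100(self, default_genome):
        g, _ = default_genome
        nd1 = g.get("ND1")
        piece = g.feature_seq(nd1)[100:200]
        seq = g.sequence + piece
        feats = list(g.features) + [
            GeneFeature("NCR", "noncoding", "J", len(g.sequence),
                        len(g.sequence) + 100)]
        g2 = AnnotatedMitogenome(g.id, seq, True, feats)
        hits = ncr_homology_scan(g2, g2.features[-1], candidates=["ND1"])
        assert hits and hits[0].gene == "ND1"
        assert hits[0].identity == pytest.approx(100.0)

    def test_randomized_quarter_matches_uniform_mismatch_expectation(
            self, default_genome):
        # randomising 25% of positions uniformly leaves ~81.25% identity
        g, _ = default_genome
        donor = g.feature_seq(g.get("ND1"))
        rng = np.random.default_rng(17)
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        identities = []
        for _ in range(200):
            start = int(rng.integers(0, len(donor) - 120))
            frag = np.frombuffer(donor[start:start + 120].encode(),
                                 dtype=np.uint8).copy()
            mask = rng.random(len(frag)) < 0.25
            frag[mask] = bases[rng.integers(0, 4, mask.sum())]
            seq = g.sequence + frag.tobytes().decode()
            feats = list(g.features) + [
                GeneFeature("NCR", "noncoding", "J", len(g.sequence),
                            len(g.sequence) + 120)]
            g2 = AnnotatedMitogenome(g.id, seq, True, feats)
            hits = ncr_homology_scan(g2, g2.features[-1], candidates=["ND1"])
            assert hits, "degraded copy must still be found"
            identities.append(hits[0].identity)
        assert np.mean(identities) == pytest.approx(81.25, abs=4.0)

    def test_short_ncr_rejected(self, default_genome):
        g, _ = default_genome
        short = GeneFeature("NCR", "noncoding", "J", 0, 20)
        with pytest.raises(ValueError, match="30"):
            ncr_homology_scan(g, short)

    def test_no_hit_below_identity_floor_returns_empty(self, default_genome):
        g, _ = default_genome
        # a foreign random sequence should not pass the 55% identity floor
        rng = np.random.default_rng(3)
        alien = "".join(rng.choice(list("ACGT"), 200))
        seq = g.sequence + alien
        feats = list(g.features) + [
            GeneFeature("NCR", "noncoding", "J", len(g.sequence),
                        len(g.sequence) + 200)]
        g2 = AnnotatedMitogenome(g.id, seq, True, feats)
        hits = ncr_homology_scan(g2, g2.features[-1], candidates=["ND1"],
                                 identity_floor=75.0)
        assert hits == []


def test_rscu_identity_on_random_count_tables():
    rng = np.random.default_rng(5)
    for _ in range(300):
        counts = {c: int(rng.integers(0, 50))
                  for fam in CODON_FAMILIES.values() for c in fam}
        rscu = rscu_from_counts(counts)
        for aa, family in CODON_FAMILIES.items():
            total = sum(counts[c] for c in family)
            expected = len(family) if total else 0.0
            assert sum(rscu[c] for c in family) == pytest.approx(
                expected, abs=1e-9)
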