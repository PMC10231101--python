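"""Descriptive genomics: base composition, strand skews, gene junctions,
codon classification, codon usage (RSCU) and non-coding-region homology.

Strand-asymmetry statistics follow the standard definitions

    AT-skew = (A - T) / (A + T)        GC-skew = (G - C) / (G + C)

computed on the given strand with ``N`` bases ignored.  Codon statistics use
the invertebrate mitochondrial genetic code (NCBI translation table 5), under
which AUA codes for Met and AGR for Ser.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import pandas as pd
from Bio.Align import PairwiseAligner
from Bio.Data import CodonTable
from Bio.Seq import reverse_complement

from .model import AnnotatedMitogenome, GeneFeature

INVERTEBRATE_MITO_TABLE = CodonTable.unambiguous_dna_by_id[5]

#: synonymous codon families of translation table 5, amino acid -> codons
CODON_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in ("".join(p) for p in product("TCAG", repeat=3)):
    if _codon in INVERTEBRATE_MITO_TABLE.stop_codons:
        continue
    _aa = INVERTEBRATE_MITO_TABLE.forward_table[_codon]
    CODON_FAMILIES.setdefault(_aa, ())
    CODON_FAMILIES[_aa] += (_codon,)

START_CODON_PATTERNS = ("ATA", "ATT", "ATC", "ATG", "GTG", "TTG")
COMPLETE_STOPS = ("TAA", "TAG")

#: a trailing T/TA counts as an incomplete stop only if the next feature
#: starts within this many bases (polyadenylation completes the codon)
INCOMPLETE_STOP_MAX_GAP = 2


@dataclass
class CompositionStats:
    """Length, base percentages and strand skews of one sequence or pool."""

    length: int
    pct_AT: float
    pct_each_base: dict[str, float]
    at_skew: float | None       # None when A+T == 0
    gc_skew: float | None       # None when G+C == 0

    @property
    def at_skew_rounded(self) -> float | None:
        return None if self.at_skew is None else round(self.at_skew, 3)

    @property
    def gc_skew_rounded(self) -> float | None:
        return None if self.gc_skew is None else round(self.gc_skew, 3)

    @property
    def pct_AT_rounded(self) -> float:
        return round(self.pct_AT, 1)

    def to_json(self) -> dict:
        return {
            "length": self.length,
            "pct_AT": self.pct_AT_rounded,
            "pct_each_base": {b: round(v, 1)
                              for b, v in self.pct_each_base.items()},
            "at_skew": self.at_skew_rounded,
            "gc_skew": self.gc_skew_rounded,
        }


def composition_stats(seq: str) -> CompositionStats:
    """Base composition and skews of a DNA sequence (N ignored in skews)."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequence contains no A/C/G/T bases")
    a, c, g, t = counts["A"], counts["C"], counts["G"], counts["T"]
    return CompositionStats(
        length=len(seq),
        pct_AT=100.0 * (a + t) / total,
        pct_each_base={b: 100.0 * counts[b] / total for b in "ACGT"},
        at_skew=(a - t) / (a + t) if a + t else None,
        gc_skew=(g - c) / (g + c) if g + c else None,
    )


# ---------------------------------------------------------------------------
# Per-class strand-aware composition
# ---------------------------------------------------------------------------

def strandwise_stats(genome: AnnotatedMitogenome,
                     features: Sequence[GeneFeature] | None = None,
                     ) -> dict[str, CompositionStats]:
    """Pooled composition per gene class, on each feature's coding strand.

    Classes: ``J-PCG``, ``N-PCG``, ``rRNA``, ``tRNA``, ``CR``.  When an
    explicit feature subset is given, a single pooled entry ``subset`` is
    returned instead.
    """
    if features is not None:
        if len(features) == 0:
            raise ValueError("empty feature subset")
        pooled = "".join(genome.feature_seq(f) for f in features)
        return {"subset": composition_stats(pooled)}

    classes: dict[str, list[str]] = {
        "J-PCG": [], "N-PCG": [], "rRNA": [], "tRNA": [], "CR": []}
    for f in genome.features:
        if f.kind == "PCG":
            classes[f"{f.strand}-PCG"].append(genome.feature_seq(f))
        elif f.kind == "rRNA":
            classes["rRNA"].append(genome.feature_seq(f))
        elif f.kind == "tRNA":
            classes["tRNA"].append(genome.feature_seq(f))
        elif f.kind == "control":
            classes["CR"].append(genome.feature_seq(f))
    return {name: composition_stats("".join(seqs))
            for name, seqs in classes.items() if seqs}


# ---------------------------------------------------------------------------
# Junction accounting
# ---------------------------------------------------------------------------

def gene_junctions(genome: AnnotatedMitogenome) -> pd.DataFrame:
    """Signed gap between each adjacent feature pair on the circle.

    Negative ``gap_bp`` means overlap, and ``overlap_seq`` carries the shared
    physical sequence.  The signed gaps close the circle:
    sum(feature lengths) + sum(gaps) == genome length.
    """
    feats = genome.features
    if len(feats) < 2:
        raise ValueError("need at least two features to form junctions")
    n = len(genome.sequence)
    for a in feats:
        for b in feats:
            if a is not b and a.start <= b.start and b.end <= a.end:
                raise ValueError(f"nested features: {b.name} inside {a.name}")
    rows = []
    for i, f in enumerate(feats):
        nxt = feats[(i + 1) % len(feats)]
        if i + 1 < len(feats):
            gap = nxt.start - f.end
        else:
            gap = nxt.start + n - f.end
        overlap_seq = ""
        if gap < 0:
            overlap_seq = genome.region(nxt.start % n, nxt.start % n - gap)
        rows.append({"upstream": f.name, "downstream": nxt.name,
                     "gap_bp": gap, "overlap_seq": overlap_seq})
    return pd.DataFrame(rows, columns=["upstream", "downstream",
                                       "gap_bp", "overlap_seq"])


# ---------------------------------------------------------------------------
# Codon classification and usage
# ---------------------------------------------------------------------------

def _downstream_gap(genome: AnnotatedMitogenome, feature: GeneFeature) -> int:
    """Distance to the next feature in the feature's transcription direction."""
    n = len(genome.sequence)
    best = n
    for other in genome.features:
        if other is feature:
            continue
        if feature.strand == "J":
            d = (other.start - feature.end) % n
        else:
            d = (feature.start - other.end) % n
        best = min(best, d)
    return best


def classify_codons(genome: AnnotatedMitogenome) -> pd.DataFrame:
    """Start/stop codon call for every protein-coding gene.

    Start codons ATN, GTG and TTG are standard.  A complete stop is a
    terminal TAA/TAG; when the gene length is not a codon multiple, a
    trailing T or TA abutting the next gene (within 2 bp) is an incomplete
    stop completed by polyadenylation.
    """
    rows = []
    for f in genome.features:
        if f.kind != "PCG":
            continue
        seq = genome.feature_seq(f)
        if len(seq) < 6:
            raise ValueError(f"PCG {f.name} shorter than 6 bp")
        start = seq[:3]
        start_standard = start in START_CODON_PATTERNS
        remainder = len(seq) % 3
        stop, complete = "", False
        if remainder == 0:
            stop = seq[-3:]
            complete = stop in COMPLETE_STOPS
        else:
            tail = seq[-remainder:]
            if tail in ("T", "TA") and \
                    _downstream_gap(genome, f) <= INCOMPLETE_STOP_MAX_GAP:
                stop, complete = tail, False
        rows.append({"gene": f.name, "strand": f.strand,
                     "length": len(seq), "start_codon": start,
                     "start_standard": start_standard, "stop_codon": stop,
                     "stop_complete": complete,
                     "stop_incomplete": stop in ("T", "TA")})
    return pd.DataFrame(rows)


@dataclass
class CodonUsageTable:
    """Codon counts, RSCU and amino-acid usage pooled over the 13 PCGs."""

    counts: dict[str, int]
    rscu: dict[str, float]
    aa_percent: dict[str, float]
    per_gene: pd.DataFrame           # start/stop classification
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for aa, codons in sorted(CODON_FAMILIES.items()):
            for codon in codons:
                rows.append({"codon": codon, "amino_acid": aa,
                             "count": self.counts.get(codon, 0),
                             "rscu": round(self.rscu.get(codon, 0.0), 3)})
        return pd.DataFrame(rows)


def rscu_from_counts(counts: dict[str, int]) -> dict[str, float]:
    """RSCU per codon: count x family size / family total, families being
    the synonymous codon sets of the invertebrate mitochondrial code."""
    rscu: dict[str, float] = {}
    for family in CODON_FAMILIES.values():
        total = sum(counts.get(c, 0) for c in family)
        for c in family:
            rscu[c] = (counts.get(c, 0) * len(family) / total) if total else 0.0
    return rscu


def codon_usage(genome: AnnotatedMitogenome) -> CodonUsageTable:
    """Codon usage over complete codons of all PCGs on their coding strands.

    RSCU for codon c in a synonymous family F is
    ``count(c) * |F| / sum(count(F))``; terminal stop codons and incomplete
    trailing bases are excluded from the counts, and stop codons never enter
    the amino-acid percentages.
    """
    per_gene = classify_codons(genome)
    counts: dict[str, int] = {}
    warns: list[str] = []
    for f in genome.features:
        if f.kind != "PCG":
            continue
        seq = genome.feature_seq(f)
        usable = len(seq) - len(seq) % 3
        codons = [seq[i:i + 3] for i in range(0, usable, 3)]
        if codons and codons[-1] in INVERTEBRATE_MITO_TABLE.stop_codons:
            codons = codons[:-1]
        for pos, codon in enumerate(codons):
            if "N" in codon:
                continue
            if codon in INVERTEBRATE_MITO_TABLE.stop_codons:
                warns.append(f"internal stop {codon} in {f.name} "
                             f"at codon {pos + 1}")
            counts[codon] = counts.get(codon, 0) + 1

    rscu = rscu_from_counts(counts)
    aa_counts = {aa: sum(counts.get(c, 0) for c in family)
                 for aa, family in CODON_FAMILIES.items()}
    aa_total = sum(aa_counts.values())
    aa_percent = {aa: 100.0 * v / aa_total for aa, v in aa_counts.items()} \
        if aa_total else {}
    return CodonUsageTable(counts, rscu, aa_percent, per_gene, warns)


# ---------------------------------------------------------------------------
# NCR homology
# ---------------------------------------------------------------------------

#: fixed local-alignment scoring so reported identities are reproducible
ALIGN_SCORING = {"match_score": 1, "mismatch_score": -1,
                 "open_gap_score": -2, "extend_gap_score": -1}
IDENTITY_FLOOR = 55.0


@dataclass
class HomologyHit:
    gene: str
    identity: float          # percent of alignment columns matching
    span: tuple[int, int]    # aligned span within the NCR
    strand: str              # strand of the candidate gene that matched
    score: float


def ncr_homology_scan(genome: AnnotatedMitogenome, ncr: GeneFeature,
                      candidates: Sequence[str] | None = None,
                      identity_floor: float = IDENTITY_FLOOR,
                      ) -> list[HomologyHit]:
    """Rank candidate genes by best local alignment against an NCR.

    Both strands of each candidate are scanned; identity is matches divided
    by alignment columns (gaps included).  Hits below ``identity_floor``
    percent are dropped; the result may be empty.
    """
    if ncr.length < 30:
        raise ValueError("NCR shorter than 30 bp")
    query = genome.feature_seq(ncr)
    if candidates is None:
        candidates = [f.name for f in genome.features
                      if f.kind in ("PCG", "rRNA")]
    aligner = PairwiseAligner(mode="local", **ALIGN_SCORING)
    hits: list[HomologyHit] = []
    for name in candidates:
        target = genome.feature_seq(genome.get(name))
        best: HomologyHit | None = None
        for strand, tseq in (("J", target), ("N", reverse_complement(target))):
            alns = aligner.align(query, tseq)
            if len(alns) == 0:
                continue
            aln = alns[0]
            counts = aln.counts()
            gaps, identities, mismatches = (counts.gaps, counts.identities,
                                            counts.mismatches)
            columns = gaps + identities + mismatches
            if columns == 0:
                continue
            identity = 100.0 * identities / columns
            span = (int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1]))
            hit = HomologyHit(name, identity, span, strand, aln.score)
            if best is None or hit.score > best.score:
                best = hit
        if best is not None and best.identity >= identity_floor:
            hits.append(best)
    hits.sort(key=lambda h: (-h.score, -h.identity, h.gene))
    return hits
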