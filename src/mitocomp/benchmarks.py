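"""Benchmark computations against deposited mitogenome records.

These functions recompute the headline descriptive statistics of a cohort of
real, annotated mitogenomes (GenBank flat files placed in a local directory
by the user; the package never downloads): genome length range, per-species
composition and skews, the universal tRNA junction overlaps, the longest
intergenic NCR and its homology to ND1, control-region lengths and the
dominant control-region repeat unit, and the Met amino-acid usage bound.
"""

from __future__ import annotations

from pathlib import Path

from .composition import (codon_usage, composition_stats, gene_junctions,
                          ncr_homology_scan)
from .cr_repeats import find_tandem_repeats
from .io import read_genbank
from .model import AnnotatedMitogenome


def load_deposited(directory: str | Path) -> list[AnnotatedMitogenome]:
    """Read every GenBank record (*.gb, *.gbk) in a directory."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.gb")) + sorted(directory.glob("*.gbk"))
    if not paths:
        raise FileNotFoundError(
            f"no GenBank records under {directory}; deposited mitogenomes "
            "must be fetched once and saved there by the user")
    return [read_genbank(p) for p in paths]


def compute_benchmarks(genomes: list[AnnotatedMitogenome]) -> dict:
    """Cohort-level benchmark quantities from annotated records."""
    out: dict = {"n_genomes": len(genomes)}
    lengths = [len(g.sequence) for g in genomes]
    out["length_min"], out["length_max"] = min(lengths), max(lengths)

    per_species = {}
    for g in genomes:
        stats = composition_stats(g.sequence)
        per_species[g.id] = {"pct_AT": stats.pct_AT_rounded,
                             "at_skew": stats.at_skew_rounded,
                             "gc_skew": stats.gc_skew_rounded}
    out["per_species"] = per_species
    out["at_skew_min"] = min(v["at_skew"] for v in per_species.values())
    out["at_skew_max"] = max(v["at_skew"] for v in per_species.values())

    # universal junction overlaps (trnW/trnC and ATP8/ATP6)
    wc, aa = set(), set()
    for g in genomes:
        table = gene_junctions(g)
        for row in table.itertuples():
            if (row.upstream, row.downstream) == ("trnW", "trnC"):
                wc.add(row.overlap_seq)
            if (row.upstream, row.downstream) == ("ATP8", "ATP6"):
                aa.add(row.overlap_seq)
    out["trnW_trnC_overlap"] = sorted(wc)
    out["ATP8_ATP6_overlap"] = sorted(aa)

    # longest trnS2/ND1 spacer and its homology
    best_ncr = None
    for g in genomes:
        table = gene_junctions(g)
        for row in table.itertuples():
            if (row.upstream, row.downstream) == ("trnS2", "ND1") \
                    and row.gap_bp > 0:
                if best_ncr is None or row.gap_bp > best_ncr[1]:
                    best_ncr = (g, row.gap_bp)
    if best_ncr:
        g, gap = best_ncr
        out["trnS2_ND1_spacer_bp"] = int(gap)
        ncr_feats = [f for f in g.features
                     if f.kind == "noncoding" and f.length >= 30]
        if ncr_feats:
            hits = ncr_homology_scan(g, ncr_feats[0])
            if hits:
                out["ncr_top_hit"] = {"gene": hits[0].gene,
                                      "identity": round(hits[0].identity, 2)}

    # control regions: lengths and dominant repeat unit
    crs = {}
    for g in genomes:
        segs = [f for f in g.features if f.kind == "control"]
        if not segs:
            continue
        total = sum(f.length for f in segs)
        arrays = []
        for f in segs:
            try:
                arrays += find_tandem_repeats(g.feature_seq(f))
            except ValueError:
                pass
        dominant = max(arrays, key=lambda a: a.score, default=None)
        crs[g.id] = {
            "segments": {f.name: f.length for f in segs},
            "total_length": total,
            "dominant_repeat": (
                {"unit_length": dominant.unit_length,
                 "copies": dominant.copies_int} if dominant else None),
        }
    out["control_regions"] = crs

    # Met usage across the cohort
    met = {}
    for g in genomes:
        usage = codon_usage(g)
        met[g.id] = round(usage.aa_percent.get("M", 0.0), 2)
    out["met_percent"] = met
    out["met_percent_min"] = min(met.values()) if met else None
    return out
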