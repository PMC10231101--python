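"""Per-genome and cross-genome analysis orchestration.

``run_pipeline`` executes every stage (validation, composition, junctions,
codon usage, gene order, mechanism call, control-region repeats) for each
input genome, quarantines genomes that fail, and summarises across the
successes.  Reports are JSON-first; all numbers come from the stage modules.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .composition import (codon_usage, composition_stats, gene_junctions,
                          ncr_homology_scan, strandwise_stats)
from .cr_repeats import cr_schematic
from .gene_order import ancestral_order, compare_orders, extract_gene_order
from .io import read_genome, validate_annotation
from .model import AnnotatedMitogenome
from .rearrange import classify_mechanism


@dataclass
class RunReport:
    """Machine-readable outcome of one pipeline run."""

    genomes: dict[str, dict] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures and bool(self.genomes)

    def to_json(self) -> dict:
        return {"genomes": self.genomes, "summary": self.summary,
                "provenance": self.provenance, "failures": self.failures}

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=2)


def analyze_genome(genome: AnnotatedMitogenome,
                   max_events: int = 2) -> dict:
    """All per-genome analysis stages, as one JSON-ready section."""
    section: dict = {"id": genome.id, "length": len(genome.sequence)}
    validation = validate_annotation(genome)
    section["validation"] = {"ok": validation.ok,
                             "issues": validation.to_json()}

    section["composition"] = {
        "genome": composition_stats(genome.sequence).to_json(),
        "by_class": {name: st.to_json()
                     for name, st in strandwise_stats(genome).items()},
    }

    junctions = gene_junctions(genome)
    section["junctions"] = junctions.to_dict(orient="records")

    usage = codon_usage(genome)
    rscu_max = max(usage.rscu, key=usage.rscu.get) if usage.rscu else None
    section["codon_usage"] = {
        "per_gene": usage.per_gene.to_dict(orient="records"),
        "rscu_argmax": rscu_max,
        "rscu": {c: round(v, 3) for c, v in sorted(usage.rscu.items())},
        "aa_percent": {a: round(v, 2)
                       for a, v in sorted(usage.aa_percent.items())},
        "warnings": usage.warnings,
    }

    if validation.ok:
        observed = extract_gene_order(genome)
        reference = ancestral_order()
        report = compare_orders(observed, reference)
        call = classify_mechanism(report, observed, reference,
                                  max_events=max_events)
        section["gene_order"] = observed.to_line()
        section["rearrangement"] = report.to_json()
        section["mechanism"] = call.to_json()
    else:
        section["gene_order"] = None
        section["rearrangement"] = {"skipped": "validation errors"}
        section["mechanism"] = {"skipped": "validation errors"}

    try:
        section["cr_repeats"] = cr_schematic(genome).to_json()
    except ValueError as exc:
        section["cr_repeats"] = {"skipped": str(exc)}

    ncrs = [f for f in genome.features
            if f.kind == "noncoding" and f.length >= 30]
    hits = []
    for ncr in ncrs:
        best = ncr_homology_scan(genome, ncr)
        hits.append({
            "ncr_start": ncr.start, "ncr_length": ncr.length,
            "top_hit": ({"gene": best[0].gene,
                         "identity": round(best[0].identity, 2),
                         "strand": best[0].strand} if best else None)})
    section["ncr_homology"] = hits
    return section


def shared_junction_motifs(junction_tables: dict[str, pd.DataFrame]) -> dict:
    """Overlap motifs identical across every genome at a named junction.

    For each junction present in all genomes, reports the shared overlap
    length/sequence, or "variable" when genomes disagree.
    """
    if len(junction_tables) < 2:
        raise ValueError("need junction tables from at least two genomes")
    keyed = {}
    for gid, table in junction_tables.items():
        keyed[gid] = {(r.upstream, r.downstream): (r.gap_bp, r.overlap_seq)
                      for r in table.itertuples()}
    common = set.intersection(*(set(d) for d in keyed.values()))
    out = {}
    for junction in sorted(common):
        values = {keyed[gid][junction] for gid in keyed}
        name = f"{junction[0]}/{junction[1]}"
        if len(values) == 1:
            gap, seq = next(iter(values))
            out[name] = {"gap_bp": int(gap), "overlap_seq": seq,
                         "overlap_len": len(seq)}
        else:
            out[name] = "variable"
    return out


def run_pipeline(inputs: list, config: dict | None = None) -> RunReport:
    """Analyse a set of genomes (paths or in-memory objects).

    A failure in one genome quarantines that genome and the run continues;
    the cross-genome summary covers the successes only.
    """
    if not inputs:
        raise ValueError("no inputs given")
    config = config or {}
    report = RunReport()
    checksums = {}
    genomes: list[AnnotatedMitogenome] = []
    for item in inputs:
        try:
            if isinstance(item, AnnotatedMitogenome):
                genome = item
                checksums[genome.id] = hashlib.sha256(
                    genome.sequence.encode()).hexdigest()[:16]
            else:
                genome = read_genome(item)
                checksums[genome.id] = hashlib.sha256(
                    Path(item).read_bytes()).hexdigest()[:16]
            genomes.append(genome)
        except Exception as exc:
            report.failures[str(item)] = f"read error: {exc}"

    for genome in genomes:
        try:
            report.genomes[genome.id] = analyze_genome(
                genome, max_events=int(config.get("max_events", 2)))
        except Exception as exc:
            report.failures[genome.id] = f"analysis error: {exc}"

    ok = report.genomes
    if ok:
        lengths = [sec["length"] for sec in ok.values()]
        at_skews = [sec["composition"]["genome"]["at_skew"]
                    for sec in ok.values()]
        gc_skews = [sec["composition"]["genome"]["gc_skew"]
                    for sec in ok.values()]
        mechanisms = {gid: sec["mechanism"].get("label")
                      for gid, sec in ok.items()}
        summary = {
            "n_genomes": len(ok),
            "length_range": [min(lengths), max(lengths)],
            "at_skew_range": [min(at_skews), max(at_skews)],
            "gc_skew_range": [min(gc_skews), max(gc_skews)],
            "mechanisms": mechanisms,
        }
        if len(ok) >= 2:
            tables = {gid: pd.DataFrame(sec["junctions"])
                      for gid, sec in ok.items()}
            summary["shared_junction_motifs"] = shared_junction_motifs(tables)
        report.summary = summary

    cfg_blob = json.dumps(config, sort_keys=True).encode()
    report.provenance = {
        "tool": "mitocomp", "version": __version__,
        "config_sha256": hashlib.sha256(cfg_blob).hexdigest()[:16],
        "input_sha256": checksums,
    }
    return report
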