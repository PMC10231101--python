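"""Reading, writing and validating annotated mitogenomes.

Supported formats:

* GenBank flat file (single DNA record) via Biopython — the interchange
  format for deposited mitogenomes.  Feature names are mapped onto the
  canonical 37-gene vocabulary on input; wraparound ``join(...)`` locations
  collapse into one feature with the ``end > length`` convention.
* FASTA plus a TSV feature table (columns: name, kind, strand, start, end;
  0-based half-open) for plain-text pipelines.

Validation checks the canonical gene complement and basic geometry; it never
raises, always returning a :class:`~mitocomp.model.ValidationReport`.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from . import vocab
from .model import AnnotatedMitogenome, GeneFeature, ValidationReport

_FEATURE_TYPES = {"CDS", "tRNA", "rRNA", "D-loop", "misc_feature", "gene"}

_PRODUCT_NAMES = {
    "COX1": "cytochrome c oxidase subunit I",
    "COX2": "cytochrome c oxidase subunit II",
    "COX3": "cytochrome c oxidase subunit III",
    "CYTB": "cytochrome b",
    "ND1": "NADH dehydrogenase subunit 1",
    "ND2": "NADH dehydrogenase subunit 2",
    "ND3": "NADH dehydrogenase subunit 3",
    "ND4": "NADH dehydrogenase subunit 4",
    "ND4L": "NADH dehydrogenase subunit 4L",
    "ND5": "NADH dehydrogenase subunit 5",
    "ND6": "NADH dehydrogenase subunit 6",
    "ATP6": "ATP synthase F0 subunit 6",
    "ATP8": "ATP synthase F0 subunit 8",
    "rrnS": "12S ribosomal RNA",
    "rrnL": "16S ribosomal RNA",
    "trnL1": "tRNA-Leu (CUN)",
    "trnL2": "tRNA-Leu (UUR)",
    "trnS1": "tRNA-Ser (AGN)",
    "trnS2": "tRNA-Ser (UCN)",
}
_AA1 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "K": "Lys", "M": "Met",
    "F": "Phe", "P": "Pro", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}


def _product_name(symbol: str) -> str:
    if symbol in _PRODUCT_NAMES:
        return _PRODUCT_NAMES[symbol]
    if symbol.startswith("trn"):
        return f"tRNA-{_AA1[symbol[3]]}"
    if symbol in ("CR", "CR1", "CR2"):
        return "control region" if symbol == "CR" else f"control region {symbol[-1]}"
    return symbol


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

def read_genbank(path: str | Path) -> AnnotatedMitogenome:
    """Parse a single-record GenBank flat file into an annotated mitogenome.

    Feature gene/product strings are mapped onto the canonical vocabulary;
    unmappable features are retained with kind ``noncoding`` and a warning is
    emitted.  Origin-spanning join locations become one feature with
    ``end > sequence length``.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises assorted parse errors
        raise ValueError(f"malformed GenBank record in {path}: {exc}") from exc
    if len(records) == 0:
        raise ValueError(f"{path}: no GenBank record found")
    if len(records) > 1:
        raise ValueError(
            f"{path}: {len(records)} records found; provide one record per file")
    rec = records[0]
    n = len(rec.seq)
    circular = rec.annotations.get("topology", "").lower() == "circular"

    features: list[GeneFeature] = []
    seen: set[tuple[str, int]] = set()
    for feat in rec.features:
        if feat.type not in _FEATURE_TYPES or feat.type == "gene":
            continue
        name = (feat.qualifiers.get("gene", [""])[0]
                or feat.qualifiers.get("product", [""])[0]
                or feat.qualifiers.get("note", [""])[0])
        note = " ".join(feat.qualifiers.get("product", [])
                        + feat.qualifiers.get("note", []))
        if feat.type == "D-loop" and not name:
            name = "control region"
        symbol = vocab.map_gene_name(name, note)
        if symbol is None:
            warnings.warn(f"{path.name}: unmapped feature {name!r} kept as NCR")
            symbol = vocab.NONCODING_MARKER
        start, end = _location_span(feat.location, n, circular)
        strand = "N" if (feat.location.strand or 1) < 0 else "J"
        if vocab.kind_of(symbol) in ("control", "noncoding"):
            strand = "J"
        key = (symbol, start)
        if key in seen:
            continue  # gene + CDS pair for the same locus
        seen.add(key)
        features.append(GeneFeature(symbol, vocab.kind_of(symbol),
                                    strand, start, end))
    return AnnotatedMitogenome(rec.id or path.stem, str(rec.seq),
                               circular, features)


def _location_span(location, n: int, circular: bool) -> tuple[int, int]:
    if isinstance(location, CompoundLocation) and circular:
        parts = sorted(location.parts, key=lambda p: int(p.start))
        first, last = parts[-1], parts[0]
        if len(parts) == 2 and int(first.end) == n and int(last.start) == 0:
            return int(first.start), n + int(last.end)
    return int(location.start), int(location.end)


def write_genbank(genome: AnnotatedMitogenome, path: str | Path) -> None:
    """Write a genome as a single-record GenBank flat file.

    Wraparound features are emitted as origin-spanning join locations.
    """
    n = len(genome.sequence)
    feats = []
    for f in genome.features:
        if f.end > 2 * n:
            raise ValueError(f"{f.name}: end beyond twice the sequence length")
        strand = -1 if f.strand == "N" else 1
        if f.wraps(n):
            loc = CompoundLocation([SimpleLocation(f.start, n, strand),
                                    SimpleLocation(0, f.end - n, strand)])
        else:
            loc = SimpleLocation(f.start, f.end, strand)
        ftype = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                 "control": "D-loop", "noncoding": "misc_feature"}[f.kind]
        quals = {"gene": [f.name], "product": [_product_name(f.name)]}
        if f.kind in ("control", "noncoding"):
            quals = {"gene": [f.name], "note": [_product_name(f.name)]}
        feats.append(SeqFeature(loc, type=ftype, qualifiers=quals))
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16],
                    description="mitochondrial genome",
                    annotations={
                        "molecule_type": "DNA",
                        "topology": "circular" if genome.circular else "linear",
                        "organism": genome.id,
                    },
                    features=feats)
    SeqIO.write([rec], str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA + TSV feature table
# ---------------------------------------------------------------------------

def read_fasta_tsv(fasta_path: str | Path, tsv_path: str | Path,
                   circular: bool = True) -> AnnotatedMitogenome:
    """Read a sequence-only FASTA paired with a TSV feature table."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{fasta_path}: expected exactly one FASTA record")
    rec = records[0]
    features = []
    with open(tsv_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            features.append(GeneFeature(row["name"], row["kind"], row["strand"],
                                        int(row["start"]), int(row["end"])))
    return AnnotatedMitogenome(rec.id, str(rec.seq), circular, features)


def write_fasta_tsv(genome: AnnotatedMitogenome, fasta_path: str | Path,
                    tsv_path: str | Path) -> None:
    SeqIO.write([SeqRecord(Seq(genome.sequence), id=genome.id, description="")],
                str(fasta_path), "fasta")
    with open(tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["name", "kind", "strand", "start", "end"])
        for f in genome.features:
            writer.writerow([f.name, f.kind, f.strand, f.start, f.end])


def read_genome(path: str | Path) -> AnnotatedMitogenome:
    """Dispatch on extension: .gb/.gbk/.genbank or .fasta/.fa (+ sibling .tsv)."""
    path = Path(path)
    if path.suffix.lower() in (".gb", ".gbk", ".genbank"):
        return read_genbank(path)
    if path.suffix.lower() in (".fa", ".fasta", ".fna"):
        tsv = path.with_suffix(".tsv")
        if not tsv.exists():
            raise FileNotFoundError(f"feature table {tsv} not found")
        return read_fasta_tsv(path, tsv)
    raise ValueError(f"unrecognised genome file extension: {path}")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

#: same-strand protein-coding genes may overlap by at most this many bases
MAX_PCG_OVERLAP = 50
#: intergenic spacers at least this long are flagged as non-coding regions
NCR_WARN_LENGTH = 50


def validate_annotation(genome: AnnotatedMitogenome) -> ValidationReport:
    """Structural checks: gene complement, geometry, overlaps, spacers.

    Errors: missing or duplicated canonical genes (a split control region,
    CR1 + CR2, is a warning, not an error), same-strand PCG overlaps longer
    than 50 bp, features outside the sequence.  Warnings: intergenic spacers
    of at least 50 bp, unannotated NCR features, split control region.
    """
    report = ValidationReport()
    n = len(genome.sequence)

    counts: dict[str, int] = {}
    for f in genome.features:
        counts[f.name] = counts.get(f.name, 0) + 1
    for gene in vocab.CANONICAL_GENES:
        if counts.get(gene, 0) == 0:
            report.add("error", "missing-gene", f"missing gene {gene}", gene)
        elif counts[gene] > 1:
            report.add("error", "duplicate-gene",
                       f"gene {gene} annotated {counts[gene]} times", gene)
    cr_count = sum(counts.get(m, 0) for m in vocab.CONTROL_MARKERS)
    if cr_count == 0:
        report.add("warning", "no-control-region", "no control region annotated")
    elif cr_count > 1:
        report.add("warning", "split-control-region",
                   "split control region (multiple CR segments)", "CR")

    for f in genome.features:
        if f.start >= n or f.end > 2 * n or f.length > n:
            report.add("error", "feature-out-of-bounds",
                       f"{f.name} [{f.start}, {f.end}) outside sequence of "
                       f"length {n}", f.name)
        if f.wraps(n) and not genome.circular:
            report.add("error", "wraparound-on-linear",
                       f"{f.name} wraps the origin of a linear genome", f.name)
        if f.kind == "noncoding" and f.length >= NCR_WARN_LENGTH:
            report.add("warning", "long-ncr",
                       f"non-coding region {f.name} of {f.length} bp", f.name)

    pcgs = [f for f in genome.features if f.kind == "PCG"]
    for a, b in zip(pcgs, pcgs[1:]):
        if a.strand == b.strand and b.start < a.end:
            overlap = a.end - b.start
            if overlap > MAX_PCG_OVERLAP:
                report.add("error", "pcg-overlap",
                           f"{a.name} and {b.name} overlap by {overlap} bp",
                           f"{a.name}/{b.name}")

    feats = genome.features
    for i, f in enumerate(feats):
        nxt = feats[(i + 1) % len(feats)] if feats else None
        if nxt is None or nxt is f:
            break
        gap = (nxt.start - f.end) if i + 1 < len(feats) else (nxt.start + n - f.end)
        if gap >= NCR_WARN_LENGTH and nxt.kind != "control" and f.kind != "control":
            report.add("warning", "intergenic-spacer",
                       f"{gap} bp spacer between {f.name} and {nxt.name}",
                       f"{f.name}/{nxt.name}")
    return report
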