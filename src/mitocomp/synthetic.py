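"""Synthetic mitogenome generator with ground-truth manifests.

Generates annotated, AT-rich circular mitogenomes that carry the 37 canonical
genes in the ancestral insect order, optionally rearranged by configured
events (TDRL, inversion, translocation — applied through the same operations
the analysis modules use), with planted junction motifs, an optional
gene-derived non-coding region, and control-region tandem-repeat arrays of
known unit length, copy number and divergence.

The sequence model is i.i.d. with configurable A+T content and per-strand
skews; protein-coding genes are drawn codon-wise from non-stop codons with
enforced start and stop codons.  Each genome comes with a
:class:`SyntheticTruth` manifest; the same config reproduces sequence and
truth byte-identically.

Random draws consume a single seeded stream in a fixed order: gene sequences
(ancestral gene order), junction gap sizes, NCR mutation, control-region
content, then spacer bases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from itertools import product
from typing import Any

import numpy as np
import yaml
from Bio.Seq import reverse_complement

from . import vocab
from .composition import composition_stats
from .gene_order import SignedGeneOrder
from .model import AnnotatedMitogenome, GeneFeature
from .rearrange import TDRLEvent, apply_tdrl

# Default gene lengths (bp), sized to the ranges observed in stick-insect
# mitogenomes: tRNAs totalling ~1450 bp, rRNAs ~1285/~780 bp, COX1 the
# longest PCG.  COX1/COX2 default to an incomplete stop T (length = 3k+1).
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "ND2": 1023, "COX1": 1534, "COX2": 688, "ATP8": 159, "ATP6": 675,
    "COX3": 789, "ND3": 354, "ND5": 1722, "ND4": 1341, "ND4L": 291,
    "ND6": 522, "CYTB": 1137, "ND1": 939,
    "rrnL": 1285, "rrnS": 780,
    **{t: 66 for t in vocab.TRNAS},
}

DEFAULT_START_CODONS: dict[str, str] = {"ND1": "TTG"}
DEFAULT_START = "ATA"

STOP_CODONS = ("TAA", "TAG", "TGA")
_ALL_CODONS = ["".join(c) for c in product("ACGT", repeat=3)]
NONSTOP_CODONS = [c for c in _ALL_CODONS if c not in STOP_CODONS]

#: junction motifs planted by default, mirroring the universal overlaps of
#: stick-insect mitogenomes
ATP_OVERLAP_MOTIF = "ATAA"       # ATP8/ATP6, 4 bp
WC_OVERLAP_MOTIF = "AAGCCTTA"    # trnW/trnC, 8 bp


@dataclass
class GeneratorConfig:
    """Everything the generator needs; defaults emulate a typical record.

    ``events`` entries: ``{"type": "tdrl", "window": [...genes...],
    "retention": {gene: "first"|"second"}}``, ``{"type": "inversion",
    "gene": g}`` or ``{"type": "translocation", "gene": g,
    "destination": "CR" | {"after": token}}`` (destination "CR" splits the
    control region around the gene).  ``cr_arrays`` entries:
    ``{"unit_length": bp, "copies": int, "divergence": fraction,
    "segment": 1|2}``.  ``ncr`` (optional): ``{"after": gene, "length": bp,
    "source": gene, "identity": fraction}`` plants a degraded gene copy as a
    non-coding region.
    """

    seed: int = 0
    id: str = ""
    genome_length_target: int = 16_000
    at_content: float = 0.75
    at_skew: float = 0.20
    gc_skew: float = -0.19
    gene_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENE_LENGTHS))
    start_codons: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_START_CODONS))
    incomplete_stop_genes: tuple[str, ...] = ("COX1", "COX2")
    events: list[dict] = field(default_factory=list)
    cr_arrays: list[dict] = field(
        default_factory=lambda: [
            {"unit_length": 109, "copies": 5, "divergence": 0.02}])
    cr_split_fraction: float = 0.5
    split_cr: list[str] = field(default_factory=list)
    ncr: dict | None = None
    plant_junction_motifs: bool = True
    max_spacer: int = 5

    def __post_init__(self) -> None:
        if not 0.5 <= self.at_content <= 0.9:
            raise ValueError("at_content must be in [0.5, 0.9]")
        for spec in self.cr_arrays:
            if not 0 <= spec.get("divergence", 0.0) <= 0.2:
                raise ValueError("array divergence must be in [0, 0.2]")
        for g, L in self.gene_lengths.items():
            if g in vocab.PCGS:
                want = 1 if g in self.incomplete_stop_genes else 0
                if L % 3 != want:
                    raise ValueError(
                        f"{g}: length {L} incompatible with "
                        f"{'incomplete' if want else 'complete'} stop")
        if not self.id:
            self.id = f"synthetic-{self.seed}"

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Ground-truth manifest emitted with every generated genome."""

    seed: int
    genome_id: str
    length: int
    gene_order: str
    events: list[dict]
    arrays: list[dict]            # absolute and CR-relative coordinates
    ncr: dict | None
    composition: dict

    def to_json(self) -> dict:
        return asdict(self)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=2)


# ---------------------------------------------------------------------------
# Event application
# ---------------------------------------------------------------------------

def _apply_events(config: GeneratorConfig,
                  ) -> tuple[SignedGeneOrder, list[dict]]:
    order = SignedGeneOrder(vocab.ANCESTRAL_ORDER)
    resolved: list[dict] = []
    events = list(config.events) + [
        {"type": "translocation", "gene": g, "destination": "CR"}
        for g in config.split_cr]
    for ev in events:
        kind = ev["type"]
        toks = list(order.tokens)
        if kind == "tdrl":
            names = [t[0] for t in toks]
            idx = [names.index(g) for g in ev["window"]]
            i, j = min(idx), max(idx) + 1
            if sorted(idx) != list(range(i, j)):
                raise ValueError(f"TDRL window {ev['window']} not contiguous")
            retention = tuple((g, ev["retention"][g]) for g in ev["window"])
            event = TDRLEvent((i, j), retention, tuple(ev["window"]))
            order = apply_tdrl(order, event)
            resolved.append({"type": "tdrl", "window": list(ev["window"]),
                             "retention": dict(ev["retention"])})
        elif kind == "inversion":
            g = ev["gene"]
            toks = [(n, -s if n == g else s) for n, s in toks]
            order = SignedGeneOrder(tuple(toks))
            resolved.append({"type": "inversion", "gene": g})
        elif kind == "translocation":
            g = ev["gene"]
            tok = next(t for t in toks if t[0] == g)
            toks.remove(tok)
            dest = ev["destination"]
            if dest == "CR":
                cr_idx = next(i for i, t in enumerate(toks) if t[0] == "CR")
                toks[cr_idx:cr_idx + 1] = [("CR1", +1), tok, ("CR2", +1)]
            else:
                after = dest["after"]
                at = next(i for i, t in enumerate(toks) if t[0] == after)
                toks.insert(at + 1, tok)
            order = SignedGeneOrder(tuple(toks))
            resolved.append({"type": "translocation", "gene": g,
                             "destination": dest})
        else:
            raise ValueError(f"unknown event type {kind!r}")
    return order, resolved


# ---------------------------------------------------------------------------
# Sequence drawing
# ---------------------------------------------------------------------------

def _base_probs(config: GeneratorConfig) -> np.ndarray:
    at, gc = config.at_content, 1.0 - config.at_content
    return np.array([
        at / 2 * (1 + config.at_skew),       # A
        gc / 2 * (1 - config.gc_skew),       # C
        gc / 2 * (1 + config.gc_skew),       # G
        at / 2 * (1 - config.at_skew),       # T
    ])

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _draw_bases(rng: np.random.Generator, length: int,
                probs: np.ndarray) -> str:
    idx = rng.choice(4, size=length, p=probs)
    return _BASES[idx].tobytes().decode()


def _codon_weights(probs: np.ndarray) -> np.ndarray:
    base_p = dict(zip("ACGT", probs))
    w = np.array([base_p[c[0]] * base_p[c[1]] * base_p[c[2]]
                  for c in NONSTOP_CODONS])
    return w / w.sum()


def _draw_pcg(rng: np.random.Generator, length: int, start: str,
              incomplete: bool, weights: np.ndarray) -> str:
    stop = "T" if incomplete else "TAA"
    n_internal = (length - 3 - len(stop)) // 3
    idx = rng.choice(len(NONSTOP_CODONS), size=n_internal, p=weights)
    body = "".join(NONSTOP_CODONS[i] for i in idx)
    return start + body + stop


def _force_tail(seq: str, motif: str) -> str:
    """Overwrite the end of a coding sequence with a junction motif, keeping
    the reading frame free of premature stops."""
    out = seq[:-len(motif)] + motif
    for k in range(0, len(out) - 3, 3):
        if out[k:k + 3] in STOP_CODONS and k >= len(out) - len(motif) - 3:
            out = out[:k] + "GCA" + out[k + 3:]
    return out


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each position with probability ``rate`` to a different base."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hit:
        others = _BASES[_BASES != arr[i]]
        arr[i] = others[rng.integers(len(others))]
    return arr.tobytes().decode()


def _build_cr(rng: np.random.Generator, length: int, specs: list[dict],
              probs: np.ndarray) -> tuple[str, list[dict]]:
    """A control-region segment: unique spacers interleaved with repeat
    arrays; returns (sequence, array records with segment-relative coords)."""
    arrays = []
    array_seqs = []
    total_rep = 0
    for spec in specs:
        unit = _draw_bases(rng, spec["unit_length"], probs)
        copies = int(spec["copies"])
        div = float(spec.get("divergence", 0.0))
        seq = "".join(_mutate(rng, unit, div) for _ in range(copies))
        array_seqs.append(seq)
        total_rep += len(seq)
        arrays.append({"unit_length": spec["unit_length"], "copies": copies,
                       "divergence": div, "consensus": unit})
    n_spacers = len(specs) + 1
    total_spacer = length - total_rep
    if total_spacer < 0:
        raise ValueError(
            f"control-region budget {length} bp cannot hold {total_rep} bp "
            "of repeat arrays; increase genome_length_target")
    base = total_spacer // n_spacers
    spacer_lens = [base] * n_spacers
    spacer_lens[-1] += total_spacer - base * n_spacers
    parts, cursor = [], 0
    for k, seq in enumerate(array_seqs):
        sp = _draw_bases(rng, spacer_lens[k], probs)
        parts.append(sp)
        cursor += len(sp)
        arrays[k]["start"] = cursor
        arrays[k]["end"] = cursor + len(seq)
        parts.append(seq)
        cursor += len(seq)
    parts.append(_draw_bases(rng, spacer_lens[-1], probs))
    return "".join(parts), arrays


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------

def generate_mitogenome(config: GeneratorConfig,
                        ) -> tuple[AnnotatedMitogenome, SyntheticTruth]:
    """Build one annotated mitogenome plus its ground-truth manifest."""
    rng = np.random.default_rng(config.seed)
    probs = _base_probs(config)
    # N-strand genes are drawn with complement-mirrored probabilities so the
    # physical (J) strand carries the configured skews genome-wide
    probs_n = probs[[3, 2, 1, 0]]
    weights = _codon_weights(probs)
    weights_n = _codon_weights(probs_n)
    order, resolved_events = _apply_events(config)
    tokens = list(order.tokens)
    final_sign = {n: s for n, s in tokens}

    # 1. coding-strand gene sequences, drawn in ancestral gene order
    gene_seqs: dict[str, str] = {}
    for name, _sign in vocab.ANCESTRAL_ORDER:
        if name in vocab.CONTROL_MARKERS:
            continue
        minority = final_sign.get(name, _sign) < 0
        L = config.gene_lengths[name]
        if name in vocab.PCGS:
            start = config.start_codons.get(name, DEFAULT_START)
            gene_seqs[name] = _draw_pcg(
                rng, L, start, name in config.incomplete_stop_genes,
                weights_n if minority else weights)
        else:
            gene_seqs[name] = _draw_bases(rng, L,
                                          probs_n if minority else probs)
    # motif planting is only coherent on the ancestral-like strands
    plant_aa = (config.plant_junction_motifs
                and final_sign.get("ATP8", 1) > 0
                and final_sign.get("ATP6", 1) > 0)
    plant_wc = (config.plant_junction_motifs
                and final_sign.get("trnW", 1) > 0)
    if plant_aa:
        gene_seqs["ATP8"] = _force_tail(gene_seqs["ATP8"], ATP_OVERLAP_MOTIF)
        atp6 = gene_seqs["ATP6"]
        gene_seqs["ATP6"] = atp6[:3] + "A" + atp6[4:]   # share the ATAA motif
    if plant_wc:
        gene_seqs["trnW"] = gene_seqs["trnW"][:-8] + WC_OVERLAP_MOTIF
        if final_sign.get("trnC", -1) < 0:
            # trnC on the N strand: its coding 3' end is the reverse
            # complement of the physical overlap with trnW's tail
            gene_seqs["trnC"] = (gene_seqs["trnC"][:-8]
                                 + reverse_complement(WC_OVERLAP_MOTIF))
        else:
            gene_seqs["trnC"] = WC_OVERLAP_MOTIF + gene_seqs["trnC"][8:]

    # 2. junction gap sizes, in final token order
    gaps: list[int] = []
    for i, (name, _) in enumerate(tokens):
        nxt = tokens[(i + 1) % len(tokens)][0]
        if plant_aa and name == "ATP8" and nxt == "ATP6":
            gaps.append(-len(ATP_OVERLAP_MOTIF))
        elif plant_wc and name == "trnW" and nxt == "trnC":
            gaps.append(-len(WC_OVERLAP_MOTIF))
        elif name in config.incomplete_stop_genes:
            gaps.append(0)
        elif name in vocab.CONTROL_MARKERS or nxt in vocab.CONTROL_MARKERS:
            gaps.append(0)
        else:
            gaps.append(int(rng.integers(0, config.max_spacer + 1)))

    # 3. optional NCR: a degraded copy of a donor gene
    ncr_record = None
    ncr_seq = ""
    if config.ncr:
        spec = config.ncr
        donor = gene_seqs[spec["source"]]
        L = int(spec["length"])
        offset = int(rng.integers(0, len(donor) - L + 1))
        rate = 1.0 - float(spec["identity"])   # _mutate always changes a base
        ncr_seq = _mutate(rng, reverse_complement(donor[offset:offset + L]),
                          rate)
        ncr_record = {"after": spec["after"], "length": L,
                      "source": spec["source"],
                      "identity_target": spec["identity"]}

    # 4. control-region content sized to hit the genome length target
    fixed = sum(config.gene_lengths[n] for n, _ in tokens
                if n not in vocab.CONTROL_MARKERS)
    fixed += sum(gaps) + len(ncr_seq)
    cr_total = config.genome_length_target - fixed
    cr_names = [n for n, _ in tokens if n in vocab.CONTROL_MARKERS]
    if cr_total < 2 * len(cr_names) * 30:
        raise ValueError(
            f"gene lengths leave only {cr_total} bp for the control region; "
            "increase genome_length_target")
    cr_seqs: dict[str, str] = {}
    cr_arrays: dict[str, list[dict]] = {}
    if len(cr_names) == 1:
        specs = [s for s in config.cr_arrays]
        cr_seqs[cr_names[0]], cr_arrays[cr_names[0]] = _build_cr(
            rng, cr_total, specs, probs)
    else:
        budget1 = int(cr_total * config.cr_split_fraction)
        budgets = {"CR1": budget1, "CR2": cr_total - budget1}
        for seg_name in cr_names:
            seg_no = 1 if seg_name == "CR1" else 2
            specs = [s for s in config.cr_arrays
                     if s.get("segment", 2) == seg_no]
            cr_seqs[seg_name], cr_arrays[seg_name] = _build_cr(
                rng, budgets[seg_name], specs, probs)

    # 5. assembly
    chunks: list[str] = []
    features: list[GeneFeature] = []
    truth_arrays: list[dict] = []
    pos = 0
    for i, (name, sign) in enumerate(tokens):
        if name in vocab.CONTROL_MARKERS:
            phys = cr_seqs[name]
        else:
            coding = gene_seqs[name]
            phys = reverse_complement(coding) if sign < 0 else coding
        assembled = "".join(chunks)
        overlap = max(0, -((pos) - len(assembled))) if pos < len(assembled) else 0
        if overlap:
            if assembled[pos:] != phys[:overlap]:
                raise AssertionError(
                    f"inconsistent overlap at {name}: planted motifs disagree")
            chunks.append(phys[overlap:])
        else:
            chunks.append(phys)
        kind = vocab.kind_of(name)
        features.append(GeneFeature(name, kind, "N" if sign < 0 else "J",
                                    pos, pos + len(phys)))
        if name in vocab.CONTROL_MARKERS:
            for rec in cr_arrays[name]:
                truth_arrays.append(rec | {
                    "segment": name,
                    "genome_start": pos + rec["start"],
                    "genome_end": pos + rec["end"]})
        pos += len(phys)
        # NCR inserted right after its anchor gene
        if ncr_record and name == ncr_record["after"]:
            features.append(GeneFeature("NCR", "noncoding", "J",
                                        pos, pos + len(ncr_seq)))
            chunks.append(ncr_seq)
            pos += len(ncr_seq)
            ncr_record["genome_start"] = pos - len(ncr_seq)
            ncr_record["genome_end"] = pos
        gap = gaps[i]
        if gap > 0:
            chunks.append(_draw_bases(rng, gap, probs))
            pos += gap
        elif gap < 0:
            pos += gap   # next feature starts inside the current one

    sequence = "".join(chunks)
    genome = AnnotatedMitogenome(config.id, sequence, True, features)

    whole = composition_stats(sequence)
    cr_stats = {name: composition_stats(cr_seqs[name]).to_json()
                for name in cr_names}
    truth = SyntheticTruth(
        seed=config.seed, genome_id=config.id, length=len(sequence),
        gene_order=order.to_line(), events=resolved_events,
        arrays=truth_arrays, ncr=ncr_record,
        composition={"genome": whole.to_json(), "control_region": cr_stats},
    )
    return genome, truth


# ---------------------------------------------------------------------------
# Composition perturbation
# ---------------------------------------------------------------------------

def perturb_composition(genome: AnnotatedMitogenome, at_content: float,
                        seed: int = 0,
                        tolerance: float = 1.0) -> AnnotatedMitogenome:
    """Resample third codon positions and non-coding bases toward a target
    A+T content (percent points tolerance ``tolerance``), without touching
    annotations, start codons or stop codons."""
    if not 0.5 <= at_content <= 0.9:
        raise ValueError("at_content must be in [0.5, 0.9]")
    rng = np.random.default_rng(seed)
    seq = np.frombuffer(genome.sequence.encode(), dtype=np.uint8).copy()
    n = len(seq)

    covered = np.zeros(n, dtype=np.int8)
    for f in genome.features:
        idx = np.arange(f.start, f.end) % n
        covered[idx] += 1

    eligible: list[int] = []
    codon_ctx: dict[int, tuple[str, str]] = {}   # phys pos -> (strand, b1+b2)
    for f in genome.features:
        if f.kind == "PCG":
            coding = genome.feature_seq(f)
            L = f.length
            usable = L - L % 3
            for k in range(3, usable - 3, 3):      # skip start and stop codons
                third = k + 2
                phys = (f.start + third) % n if f.strand == "J" \
                    else (f.start + (L - 1 - third)) % n
                if covered[phys] == 1:
                    eligible.append(phys)
                    codon_ctx[phys] = (f.strand, coding[k:k + 2])
        elif f.kind in ("control", "noncoding"):
            for p in range(f.start, f.end):
                if covered[p % n] == 1:
                    eligible.append(p % n)
    eligible.extend(np.flatnonzero(covered == 0).tolist())
    eligible = np.array(sorted(set(eligible)), dtype=np.int64)

    is_at = np.isin(seq, np.frombuffer(b"AT", dtype=np.uint8))
    target = at_content * 100.0
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}

    def current() -> float:
        return 100.0 * is_at.sum() / n

    def makes_stop(phys: int, new_base: str) -> bool:
        ctx = codon_ctx.get(phys)
        if ctx is None:
            return False
        strand, head = ctx
        third = new_base if strand == "J" else comp[new_base]
        return head + third in STOP_CODONS

    rng.shuffle(eligible)
    at_pool = [p for p in eligible if is_at[p]]
    gc_pool = [p for p in eligible if not is_at[p]]
    while abs(current() - target) > tolerance / 2:
        need_at = current() < target
        pool = gc_pool if need_at else at_pool
        if not pool:
            raise ValueError("target A+T content unreachable under constraints")
        p = pool.pop()
        choices = "AT" if need_at else "GC"
        pick = choices[int(rng.integers(2))]
        if makes_stop(p, pick):
            pick = choices[1] if pick == choices[0] else choices[0]
            if makes_stop(p, pick):
                continue
        seq[p] = ord(pick)
        is_at[p] = need_at
    return AnnotatedMitogenome(genome.id, seq.tobytes().decode(),
                               genome.circular, list(genome.features))


# ---------------------------------------------------------------------------
# Study-condition cohort
# ---------------------------------------------------------------------------

def study_cohort_configs(seed: int = 0) -> list[GeneratorConfig]:
    """Nine generator configs emulating the structure of a stick-insect
    mitogenome cohort: lengths ~15-17.8 kb, A+T 74-79%, one trnA/trnR TDRL
    swap, one split control region with an inverted+translocated trnI, one
    gene-derived 198 bp NCR, and the observed variety of CR repeat arrays."""
    base = dict(at_skew=0.20, gc_skew=-0.19)
    specs: list[dict] = [
        dict(id="sim-tdrl-swap", genome_length_target=15_600, at_content=0.75,
             events=[{"type": "tdrl", "window": ["trnA", "trnR"],
                      "retention": {"trnA": "second", "trnR": "first"}}],
             cr_arrays=[{"unit_length": 98, "copies": 6, "divergence": 0.02},
                        {"unit_length": 21, "copies": 2, "divergence": 0.01}]),
        dict(id="sim-split-cr", genome_length_target=16_900, at_content=0.76,
             events=[{"type": "inversion", "gene": "trnI"},
                     {"type": "translocation", "gene": "trnI",
                      "destination": "CR"}],
             cr_split_fraction=0.53,
             cr_arrays=[{"unit_length": 109, "copies": 5, "divergence": 0.02,
                         "segment": 2}]),
        dict(id="sim-ncr", genome_length_target=16_100, at_content=0.74,
             ncr={"after": "trnS2", "length": 198, "source": "ND1",
                  "identity": 0.73},
             cr_arrays=[{"unit_length": 387, "copies": 2, "divergence": 0.02},
                        {"unit_length": 21, "copies": 3, "divergence": 0.01}]),
        dict(id="sim-two-arrays", genome_length_target=16_300,
             at_content=0.78,
             cr_arrays=[{"unit_length": 99, "copies": 4, "divergence": 0.03},
                        {"unit_length": 125, "copies": 7, "divergence": 0.02}]),
        dict(id="sim-long-cr", genome_length_target=17_200, at_content=0.77,
             cr_arrays=[{"unit_length": 209, "copies": 3, "divergence": 0.02},
                        {"unit_length": 210, "copies": 5, "divergence": 0.02},
                        {"unit_length": 50, "copies": 2, "divergence": 0.01}]),
        dict(id="sim-many-copies", genome_length_target=15_900,
             at_content=0.79,
             cr_arrays=[{"unit_length": 70, "copies": 12, "divergence": 0.02}]),
        dict(id="sim-three-arrays", genome_length_target=16_000,
             at_content=0.75,
             cr_arrays=[{"unit_length": 114, "copies": 3, "divergence": 0.02},
                        {"unit_length": 21, "copies": 4, "divergence": 0.01}]),
        dict(id="sim-mixed", genome_length_target=17_761, at_content=0.74,
             cr_arrays=[{"unit_length": 166, "copies": 5, "divergence": 0.02},
                        {"unit_length": 111, "copies": 7, "divergence": 0.02}]),
        dict(id="sim-plain", genome_length_target=15_011, at_content=0.79,
             cr_arrays=[]),
    ]
    return [GeneratorConfig(seed=seed + k, **base, **spec)
            for k, spec in enumerate(specs)]
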