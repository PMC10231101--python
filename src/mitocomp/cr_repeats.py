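"""Tandem-repeat detection and control-region schematics.

Control regions of insect mitogenomes commonly carry tandem-repeat arrays
(observed unit lengths roughly 8-700 bp, 2-50 copies, near-identical units).
Detection works from the distance spectrum of repeated 8-mers: each candidate
period is verified by aligning successive unit-sized frames to a column-wise
consensus, arrays are scored by copies x identity, and overlapping candidates
are resolved greedily.  The reported unit is always the primitive (smallest)
period explaining the array.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import AnnotatedMitogenome, GeneFeature

KMER = 8


@dataclass
class TandemRepeatArray:
    """A located repeat array: [start, end) within the scanned sequence."""

    start: int
    end: int
    unit_length: int
    copies: float               # span / unit_length
    consensus: str
    identity: float             # percent unit-vs-consensus matches

    @property
    def copies_int(self) -> int:
        """Nearest-integer copy number, the paper-style "N x L bp" count."""
        return int(round(self.copies))

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def score(self) -> float:
        return self.copies * self.identity

    def label(self) -> str:
        return f"{self.copies_int} x {self.unit_length} bp"

    def to_json(self) -> dict:
        return {"start": self.start, "end": self.end,
                "unit_length": self.unit_length,
                "copies": round(self.copies, 2), "copies_int": self.copies_int,
                "identity": round(self.identity, 1),
                "consensus": self.consensus}


def _candidate_periods(seq: str, min_unit: int, max_unit: int) -> list[int]:
    """Candidate periods from distances between repeated 8-mers.

    A distance below ``min_unit`` contributes its smallest multiple within
    bounds, so short exact periods are still found (and later reduced back to
    their primitive length)."""
    n = len(seq)
    last_pos: dict[str, int] = {}
    support: dict[int, int] = {}
    for i in range(n - KMER + 1):
        kmer = seq[i:i + KMER]
        prev = last_pos.get(kmer)
        if prev is not None:
            d = i - prev
            if d <= max_unit:
                if d < min_unit:
                    d = ((min_unit + d - 1) // d) * d
                if d <= max_unit:
                    support[d] = support.get(d, 0) + 1
        last_pos[kmer] = i
    ranked = sorted(support, key=lambda d: (-support[d], d))
    return ranked[:40]


def _consensus_identity(s: np.ndarray, start: int, n_units: int,
                        period: int) -> tuple[str, float]:
    frames = s[start:start + n_units * period].reshape(n_units, period)
    consensus = np.empty(period, dtype=frames.dtype)
    for base in (65, 67, 71, 84, 78):        # A C G T N; majority, A-first ties
        counts = (frames == base).sum(axis=0)
        if base == 65:
            best = counts
            consensus[:] = base
        else:
            win = counts > best
            consensus[win] = base
            best = np.maximum(best, counts)
    identity = float((frames == consensus).mean()) * 100.0
    return consensus.tobytes().decode(), identity


def _primitive_period(consensus: str, min_identity: float) -> int:
    """Smallest sub-period of the consensus that explains it at the identity
    floor; e.g. a 140 bp consensus of two near-identical halves reports 70."""
    p = len(consensus)
    arr = np.frombuffer(consensus.encode(), dtype=np.uint8)
    for d in range(2, p // 2 + 1):
        if p % d:
            continue
        units = arr.reshape(p // d, d)
        if float((units == units[0]).mean()) * 100.0 >= min_identity:
            return d
    return p


#: local scoring of the lag-match profile (match +2, mismatch -7, TRF-style);
#: a maximal segment must reach this score before a candidate array is built
MIN_SEGMENT_SCORE = 24.0


def _max_scoring_segments(match: np.ndarray, min_score: float,
                          ) -> list[tuple[int, int]]:
    """Maximal positive excursions of the +2/-7 score walk over a boolean
    match profile; returns (start, end) index pairs, end inclusive."""
    w = np.where(match, 2.0, -7.0)
    cs = np.concatenate(([0.0], np.cumsum(w)))
    height = cs - np.minimum.accumulate(cs)
    zeros = np.flatnonzero(height == 0)
    segments: list[tuple[int, int]] = []
    bounds = list(zeros) + [len(height) - 1]
    for k in range(len(bounds) - 1):
        z0, z1 = bounds[k], bounds[k + 1]
        if z1 <= z0 + 1:
            continue
        chunk = height[z0:z1 + 1]
        peak = int(np.argmax(chunk))
        if chunk[peak] >= min_score:
            segments.append((z0, z0 + peak - 1))
    return segments


def find_tandem_repeats(seq: str, min_unit: int = 8, max_unit: int = 700,
                        min_copies: int = 2, min_identity: float = 80.0,
                        circular: bool = False) -> list[TandemRepeatArray]:
    """Detect tandem-repeat arrays in a DNA sequence.

    Candidate periods come from the repeated-8-mer distance spectrum; each is
    extended along runs where the sequence matches itself at that period,
    then verified against a per-column consensus.  Arrays are kept when the
    unit-vs-consensus identity reaches ``min_identity`` percent and the copy
    number reaches ``min_copies``.  With ``circular=True`` the sequence is
    doubled once so origin-spanning arrays are caught; coordinates are then
    reported modulo the original length.
    """
    if not (2 <= min_unit <= max_unit):
        raise ValueError("need 2 <= min_unit <= max_unit")
    if min_copies < 2:
        raise ValueError("min_copies must be at least 2")
    if not 0 < min_identity <= 100:
        raise ValueError("min_identity must be in (0, 100]")
    seq = seq.upper()
    n0 = len(seq)
    if n0 < 2 * min_unit:
        raise ValueError(f"sequence shorter than 2 x min_unit ({2 * min_unit})")
    work = seq + seq if circular else seq
    s = np.frombuffer(work.encode(), dtype=np.uint8)
    n = len(s)
    max_unit = min(max_unit, n0 // 2)

    # gate for extending the array by one more unit copy: adjacent diverged
    # copies match pairwise at roughly (identity/100)^2
    unit_gate = max(0.6, (min_identity / 100.0) ** 2)

    candidates: list[TandemRepeatArray] = []
    for p in _candidate_periods(work, min_unit, max_unit):
        if n <= p:
            continue
        match = s[:-p] == s[p:]
        for a, e in _max_scoring_segments(match, MIN_SEGMENT_SCORE):
            # rough span [a, e+1+p); snap to unit tiling and extend outward
            start, end = int(a), int(e) + 1 + p
            while start - p >= 0 and \
                    float((s[start - p:start] == s[start:start + p]).mean()) \
                    >= unit_gate:
                start -= p
            while end + p <= n and \
                    float((s[end:end + p] == s[end - p:end]).mean()) \
                    >= unit_gate:
                end += p
            n_units = (end - start) // p
            if n_units < min_copies:
                continue
            end = start + n_units * p        # whole units only, for consensus
            consensus, identity = _consensus_identity(s, start, n_units, p)
            if identity < min_identity:
                continue
            unit = _primitive_period(consensus, min_identity)
            if unit != p:
                # re-extend at the primitive period, then rebuild consensus
                while start - unit >= 0 and \
                        float((s[start - unit:start]
                               == s[start:start + unit]).mean()) >= unit_gate:
                    start -= unit
                while end + unit <= n and \
                        float((s[end:end + unit]
                               == s[end - unit:end]).mean()) >= unit_gate:
                    end += unit
                n_units = (end - start) // unit
                end = start + n_units * unit
                consensus, identity = _consensus_identity(
                    s, start, n_units, unit)
                if identity < min_identity:
                    continue
            # fractional copies: partial unit matches at either boundary
            cons = np.frombuffer(consensus.encode(), dtype=np.uint8)
            best_d = 0
            for d in range(1, unit):
                if start - d < 0:
                    break
                frac = float((s[start - d:start] == cons[unit - d:]).mean())
                if frac >= min_identity / 100.0:
                    best_d = d
            start -= best_d
            tail_d = 0
            for d in range(1, unit):
                if end + d > n:
                    break
                frac = float((s[end:end + d] == cons[:d]).mean())
                if frac >= min_identity / 100.0:
                    tail_d = d
            end += tail_d
            copies = (end - start) / unit
            if copies < min_copies:
                continue
            candidates.append(TandemRepeatArray(
                int(start), int(end), unit, copies, consensus, identity))

    # greedy overlap resolution: best score first, ties smaller unit/leftmost
    candidates.sort(key=lambda c: (-c.score, c.unit_length, c.start))
    accepted: list[TandemRepeatArray] = []
    for cand in candidates:
        if circular and cand.start >= n0:
            continue
        if any(cand.start < acc.end and acc.start < cand.end
               for acc in accepted):
            continue
        accepted.append(cand)
    if circular:
        for arr in accepted:
            arr.end = min(arr.end, arr.start + n0)
            arr.copies = (arr.end - arr.start) / arr.unit_length
    accepted.sort(key=lambda c: c.start)
    return accepted


# ---------------------------------------------------------------------------
# Schematic
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    kind: str                   # "unique" | "repeat array" | "embedded gene"
    label: str
    span: tuple[int, int]       # absolute genome coordinates, half-open


@dataclass
class CRSchematic:
    """Tiling of the control region(s) into unique stretches, repeat arrays
    and embedded genes (for split control regions)."""

    genome_id: str
    segments: list[Segment] = field(default_factory=list)
    arrays: dict[str, list[TandemRepeatArray]] = field(default_factory=dict)

    def render_text(self) -> str:
        parts = []
        for seg in self.segments:
            length = seg.span[1] - seg.span[0]
            if seg.kind == "repeat array":
                parts.append(seg.label)
            elif seg.kind == "embedded gene":
                parts.append(f"[{seg.label}]")
            else:
                parts.append(f"{seg.label}({length} bp)")
        return " | ".join(parts)

    def plot(self, path: str) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(10, 1.8))
        colors = {"unique": "#d9d9d9", "repeat array": "#4c72b0",
                  "embedded gene": "#dd8452"}
        for seg in self.segments:
            x0, x1 = seg.span
            ax.barh(0, x1 - x0, left=x0, height=0.5,
                    color=colors[seg.kind], edgecolor="black", linewidth=0.5)
            if seg.kind != "unique":
                ax.text((x0 + x1) / 2, 0, seg.label, ha="center", va="center",
                        fontsize=7, rotation=0)
        ax.set_yticks([])
        ax.set_xlabel("genome position (bp)")
        ax.set_title(f"{self.genome_id} control region")
        fig.tight_layout()
        fig.savefig(path)
        plt.close(fig)

    def to_json(self) -> dict:
        return {
            "genome": self.genome_id,
            "segments": [{"kind": s.kind, "label": s.label,
                          "start": s.span[0], "end": s.span[1]}
                         for s in self.segments],
            "arrays": {name: [a.to_json() for a in arrs]
                       for name, arrs in self.arrays.items()},
        }


def cr_schematic(genome: AnnotatedMitogenome,
                 min_unit: int = 8, max_unit: int = 700,
                 min_copies: int = 2,
                 min_identity: float = 80.0) -> CRSchematic:
    """Lay out the control region(s): repeat arrays, unique segments and any
    genes embedded between split-CR segments."""
    controls = [f for f in genome.features if f.kind == "control"]
    if not controls:
        raise ValueError("genome has no control-region feature")
    controls.sort(key=lambda f: f.start)
    schematic = CRSchematic(genome.id)

    def tile_control(f: GeneFeature) -> None:
        seq = genome.feature_seq(f)
        try:
            arrays = find_tandem_repeats(seq, min_unit, max_unit,
                                         min_copies, min_identity)
        except ValueError:
            arrays = []
        schematic.arrays[f.name] = arrays
        cursor = 0
        for arr in arrays:
            if arr.start > cursor:
                schematic.segments.append(Segment(
                    "unique", f.name,
                    (f.start + cursor, f.start + arr.start)))
            schematic.segments.append(Segment(
                "repeat array", arr.label(),
                (f.start + arr.start, f.start + arr.end)))
            cursor = arr.end
        if cursor < f.length:
            schematic.segments.append(Segment(
                "unique", f.name, (f.start + cursor, f.start + f.length)))

    for i, f in enumerate(controls):
        tile_control(f)
        if i + 1 < len(controls):
            nxt = controls[i + 1]
            embedded = [g for g in genome.features
                        if g.kind not in ("control",)
                        and f.end <= g.start and g.end <= nxt.start]
            for g in sorted(embedded, key=lambda g: g.start):
                schematic.segments.append(Segment(
                    "embedded gene", g.name, (g.start, g.end)))
    return schematic
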