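"""Shared domain types: annotated mitogenomes and validation reports.

Coordinates are 0-based, half-open, on the linearised circle.  A feature that
spans the origin of a circular genome is encoded with ``end > len(sequence)``
("wraparound convention"); consumers normalise positions modulo the sequence
length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

from Bio.Seq import reverse_complement

from . import vocab

STRANDS = ("J", "N")


@dataclass
class GeneFeature:
    """A typed, stranded gene feature on the mitogenome circle.

    ``name`` is a canonical symbol (37-gene vocabulary, CR/CR1/CR2 markers,
    or NCR for unannotated non-coding features).  ``strand`` is "J" (majority,
    GenBank plus) or "N" (minority); control features carry "J" by convention.
    """

    name: str
    kind: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in vocab.KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be 'J' or 'N', got {self.strand!r}")
        if self.start < 0:
            raise ValueError(f"{self.name}: start must be >= 0")
        if self.end <= self.start:
            raise ValueError(f"{self.name}: end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start

    def wraps(self, seq_length: int) -> bool:
        return self.end > seq_length


@dataclass
class AnnotatedMitogenome:
    """A (usually circular) mitogenome sequence plus ordered gene features."""

    id: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if set(self.sequence) - set("ACGTN"):
            bad = sorted(set(self.sequence) - set("ACGTN"))
            raise ValueError(f"sequence contains non-ACGTN characters: {bad}")
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        seen = set()
        for f in self.features:
            key = (f.name, f.start)
            if key in seen:
                raise ValueError(f"duplicate feature {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.sequence)

    # -- sequence access ----------------------------------------------------

    def region(self, start: int, end: int) -> str:
        """Physical (J-strand) sequence of [start, end); wraparound allowed."""
        n = len(self.sequence)
        if end <= n:
            return self.sequence[start:end]
        if not self.circular:
            raise ValueError("wraparound region on a linear genome")
        if end - start > n:
            raise ValueError("region longer than the genome")
        return self.sequence[start:] + self.sequence[: end - n]

    def feature_seq(self, feature: GeneFeature) -> str:
        """Coding-strand sequence of a feature (reverse-complemented for N)."""
        s = self.region(feature.start % len(self.sequence),
                        feature.start % len(self.sequence) + feature.length)
        return reverse_complement(s) if feature.strand == "N" else s

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(f.name == name for f in self.features)

    def rotated(self, offset: int) -> "AnnotatedMitogenome":
        """Return the same circular genome linearised at a different origin."""
        if not self.circular:
            raise ValueError("cannot rotate a linear genome")
        n = len(self.sequence)
        offset %= n
        seq = self.sequence[offset:] + self.sequence[:offset]
        feats = [replace(f, start=(f.start - offset) % n,
                         end=(f.start - offset) % n + f.length)
                 for f in self.features]
        return AnnotatedMitogenome(self.id, seq, True, feats)


@dataclass(frozen=True)
class Issue:
    severity: str          # "error" | "warning"
    code: str
    message: str
    feature: str = "-"


@dataclass
class ValidationReport:
    """Outcome of the structural checks on an annotated mitogenome."""

    issues: list[Issue] = field(default_factory=list)

    @property
    def errors(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "warning"]

    @property
    def ok(self) -> bool:
        return not self.errors

    def __iter__(self) -> Iterator[Issue]:
        return iter(self.issues)

    def add(self, severity: str, code: str, message: str,
            feature: str = "-") -> None:
        self.issues.append(Issue(severity, code, message, feature))

    def to_json(self) -> list[dict]:
        return [i.__dict__ | {} for i in self.issues]


def features_by_kind(genome: AnnotatedMitogenome,
                     kinds: Iterable[str]) -> list[GeneFeature]:
    wanted = set(kinds)
    return [f for f in genome.features if f.kind in wanted]
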