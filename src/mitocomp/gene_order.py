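"""Circular signed gene orders and rearrangement detection.

A mitogenome's annotation is reduced to a circular signed permutation over
the canonical 37-gene vocabulary (sign ``+`` = J strand).  Control-region
markers (CR, CR1, CR2) travel with the order as positional markers — they
are excluded from permutation arithmetic but kept for display and for
detecting genes translocated into the control region.

Equality of orders is rotation-invariant; the serialised form linearises at
trnI's slot by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

from . import vocab

Token = tuple[str, int]   # (symbol, sign); sign +1 = J strand


def _is_marker(name: str) -> bool:
    return name in vocab.CONTROL_MARKERS


@dataclass(frozen=True)
class SignedGeneOrder:
    """A circular signed gene order with interleaved control markers."""

    tokens: tuple[Token, ...]

    def __post_init__(self) -> None:
        genes = [t[0] for t in self.tokens if not _is_marker(t[0])]
        if len(genes) != len(set(genes)):
            dup = sorted({g for g in genes if genes.count(g) > 1})
            raise ValueError(f"duplicate genes in order: {dup}")
        for name, sign in self.tokens:
            if sign not in (-1, +1):
                raise ValueError(f"{name}: sign must be +1 or -1")
            if not _is_marker(name) and name not in vocab.CANONICAL_GENES:
                raise ValueError(f"unknown gene symbol {name!r}")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_line(cls, line: str) -> "SignedGeneOrder":
        """Parse a whitespace-separated token line; leading '-' = N strand."""
        tokens = []
        for tok in line.split():
            if tok.startswith("-"):
                tokens.append((tok[1:], -1))
            else:
                tokens.append((tok, +1))
        return cls(tuple(tokens))

    def to_line(self) -> str:
        return " ".join(f"-{n}" if s < 0 else n
                        for n, s in self.canonical().tokens)

    # -- views ---------------------------------------------------------------

    @property
    def genes(self) -> tuple[Token, ...]:
        """Gene tokens only (control markers dropped)."""
        return tuple(t for t in self.tokens if not _is_marker(t[0]))

    @property
    def gene_symbols(self) -> tuple[str, ...]:
        return tuple(t[0] for t in self.genes)

    def sign_of(self, gene: str) -> int:
        for name, sign in self.tokens:
            if name == gene:
                return sign
        raise KeyError(gene)

    def canonical(self) -> "SignedGeneOrder":
        """Rotate so the order begins at trnI's slot (or the lexicographically
        smallest rotation when trnI is absent, e.g. for sub-orders)."""
        toks = self.tokens
        for i, (name, _) in enumerate(toks):
            if name == "trnI":
                return SignedGeneOrder(toks[i:] + toks[:i])
        best = min(range(len(toks)),
                   key=lambda i: toks[i:] + toks[:i])
        return SignedGeneOrder(toks[best:] + toks[:best])

    # -- equality (rotation-invariant) --------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignedGeneOrder):
            return NotImplemented
        return _cyclic_equal(self.tokens, other.tokens)

    def __hash__(self) -> int:
        return hash(self.canonical().tokens)


def _cyclic_equal(a: Sequence, b: Sequence) -> bool:
    if len(a) != len(b):
        return False
    if len(a) == 0:
        return True
    a, b = tuple(a), tuple(b)
    return any(b[i:] + b[:i] == a for i in range(len(b)))


# ---------------------------------------------------------------------------
# Construction from annotations
# ---------------------------------------------------------------------------

def ancestral_order() -> SignedGeneOrder:
    """The ancestral insect (Drosophila-type) ground-pattern gene order."""
    return SignedGeneOrder(vocab.ANCESTRAL_ORDER)


def extract_gene_order(genome) -> SignedGeneOrder:
    """Reduce an annotated genome to its circular signed gene order.

    Features are taken in positional order; sign comes from the strand;
    CR markers are interleaved at their positions; unannotated NCR features
    are dropped.
    """
    tokens: list[Token] = []
    for f in sorted(genome.features, key=lambda f: f.start):
        if f.kind == "noncoding":
            continue
        sign = -1 if f.strand == "N" else +1
        tokens.append((f.name, sign))
    return SignedGeneOrder(tuple(tokens))


# ---------------------------------------------------------------------------
# Adjacency (breakpoint) arithmetic
# ---------------------------------------------------------------------------

def _canonical_adjacency(a: Token, b: Token) -> tuple[Token, Token]:
    """Orientation-aware canonical form: (a,b) reads equal to (-b,-a)."""
    fwd = (a, b)
    rev = ((b[0], -b[1]), (a[0], -a[1]))
    return min(fwd, rev)


def adjacency_set(order: SignedGeneOrder) -> set[tuple[Token, Token]]:
    genes = order.genes
    return {_canonical_adjacency(genes[i], genes[(i + 1) % len(genes)])
            for i in range(len(genes))}


def breakpoint_distance(a: SignedGeneOrder, b: SignedGeneOrder) -> int:
    """Number of signed adjacencies of ``a`` absent from ``b`` (circular,
    orientation-aware).  Symmetric because both adjacency sets have equal
    cardinality."""
    _check_same_genes(a, b)
    return len(adjacency_set(a) - adjacency_set(b))


def _check_same_genes(a: SignedGeneOrder, b: SignedGeneOrder) -> None:
    sa, sb = set(a.gene_symbols), set(b.gene_symbols)
    if sa != sb:
        raise ValueError(f"gene sets differ: only in first {sorted(sa - sb)}, "
                         f"only in second {sorted(sb - sa)}")


# ---------------------------------------------------------------------------
# Rearrangement report
# ---------------------------------------------------------------------------

@dataclass
class RearrangementReport:
    """Outcome of comparing an observed order against a reference."""

    identical: bool
    inverted: list[str]
    translocated: list[tuple[str, str, str]]   # (gene, old context, new context)
    breakpoints: int
    affected_cluster: str = ""

    @property
    def translocated_genes(self) -> list[str]:
        return [t[0] for t in self.translocated]

    def to_json(self) -> dict:
        return {
            "identical": self.identical,
            "inverted": self.inverted,
            "translocated": [{"gene": g, "old_context": o, "new_context": n}
                             for g, o, n in self.translocated],
            "breakpoints": self.breakpoints,
            "affected_cluster": self.affected_cluster,
        }


def _neighbor_context(order: SignedGeneOrder, gene: str) -> tuple[str, str]:
    """Immediate token neighbours of a gene, CR1/CR2 collapsed to CR."""
    toks = order.tokens
    for i, (name, _) in enumerate(toks):
        if name == gene:
            prev = toks[(i - 1) % len(toks)][0]
            nxt = toks[(i + 1) % len(toks)][0]
            collapse = lambda s: "CR" if _is_marker(s) else s
            return collapse(prev), collapse(nxt)
    raise KeyError(gene)


def _minimal_removal_sets(obs: tuple[Token, ...], ref: tuple[Token, ...],
                          candidates: Sequence[str], max_exact: int = 4,
                          ) -> tuple[list[frozenset[str]], bool]:
    """All smallest gene subsets whose removal makes the orders cyclically
    equal.  Exact up to ``max_exact`` genes; greedy beyond (flagged)."""
    def removed(tokens, drop):
        return tuple(t for t in tokens if t[0] not in drop)

    if _cyclic_equal(obs, ref):
        return [frozenset()], False
    for size in range(1, max_exact + 1):
        found = [frozenset(sub) for sub in combinations(candidates, size)
                 if _cyclic_equal(removed(obs, set(sub)), removed(ref, set(sub)))]
        if found:
            return found, False
    # greedy fallback: peel off the gene removing the most breakpoints
    drop: set[str] = set()
    pool = list(candidates)
    while pool and not _cyclic_equal(removed(obs, drop), removed(ref, drop)):
        best = max(pool, key=lambda g: -_mismatch_count(
            removed(obs, drop | {g}), removed(ref, drop | {g})))
        drop.add(best)
        pool.remove(best)
    return [frozenset(drop)], True


def _mismatch_count(a: tuple[Token, ...], b: tuple[Token, ...]) -> int:
    if len(a) != len(b):
        return max(len(a), len(b))
    best = len(a)
    for i in range(len(b)):
        rot = b[i:] + b[:i]
        best = min(best, sum(x != y for x, y in zip(a, rot)))
    return best


def _minimal_arc(reference: SignedGeneOrder, genes: set[str]) -> list[str]:
    """Smallest contiguous block of the reference order covering ``genes``."""
    symbols = reference.gene_symbols
    n = len(symbols)
    positions = sorted(symbols.index(g) for g in genes)
    if not positions:
        return []
    if len(positions) == 1:
        return [symbols[positions[0]]]
    # the minimal covering arc excludes the largest circular gap
    gaps = []
    for i, p in enumerate(positions):
        nxt = positions[(i + 1) % len(positions)]
        gaps.append(((nxt - p) % n, i))
    biggest_gap, idx = max(gaps)
    start = positions[(idx + 1) % len(positions)]
    span = n - biggest_gap + 1      # genes in the covering arc, ends inclusive
    return [symbols[(start + k) % n] for k in range(min(span, n))]


def _cluster_label(reference: SignedGeneOrder, genes: set[str]) -> str:
    if not genes:
        return ""
    for name, members in vocab.NAMED_CLUSTERS.items():
        if genes <= set(members):
            return name
    arc = _minimal_arc(reference, genes)
    return "-".join(vocab.TRNA_LETTER.get(g, g) for g in arc)


def compare_orders(observed: SignedGeneOrder,
                   reference: SignedGeneOrder) -> RearrangementReport:
    """Detect inversions, translocations and breakpoints between two orders.

    * inverted — genes whose sign differs.
    * translocated — the union of all minimal gene sets whose removal makes
      the remaining signed orders identical (signs of inverted genes are
      normalised first so a pure in-place inversion is not counted), plus any
      gene that moved between control-region segments (flanked by CR markers
      in one order only).
    * breakpoints — observed signed adjacencies absent from the reference.
    * affected_cluster — named ancestral tRNA cluster containing all events,
      or the minimal contiguous ancestral block.
    """
    _check_same_genes(observed, reference)
    inverted = sorted(g for g in observed.gene_symbols
                      if observed.sign_of(g) != reference.sign_of(g))

    ref_sign = {g: reference.sign_of(g) for g in reference.gene_symbols}
    obs_norm = tuple((n, ref_sign[n]) for n, _ in observed.genes)
    ref_genes = reference.genes

    bp = breakpoint_distance(observed, reference)
    diff_adj = adjacency_set(observed) - adjacency_set(reference)
    candidates = sorted({tok[0] for adj in diff_adj for tok in adj})
    removal_sets, _heuristic = _minimal_removal_sets(obs_norm, ref_genes,
                                                     candidates)
    moved = set().union(*removal_sets) if removal_sets else set()

    # genes translocated into (or out of) the control region
    for g in observed.gene_symbols:
        obs_ctx = _neighbor_context(observed, g)
        ref_ctx = _neighbor_context(reference, g)
        obs_in_cr = obs_ctx == ("CR", "CR")
        ref_in_cr = ref_ctx == ("CR", "CR")
        if obs_in_cr != ref_in_cr:
            moved.add(g)

    translocated = []
    for g in sorted(moved):
        old = "|".join(_neighbor_context(reference, g))
        new = "|".join(_neighbor_context(observed, g))
        translocated.append((g, old, new))

    identical = (not inverted and not translocated and bp == 0
                 and _cyclic_equal(observed.tokens, reference.tokens))
    events = set(inverted) | {t[0] for t in translocated}
    cluster = _cluster_label(reference, events)
    return RearrangementReport(identical, inverted, translocated, bp, cluster)


def rotations(order: SignedGeneOrder) -> Iterable[SignedGeneOrder]:
    toks = order.tokens
    for i in range(len(toks)):
        yield SignedGeneOrder(toks[i:] + toks[:i])
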