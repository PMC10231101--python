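"""Rearrangement mechanism inference: TDRL scenarios and recombination calls.

The tandem duplication/random loss (TDRL) model duplicates a contiguous gene
window in tandem and then deletes one copy of each duplicated gene.  TDRL
can shuffle gene order but can never flip a gene's strand, so any observed
inversion rules it out and points to recombination instead (inversion, or
inversion followed by translocation when the gene also moved).

``tdrl_search`` enumerates *all* minimal-event TDRL scenarios between two
signed orders, localised to the smallest contiguous block containing the
differences; ``tdrl_reachable_oracle`` is an independent exhaustive
enumeration used for verification on small orders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from .gene_order import (SignedGeneOrder, Token, _check_same_genes,
                         _cyclic_equal, _is_marker)

RETAIN = ("first", "second")


@dataclass(frozen=True)
class TDRLEvent:
    """One duplication-then-loss event.

    ``window`` is a half-open index span [i, j) on the linearised order the
    event applies to; ``retention`` chooses, per gene in the window, which
    tandem copy survives.  Control markers inside the window do not count
    toward retention: unless listed explicitly they are kept in both copies
    (modelling split control regions as duplication remnants).
    """

    window: tuple[int, int]
    retention: tuple[tuple[str, str], ...]   # ((gene, "first"|"second"), ...)
    window_genes: tuple[str, ...] = ()

    @property
    def retention_map(self) -> dict[str, str]:
        return dict(self.retention)

    def describe(self) -> str:
        names = list(self.window_genes) or [g for g, _ in self.retention]
        block = "-".join(names)
        lost = []
        ret = self.retention_map
        for g in names:
            choice = ret.get(g)
            if choice == "second":
                lost.append(f"the first {g}")
            elif choice == "first":
                lost.append(f"the second {g}")
        return (f"{block} duplicated to {block}-{block}; "
                f"lost {', '.join(lost) if lost else 'nothing'}")


def apply_tdrl(order: SignedGeneOrder, event: TDRLEvent) -> SignedGeneOrder:
    """Apply one TDRL event; deterministic, signs always preserved."""
    toks = list(order.tokens)
    i, j = event.window
    if not (0 <= i < j <= len(toks)) or j - i < 2:
        raise ValueError(f"window {event.window} out of bounds or too short")
    win = toks[i:j]
    ret = event.retention_map
    for name, _ in win:
        if not _is_marker(name) and name not in ret:
            raise ValueError(f"retention missing window gene {name}")
    first_pass, second_pass = [], []
    for tok in win:
        choice = ret.get(tok[0], "both" if _is_marker(tok[0]) else None)
        if choice in ("first", "both"):
            first_pass.append(tok)
        if choice in ("second", "both"):
            second_pass.append(tok)
    return SignedGeneOrder(tuple(toks[:i] + first_pass + second_pass + toks[j:]))


@dataclass
class TDRLScenario:
    """An ordered event list whose application transforms source into target.

    The transformation is checked at construction time, never assumed.
    """

    events: list[TDRLEvent]
    source: SignedGeneOrder
    target: SignedGeneOrder

    def __post_init__(self) -> None:
        cur = self.source
        for ev in self.events:
            cur = apply_tdrl(cur, ev)
        if cur != self.target:
            raise ValueError("TDRL scenario does not reproduce its target")

    def replay(self) -> list[SignedGeneOrder]:
        """Source, every intermediate order, and the final order."""
        orders = [self.source]
        for ev in self.events:
            orders.append(apply_tdrl(orders[-1], ev))
        return orders


# ---------------------------------------------------------------------------
# Minimal-scenario search
# ---------------------------------------------------------------------------

_SuccessorMap = dict[tuple[int, ...], tuple[int, int, int]]
_SUCCESSOR_CACHE: dict[tuple[int, ...], _SuccessorMap] = {}
_CACHE_LIMIT = 120_000


def _successor_events(order: tuple[int, ...]) -> _SuccessorMap:
    """result order -> canonical (i, j, retention mask) reaching it in one event.

    Events are enumerated in the canonical order (window start, window
    length, retention mask with first<second encoded 0<1), so the stored
    event is the canonical representative for its result.
    """
    cached = _SUCCESSOR_CACHE.get(order)
    if cached is not None:
        return cached
    n = len(order)
    out: _SuccessorMap = {}
    for i in range(n - 1):
        for length in range(2, n - i + 1):
            j = i + length
            win = order[i:j]
            head, tail = order[:i], order[j:]
            for mask in range(1 << length):
                kept_first = tuple(win[k] for k in range(length)
                                   if not mask & (1 << k))
                kept_second = tuple(win[k] for k in range(length)
                                    if mask & (1 << k))
                result = head + kept_first + kept_second + tail
                out.setdefault(result, (i, j, mask))
    if len(_SUCCESSOR_CACHE) * max(1, len(out)) > _CACHE_LIMIT:
        _SUCCESSOR_CACHE.clear()
    _SUCCESSOR_CACHE[order] = out
    return out


def _framings(source: SignedGeneOrder, target: SignedGeneOrder,
              ) -> list[tuple[tuple[Token, ...], tuple[Token, ...], int]]:
    """All rotation alignments of the circular orders, each rotated so its
    differing positions form a contiguous block starting at index 0.

    Returns (framed source, framed target, block span) triples sorted by
    block span; an empty list means the orders are identical.  Searching
    every framing keeps the event count minimal under circular (rotation-
    invariant) equality, where windows may not wrap the chosen origin.
    """
    src, tgt = source.genes, target.genes
    n = len(src)
    out = []
    for r in range(n):
        rot = tgt[r:] + tgt[:r]
        mism = [i for i in range(n) if rot[i] != src[i]]
        if not mism:
            return []
        gaps = []
        for k, p in enumerate(mism):
            nxt = mism[(k + 1) % len(mism)]
            gaps.append(((nxt - p) % n, k))
        big, idx = max(gaps)
        span = min(n - big + 1, n) if len(mism) > 1 else 1
        start = mism[(idx + 1) % len(mism)]
        frame_src = src[start:] + src[:start]
        frame_tgt = rot[start:] + rot[:start]
        out.append((frame_src, frame_tgt, span))
    out.sort(key=lambda f: f[2])
    # identical framings can arise from different rotations of a symmetric
    # target; keep the first of each
    seen, unique = set(), []
    for f in out:
        key = (f[0], f[1])
        if key not in seen:
            seen.add(key)
            unique.append(f)
    return unique


def _decode_event(code: tuple[int, int, int],
                  frame: tuple[Token, ...]) -> TDRLEvent:
    i, j, mask = code
    genes = tuple(frame[k][0] for k in range(i, j))
    retention = tuple((g, RETAIN[(mask >> k) & 1]) for k, g in enumerate(genes))
    return TDRLEvent((i, j), retention, genes)


def tdrl_search(source: SignedGeneOrder, target: SignedGeneOrder,
                max_events: int = 2, enumerate_scenarios: bool = True,
                max_block: int = 12) -> list[TDRLScenario] | None:
    """All minimal TDRL scenarios from source to target, or None if infeasible.

    Infeasible when any gene's sign differs (TDRL cannot invert) or when no
    scenario exists within ``max_events`` (at most 3).  Scenarios producing
    identical intermediate orders collapse to one canonical representative;
    the search is localised to the smallest contiguous block containing all
    differences, and rotation framings whose differing block exceeds
    ``max_block`` genes are not searched (event enumeration is exponential in
    the block size; every rearrangement cluster reported in insects is far
    smaller).  With ``enumerate_scenarios=False`` only one witness scenario
    of minimal event count is returned.
    """
    if not 0 <= max_events <= 3:
        raise ValueError("max_events must be between 0 and 3")
    _check_same_genes(source, target)
    for g in source.gene_symbols:
        if source.sign_of(g) != target.sign_of(g):
            return None     # a sign flip: TDRL cannot generate inversions

    framings = _framings(source, target)
    if not framings:
        only = SignedGeneOrder(source.genes)
        return [TDRLScenario([], only, SignedGeneOrder(target.genes))]
    if max_events == 0:
        return None

    def scenario(frame_src, frame_tgt,
                 codes: tuple[tuple[int, int, int], ...]) -> TDRLScenario:
        events, frame = [], frame_src
        cur = SignedGeneOrder(frame_src)
        for code in codes:
            ev = _decode_event(code, frame)
            events.append(ev)
            cur = apply_tdrl(cur, ev)
            frame = cur.tokens
        return TDRLScenario(events, SignedGeneOrder(frame_src),
                            SignedGeneOrder(frame_tgt))

    def collect(depth: int) -> list[TDRLScenario]:
        found: list[TDRLScenario] = []
        seen_traj: set = set()
        for frame_src, frame_tgt, span in framings:
            if span < 2 or span > max_block:
                continue
            # int-code the differing block so the successor cache is shared
            block = frame_src[:span]
            index = {tok: k for k, tok in enumerate(block)}
            src_t = tuple(range(span))
            tgt_t = tuple(index[tok] for tok in frame_tgt[:span])
            m1 = _successor_events(src_t)
            if depth == 1:
                if tgt_t in m1:
                    sc = scenario(frame_src, frame_tgt, (m1[tgt_t],))
                    if () not in seen_traj:
                        seen_traj.add(())
                        found.append(sc)
                    if not enumerate_scenarios:
                        return found
                continue
            for mid in sorted(m1, key=lambda o: m1[o]):
                if mid == src_t:
                    continue
                m2 = _successor_events(mid)
                if depth == 2:
                    if tgt_t in m2:
                        sc = scenario(frame_src, frame_tgt,
                                      (m1[mid], m2[tgt_t]))
                        key = tuple(o.canonical().tokens
                                    for o in sc.replay()[1:-1])
                        if key not in seen_traj:
                            seen_traj.add(key)
                            found.append(sc)
                        if not enumerate_scenarios:
                            return found
                    continue
                for mid2 in sorted(m2, key=lambda o: m2[o]):
                    if mid2 in (src_t, mid):
                        continue
                    m3 = _successor_events(mid2)
                    if tgt_t in m3:
                        sc = scenario(frame_src, frame_tgt,
                                      (m1[mid], m2[mid2], m3[tgt_t]))
                        key = tuple(o.canonical().tokens
                                    for o in sc.replay()[1:-1])
                        if key not in seen_traj:
                            seen_traj.add(key)
                            found.append(sc)
                        if not enumerate_scenarios:
                            return found
        return found

    for depth in range(1, max_events + 1):
        found = collect(depth)
        if found:
            return found
    return None


# ---------------------------------------------------------------------------
# Exhaustive reachability oracle (verification only)
# ---------------------------------------------------------------------------

def tdrl_reachable_oracle(source: SignedGeneOrder, depth: int,
                          ) -> set[tuple[Token, ...]]:
    """Every gene order reachable from ``source`` in at most ``depth`` TDRL
    events, by brute-force enumeration of all (window, per-gene copy choice)
    compositions.  Limited to orders of at most 7 genes and depth at most 2.
    """
    genes = source.genes
    if len(genes) > 7:
        raise ValueError("oracle limited to orders of at most 7 genes")
    if depth > 2:
        raise ValueError("oracle limited to depth 2")

    def one_step(order: tuple[Token, ...]) -> set[tuple[Token, ...]]:
        n = len(order)
        results: set[tuple[Token, ...]] = set()
        for i in range(n - 1):
            for j in range(i + 2, n + 1):
                length = j - i
                # positions in the tandem duplicate: first copy k, second L+k
                for keeps in product(*[(k, length + k) for k in range(length)]):
                    middle = tuple(order[i + p % length]
                                   for p in sorted(keeps))
                    results.add(order[:i] + middle + order[j:])
        return results

    frontier = {genes}
    reachable = {genes}
    for _ in range(depth):
        nxt: set[tuple[Token, ...]] = set()
        for order in frontier:
            nxt |= one_step(order)
        frontier = nxt - reachable
        reachable |= nxt
    return reachable


# ---------------------------------------------------------------------------
# Mechanism classification
# ---------------------------------------------------------------------------

MECHANISM_LABELS = ("none", "TDRL", "recombination_inversion",
                    "recombination_inversion_translocation", "unexplained")


@dataclass
class MechanismCall:
    """Label plus human-readable narrative for one observed rearrangement."""

    label: str
    narrative: list[str] = field(default_factory=list)
    scenarios: list[TDRLScenario] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "label": self.label,
            "narrative": self.narrative,
            "n_minimal_scenarios": len(self.scenarios),
            "scenarios": [[ev.describe() for ev in sc.events]
                          for sc in self.scenarios],
        }


def classify_mechanism(report, observed: SignedGeneOrder,
                       reference: SignedGeneOrder,
                       max_events: int = 2) -> MechanismCall:
    """Decide the rearrangement mechanism from a comparison report.

    Decision rule: identical orders -> none; no inversions and a TDRL
    scenario exists -> TDRL (all minimal scenarios attached, searched from
    the reference toward the observed order); inverted genes that also
    translocated -> recombination (inversion + translocation); inversions in
    place -> recombination (inversion); otherwise unexplained.
    """
    if report.identical:
        return MechanismCall("none", ["gene order identical to the reference"])
    if not report.inverted:
        scenarios = tdrl_search(reference, observed, max_events=max_events)
        if scenarios is not None and scenarios and scenarios[0].events:
            narrative = [ev.describe() for ev in scenarios[0].events]
            return MechanismCall("TDRL", narrative, scenarios)
        return MechanismCall(
            "unexplained",
            [f"no TDRL scenario within {max_events} events and no inversion"])
    trans = set(report.translocated_genes)
    narrative = []
    for g in report.inverted:
        if g in trans:
            ctx = next(n for gg, _, n in report.translocated if gg == g)
            where = ("between control-region segments"
                     if ctx == "CR|CR" else f"to context {ctx}")
            narrative.append(f"{g} inverted, then translocated {where}")
        else:
            narrative.append(f"{g} inverted in place")
    for g in sorted(trans - set(report.inverted)):
        narrative.append(f"{g} translocated")
    if set(report.inverted) & trans:
        return MechanismCall("recombination_inversion_translocation", narrative)
    return MechanismCall("recombination_inversion", narrative)
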