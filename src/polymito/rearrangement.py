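"""Tandem duplication-random loss (TDRL) events on gene orders.

A TDRL event replaces a contiguous segment of a gene order with ``copies``
tandem copies of itself and then deletes a subset of the copied gene slots.
"Random loss" is generalised to an arbitrary keep-pattern; the classic
one-duplication TDRL is the ``copies=2`` case.  ``explain`` searches for all
minimal-length event series transforming an ancestral order into a derived
one: intermediate events are enumerated (with a bounded keep-pattern space),
while the final step of every series uses an exact chain-cover reachability
check, so series of length <= 2 are found exactly whenever one exists within
``max_copies``.

Orders are label tuples; circular orders are rotated to a fixed anchor gene
(Cytb when present) before comparison so rotations are not counted as
rearrangements.  Strand/inversions are not modelled (TDRL preserves
orientation).
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "GeneOrder",
    "TdrlEvent",
    "EventSeries",
    "ExplainResult",
    "apply_tdrl",
    "explain",
    "verify_series",
]

DEFAULT_ANCHOR = "Cytb"


@dataclass(frozen=True)
class GeneOrder:
    """An ordered gene arrangement (duplicate labels allowed)."""

    genes: tuple
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("empty gene order")
        object.__setattr__(self, "genes", tuple(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def canonical(self, anchor: str = DEFAULT_ANCHOR) -> "GeneOrder":
        """Rotate a circular order to start at the anchor gene (first occurrence).

        Falls back to the lexicographically smallest rotation when the anchor
        is absent.  Linear orders are returned unchanged.
        """
        if not self.circular:
            return self
        g = self.genes
        if anchor in g:
            i = g.index(anchor)
            rot = g[i:] + g[:i]
        else:
            rot = min(tuple(g[i:] + g[:i]) for i in range(len(g)))
        return GeneOrder(rot, circular=True)


@dataclass(frozen=True)
class TdrlEvent:
    """Duplicate ``order[start:end]`` ``copies`` times, keeping flagged slots.

    ``kept[c][i]`` says whether copy ``c`` retains the segment's i-th gene.
    """

    start: int
    end: int
    copies: int
    kept: tuple  # copies x segment-length booleans

    def __post_init__(self) -> None:
        if self.copies < 2:
            raise ValueError("a duplication event needs copies >= 2")
        if self.end <= self.start:
            raise ValueError("empty segment")
        kept = tuple(tuple(bool(b) for b in row) for row in self.kept)
        if len(kept) != self.copies or any(len(r) != self.end - self.start for r in kept):
            raise ValueError("kept flags inconsistent with copies and segment length")
        object.__setattr__(self, "kept", kept)


@dataclass(frozen=True)
class EventSeries:
    events: tuple = ()
    result: GeneOrder | None = field(default=None, compare=False)

    def __len__(self) -> int:
        return len(self.events)


@dataclass(frozen=True)
class ExplainResult:
    series: tuple
    status: str  # "ok" | "truncated"

    def __iter__(self):
        return iter(self.series)

    def __len__(self) -> int:
        return len(self.series)


def apply_tdrl(order: GeneOrder, event: TdrlEvent, allow_loss: bool = False) -> GeneOrder:
    """Apply one duplication-loss event; raises if a gene would vanish entirely."""
    g = order.genes
    if event.start < 0 or event.end > len(g):
        raise IndexError(
            f"segment [{event.start}, {event.end}) outside order of length {len(g)}"
        )
    segment = g[event.start : event.end]
    new_segment = tuple(
        segment[i]
        for c in range(event.copies)
        for i in range(len(segment))
        if event.kept[c][i]
    )
    result = g[: event.start] + new_segment + g[event.end :]
    if not allow_loss:
        lost = set(segment) - set(result)
        if lost:
            raise ValueError(f"event deletes every copy of {sorted(lost)} (loss disabled)")
    return GeneOrder(result, circular=order.circular)


def verify_series(
    ancestral: GeneOrder, series: EventSeries | Sequence[TdrlEvent], derived: GeneOrder
) -> bool:
    """Replay events on the ancestral order; True iff the result matches derived.

    Invalid events (out-of-bounds segments, total loss) raise rather than
    returning False.
    """
    events = series.events if isinstance(series, EventSeries) else tuple(series)
    state = ancestral.canonical()
    for e in events:
        state = apply_tdrl(state, e)
    return state.canonical().genes == derived.canonical().genes


# ---------------------------------------------------------------------------
# One-step reachability (exact): chain cover of the replaced window
# ---------------------------------------------------------------------------

def _min_chain_cover(middle: Sequence, segment: Sequence):
    """Split ``middle`` into the fewest consecutive blocks, each an in-order
    subsequence of ``segment``.  Greedy earliest-match is optimal because a
    smaller segment cursor never excludes a future match.

    Returns (n_chains, matched) where matched[c] is the list of segment
    positions used by chain c, or None if some gene of middle is absent from
    segment.
    """
    occ: dict = {}
    for i, gene in enumerate(segment):
        occ.setdefault(gene, []).append(i)
    chains: list[list[int]] = [[]]
    cursor = 0
    for gene in middle:
        positions = occ.get(gene)
        if not positions:
            return None
        nxt = next((p for p in positions if p >= cursor), None)
        if nxt is None:
            chains.append([])
            nxt = positions[0]
        chains[-1].append(nxt)
        cursor = nxt + 1
    return len(chains), chains


def _one_step_events(
    x: tuple, y: tuple, max_copies: int, allow_loss: bool = False
) -> Iterable[TdrlEvent]:
    """All TDRL events (up to ``max_copies``) turning order ``x`` into ``y``."""
    n, m = len(x), len(y)
    cp = 0
    while cp < min(n, m) and x[cp] == y[cp]:
        cp += 1
    cs = 0
    while cs < min(n, m) and x[n - 1 - cs] == y[m - 1 - cs]:
        cs += 1

    seen = set()
    for i in range(cp + 1):
        for j in range(n, i, -1):  # segment = x[i:j], needs j > i
            if n - j > cs:
                break
            if m - (n - j) < i:
                continue
            middle = y[i : m - (n - j)]
            segment = x[i:j]
            if not middle:
                continue
            cover = _min_chain_cover(middle, segment)
            if cover is None:
                continue
            n_chains, matched = cover
            if n_chains > max_copies:
                continue
            copies = max(2, n_chains)
            kept = []
            for c in range(copies):
                row = [False] * len(segment)
                if c < len(matched):
                    for p in matched[c]:
                        row[p] = True
                kept.append(tuple(row))
            event = TdrlEvent(i, j, copies, tuple(kept))
            if not allow_loss:
                present_after = set(x[:i]) | set(middle) | set(x[j:])
                if set(segment) - present_after:
                    continue
            sig = (i, j, copies, event.kept)
            if sig not in seen:
                seen.add(sig)
                yield event


# ---------------------------------------------------------------------------
# Event enumeration for intermediate steps (bounded keep-pattern space)
# ---------------------------------------------------------------------------

def _enumerate_events(
    x: tuple, max_copies: int, slot_cap: int = 12
) -> Iterable[TdrlEvent]:
    """All events on ``x`` whose slot count (copies x segment length) fits the cap."""
    n = len(x)
    total = Counter(x)
    for i in range(n):
        for j in range(i + 1, n + 1):
            segment = x[i:j]
            seg_count = Counter(segment)
            outside_set = {g for g in seg_count if total[g] > seg_count[g]}
            L = j - i
            for copies in range(2, max_copies + 1):
                if copies * L > slot_cap:
                    continue
                for bits in itertools.product((False, True), repeat=copies * L):
                    kept = tuple(
                        tuple(bits[c * L : (c + 1) * L]) for c in range(copies)
                    )
                    # no-loss: every segment gene kept somewhere or present outside
                    ok = True
                    for p, gene in enumerate(segment):
                        if gene in outside_set:
                            continue
                        if not any(kept[c][p2] for c in range(copies)
                                   for p2 in range(L) if segment[p2] == gene):
                            ok = False
                            break
                    if ok:
                        yield TdrlEvent(i, j, copies, kept)


def explain(
    ancestral: GeneOrder,
    derived: GeneOrder,
    max_events: int = 3,
    max_copies: int = 3,
    series_cap: int = 50,
    state_cap: int = 200_000,
) -> ExplainResult:
    """All minimal-length TDRL series from ``ancestral`` to ``derived``.

    Breadth-first over canonicalised states with duplicate-state pruning;
    returns every minimal series (capped at ``series_cap``) or an empty result
    when the target is unreachable within ``max_events``.  Status is
    ``"truncated"`` when a search bound (series/state cap) was hit, never a
    silent cut-off.
    """
    if len(derived) > 14:
        raise ValueError("derived order longer than 14 labels; search intractable")
    anc = ancestral.canonical()
    der = derived.canonical()
    x0, y = anc.genes, der.genes
    truncated = False

    if x0 == y:
        return ExplainResult((EventSeries((), der),), "ok")

    der_set = set(y)

    # frontier of (state, event-prefix); depth d holds states after d events
    frontier: dict[tuple, tuple] = {x0: ()}
    for depth in range(1, max_events + 1):
        found: list[EventSeries] = []
        capped = False
        for state, prefix in frontier.items():
            for last in _one_step_events(state, y, max_copies):
                found.append(EventSeries(prefix + (last,), der))
                if len(found) >= series_cap:  # reporting cap, not a search bound
                    capped = True
                    break
            if capped:
                break
        if found:
            return ExplainResult(tuple(found), "ok")
        if depth == max_events:
            break
        nxt: dict[tuple, tuple] = {}
        for state, prefix in frontier.items():
            for event in _enumerate_events(state, max_copies):
                try:
                    new = apply_tdrl(GeneOrder(state, anc.circular), event)
                except ValueError:
                    continue
                g = new.canonical().genes
                if len(g) > len(y) + 4 or set(g) != der_set:
                    continue
                if g not in nxt and g != x0:
                    nxt[g] = prefix + (event,)
                if len(nxt) >= state_cap:
                    truncated = True
                    break
            if truncated:
                break
        frontier = nxt
        if not frontier:
            break
    return ExplainResult((), "truncated" if truncated else "ok")
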