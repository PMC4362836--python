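"""Signed-genome model, breakpoint graph, DCJ distance and sorting scenarios.

A genome is an ordered collection of linear chromosomes, each a sequence of
signed block identifiers.  Every block contributes two extremities, its *tail*
``(id, 't')`` and *head* ``(id, 'h')``; a chromosome read left to right visits
``tail -> head`` for a positively-signed block and ``head -> tail`` for a
negative one.  Consecutive extremities of neighbouring blocks form
*adjacencies*; chromosome ends are *telomeres*.

The double-cut-and-join (DCJ) operation cuts up to two adjacencies and rejoins
the four ends, which uniformly models inversions, reciprocal translocations,
fusions and fissions.  The DCJ distance between two genomes over the same
blocks is ``N - (C + I/2)`` where ``N`` is the number of blocks and ``C`` and
``I`` are the cycles and odd-length paths of their adjacency graph.

Scenarios extracted here are DCJ-optimal.  A transposition costs two
operations under this model, and for unoriented components a pure-inversion
scenario can be longer than the DCJ one; in that case the scenario reported is
the optimal mixed one and the discrepancy is flagged on the events (a circular
intermediate is excised and reabsorbed by the following operation).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

Extremity = tuple[int, str]  # (block id, 'h' | 't')

EVENT_TYPES = ("inversion", "fusion", "fission", "translocation")


class BlockSetMismatch(ValueError):
    """The two genomes do not share an identical block-id set."""


@dataclass(frozen=True)
class GenomeArrangement:
    """A genome (leaf or ancestral node) as signed block orders per chromosome."""

    name: str
    chromosomes: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for chrom in self.chromosomes:
            if not chrom:
                raise ValueError("empty chromosome")
            for signed in chrom:
                bid = abs(signed)
                if bid == 0 or bid in seen:
                    raise ValueError(f"block id {bid} duplicated or zero")
                seen.add(bid)

    @classmethod
    def from_lists(cls, name: str, chromosomes: Iterable[Iterable[int]]) -> "GenomeArrangement":
        return cls(name, tuple(tuple(c) for c in chromosomes))

    @property
    def block_ids(self) -> frozenset[int]:
        return frozenset(abs(s) for chrom in self.chromosomes for s in chrom)

    @property
    def n_blocks(self) -> int:
        return sum(len(c) for c in self.chromosomes)

    def canonical(self) -> "GenomeArrangement":
        """Normalise chromosome flips and order (a chromosome equals its reverse
        complement)."""
        chroms = []
        for chrom in self.chromosomes:
            flipped = tuple(-s for s in reversed(chrom))
            chroms.append(min(chrom, flipped))
        chroms.sort(key=lambda c: (min(abs(s) for s in c), c))
        return GenomeArrangement(self.name, tuple(chroms))

    def equivalent(self, other: "GenomeArrangement") -> bool:
        """Equality up to chromosome order and whole-chromosome flips."""
        return self.canonical().chromosomes == other.canonical().chromosomes


@dataclass(frozen=True)
class AdjacencySet:
    """Breakpoint-graph encoding of one genome: adjacency pairs plus telomeres."""

    adjacencies: frozenset[frozenset[Extremity]]
    telomeres: frozenset[Extremity]


@dataclass(frozen=True)
class EventRecord:
    """One rearrangement on a tree branch, with the segment ends it breaks."""

    branch: str
    event_type: str
    broken_ends: frozenset[Extremity]
    chroms_involved: frozenset[int] = frozenset()
    step: int = 0
    new_adjacencies: frozenset[frozenset[Extremity]] = frozenset()
    flagged: bool = False  # circular intermediate involved
    params: tuple = ()  # simulator replay payload


def left_end(signed: int) -> Extremity:
    return (signed, "t") if signed > 0 else (-signed, "h")


def right_end(signed: int) -> Extremity:
    return (signed, "h") if signed > 0 else (-signed, "t")


def other_end(e: Extremity) -> Extremity:
    return (e[0], "h" if e[1] == "t" else "t")


def adjacencies(genome: GenomeArrangement) -> AdjacencySet:
    """The adjacency/telomere encoding of a linear multichromosomal genome."""
    adj: set[frozenset[Extremity]] = set()
    tel: set[Extremity] = set()
    for chrom in genome.chromosomes:
        tel.add(left_end(chrom[0]))
        tel.add(right_end(chrom[-1]))
        for a, b in zip(chrom, chrom[1:]):
            adj.add(frozenset({right_end(a), left_end(b)}))
    return AdjacencySet(frozenset(adj), frozenset(tel))


def _partner_map(adj: AdjacencySet) -> dict[Extremity, Extremity]:
    partner: dict[Extremity, Extremity] = {}
    for pair in adj.adjacencies:
        a, b = sorted(pair)
        partner[a] = b
        partner[b] = a
    return partner


def _require_same_blocks(a: GenomeArrangement, b: GenomeArrangement) -> None:
    if a.block_ids != b.block_ids:
        diff = sorted(a.block_ids ^ b.block_ids)
        raise BlockSetMismatch(f"block sets differ; symmetric difference {diff}")


def dcj_distance(a: GenomeArrangement, b: GenomeArrangement) -> int:
    """Minimum number of DCJ operations transforming ``a`` into ``b``."""
    _require_same_blocks(a, b)
    pa = _partner_map(adjacencies(a))
    pb = _partner_map(adjacencies(b))
    n = a.n_blocks
    extremities = [(bid, e) for bid in sorted(a.block_ids) for e in ("t", "h")]
    visited: set[Extremity] = set()
    cycles = 0
    odd_paths = 0
    for start in extremities:
        if start in visited:
            continue
        # Walk the component of the adjacency graph through this extremity,
        # alternating a-edges and b-edges.  A component is a cycle iff the walk
        # returns to the start; otherwise it is a path whose parity is the
        # number of graph edges (= extremities it contains).
        component: set[Extremity] = set()
        is_cycle = True
        for first_side in (pa, pb):
            cur, side = start, first_side
            while True:
                component.add(cur)
                nxt = side.get(cur)
                if nxt is None:
                    is_cycle = False
                    break
                side = pb if side is pa else pa
                cur = nxt
                if cur == start and side is pa:
                    break
            if is_cycle and first_side is pa:
                break  # closed cycle; no need to walk the other direction
        if is_cycle:
            cycles += 1
        elif len(component) % 2 == 1:
            odd_paths += 1
        visited |= component
    assert odd_paths % 2 == 0
    return n - cycles - odd_paths // 2


class _GenomeState:
    """Mutable adjacency/telomere state used while extracting a scenario."""

    def __init__(self, genome: GenomeArrangement):
        self.blocks = sorted(genome.block_ids)
        self.partner: dict[Extremity, Extremity | None] = {}
        for bid in self.blocks:
            self.partner[(bid, "t")] = None
            self.partner[(bid, "h")] = None
        for pair in adjacencies(genome).adjacencies:
            a, b = tuple(pair)
            self.partner[a] = b
            self.partner[b] = a

    def adjacency_set(self) -> frozenset[frozenset[Extremity]]:
        return frozenset(
            frozenset({a, b}) for a, b in self.partner.items() if b is not None and a < b
        )

    def has_adjacency(self, p: Extremity, q: Extremity) -> bool:
        return self.partner[p] == q

    def chromosome_of(self, e: Extremity) -> tuple[list[Extremity], bool]:
        """Ordered extremity walk of the chromosome containing ``e``.

        Returns (walk, is_circular); a linear walk runs telomere to telomere.
        """
        # walk right: alternate block-mate and adjacency-partner links
        seq = [e, other_end(e)]
        while True:
            nxt = self.partner[seq[-1]]
            if nxt is None:
                break
            if nxt == seq[0]:
                return seq, True
            seq.append(nxt)
            seq.append(other_end(nxt))
        # walk left from e
        head = [e]
        while True:
            nxt = self.partner[head[-1]]
            if nxt is None:
                break
            head.append(nxt)
            head.append(other_end(nxt))
        head.reverse()
        return head + seq[1:], False

    def chrom_signature(self, e: Extremity) -> frozenset[Extremity]:
        walk, _ = self.chromosome_of(e)
        return frozenset(walk)

    def apply_join(self, p: Extremity, q: Extremity) -> tuple[frozenset[Extremity], set]:
        """DCJ that creates adjacency {p, q}; returns (broken ends, new pairs)."""
        x = self.partner[p]
        y = self.partner[q]
        broken = {p, q}
        if x is not None:
            broken.add(x)
        if y is not None:
            broken.add(y)
        self.partner[p] = q
        self.partner[q] = p
        new_pairs = {frozenset({p, q})}
        if x is not None and y is not None:
            self.partner[x] = y
            self.partner[y] = x
            new_pairs.add(frozenset({x, y}))
        elif x is not None:
            self.partner[x] = None
        elif y is not None:
            self.partner[y] = None
        return frozenset(broken), new_pairs

    def apply_cut(self, p: Extremity) -> frozenset[Extremity]:
        x = self.partner[p]
        assert x is not None
        self.partner[p] = None
        self.partner[x] = None
        return frozenset({p, x})

    def to_arrangement(self, name: str) -> GenomeArrangement:
        chroms = []
        seen: set[Extremity] = set()
        for bid in self.blocks:
            for ext in ((bid, "t"), (bid, "h")):
                if ext in seen or self.partner[ext] is not None:
                    continue
                walk, circ = self.chromosome_of(ext)
                if walk[0] != ext:
                    continue  # reached from the other telomere
                seen.update(walk)
                signed = []
                for i in range(0, len(walk), 2):
                    ee = walk[i]
                    signed.append(ee[0] if ee[1] == "t" else -ee[0])
                chroms.append(tuple(signed))
        remaining = {e for e, p in self.partner.items() if e not in seen}
        if remaining:
            raise ValueError("circular chromosomes present; cannot linearise")
        return GenomeArrangement(name, tuple(chroms))


def _classify_join(state: _GenomeState, p: Extremity, q: Extremity) -> tuple[str, bool]:
    """Event type of the DCJ creating {p, q}, and whether a circular piece is
    created or consumed."""
    walk_p, circ_p = state.chromosome_of(p)
    set_p = frozenset(walk_p)
    if q in set_p:
        if circ_p:
            return "inversion", True  # rewiring within a circular intermediate
        # Same linear chromosome: the join either reverses the spanned segment
        # (stays one linear piece) or excises a circular piece.
        idx = {e: i for i, e in enumerate(walk_p)}
        i, j = idx[p], idx[q]
        # In the telomere-to-telomere walk, adjacencies sit at (odd, even)
        # index pairs.  Joining two extremities of equal index parity reverses
        # the segment between the cuts (an inversion); mixed parity closes a
        # circular excision.
        if i % 2 == j % 2:
            return "inversion", False
        return "fission", True  # circular excision
    walk_q, circ_q = state.chromosome_of(q)
    if circ_p or circ_q:
        return "fusion", True  # reabsorb a circular intermediate
    p_tel = state.partner[p] is None
    q_tel = state.partner[q] is None
    if p_tel and q_tel:
        # joining two chromosome ends end-to-end
        return "fusion", False
    return "translocation", False


def sorting_scenario(
    a: GenomeArrangement,
    b: GenomeArrangement,
    prefer_inversions: bool = True,
    branch: str = "",
) -> list[EventRecord]:
    """A DCJ-optimal, deterministic scenario transforming ``a`` into ``b``.

    Greedy extraction: at each step every adjacency of ``b`` missing from the
    current genome is a candidate distance-reducing join.  Candidates are
    ranked to (1) reabsorb circular intermediates immediately, (2) prefer
    inversions when requested, breaking ties on the lexicographically smallest
    extremity involved; trailing telomere cuts clear adjacencies absent in
    ``b``.
    """
    _require_same_blocks(a, b)
    state = _GenomeState(a)
    target = _partner_map(adjacencies(b))
    target_pairs = sorted(
        (tuple(sorted(pair)) for pair in adjacencies(b).adjacencies),
    )
    events: list[EventRecord] = []
    step = 0
    pending = True
    while pending:
        candidates = []
        for p, q in target_pairs:
            if state.has_adjacency(p, q):
                continue
            etype, circular = _classify_join(state, p, q)
            if prefer_inversions:
                rank = (0 if circular and etype == "fusion" else 1, 0 if etype == "inversion" else 1)
            else:
                rank = (0 if circular and etype == "fusion" else 1, 1)
            candidates.append((rank, (p, q), etype, circular))
        if not candidates:
            break
        candidates.sort()
        _, (p, q), etype, circular = candidates[0]
        sig_before = {state.chrom_signature(p)}
        sig_before.add(state.chrom_signature(q))
        broken, new_pairs = state.apply_join(p, q)
        step += 1
        events.append(
            EventRecord(
                branch=branch,
                event_type=etype,
                broken_ends=broken,
                chroms_involved=frozenset(range(len(sig_before))),
                step=step,
                new_adjacencies=frozenset(new_pairs),
                flagged=circular,
            )
        )
    # Telomere phase: cut adjacencies whose extremities are telomeric in b.
    for bid in state.blocks:
        for ext in ((bid, "t"), (bid, "h")):
            if target.get(ext) is None and state.partner[ext] is not None:
                _, circ = state.chromosome_of(ext)
                broken = state.apply_cut(ext)
                step += 1
                events.append(
                    EventRecord(
                        branch=branch,
                        event_type="fission",
                        broken_ends=broken,
                        chroms_involved=frozenset({0}),
                        step=step,
                        flagged=circ,
                    )
                )
    assert state.adjacency_set() == frozenset(
        frozenset({x, y}) for x, y in target.items() if x < y
    )
    return events


def classify_event(event: EventRecord, before: GenomeArrangement) -> str:
    """Recompute an event's type from the genome it was applied to."""
    state = _GenomeState(before)
    for pair in event.new_adjacencies:
        p, q = sorted(pair)
        if not all(e in event.broken_ends for e in (p, q)):
            continue
        if state.partner.get(p, "missing") == "missing":
            raise ValueError(f"extremity {p} not in genome {before.name}")
        etype, _ = _classify_join(state, p, q)
        return etype
    # no recorded join: a pure cut
    for e in event.broken_ends:
        if state.partner.get(e, "missing") == "missing":
            raise ValueError(f"extremity {e} not in genome {before.name}")
    return "fission"


def replay_scenario(
    a: GenomeArrangement, events: Sequence[EventRecord], name: str = "replayed"
) -> GenomeArrangement:
    """Apply a scenario's joins/cuts in order; returns the resulting genome."""
    state = _GenomeState(a)
    for ev in events:
        joined: set[Extremity] = set()
        for pair in sorted(ev.new_adjacencies, key=sorted):
            p, q = sorted(pair)
            state.apply_join(p, q)
            joined.update((p, q))
        if not ev.new_adjacencies:
            cut = [e for e in sorted(ev.broken_ends) if state.partner[e] is not None]
            if cut:
                state.apply_cut(cut[0])
    return state.to_arrangement(name)


@dataclass(frozen=True)
class WholeBlockOrientation:
    """Orientation evidence for a block that is a whole chromosome on its own."""

    block_id: int
    minority_species: frozenset[str]
    counted: bool  # True inversion under the >=2-species support rule
    status: str  # 'true_inversion' | 'orientation_unknown' | 'consistent'


def count_whole_block_inversions(
    arrangements: Mapping[str, GenomeArrangement],
) -> list[WholeBlockOrientation]:
    """Apply the whole-block inversion support rule across species.

    A block forming a chromosome on its own carries no internal marker of
    orientation, so a solitary disagreeing species is treated as unknown; a
    different orientation recovered in two or more species counts as a true
    inversion.
    """
    if not arrangements:
        return []
    singleton_blocks: set[int] = set()
    for g in arrangements.values():
        for chrom in g.chromosomes:
            if len(chrom) == 1:
                singleton_blocks.add(abs(chrom[0]))
    out = []
    for bid in sorted(singleton_blocks):
        signs: dict[str, int] = {}
        for sp, g in arrangements.items():
            for chrom in g.chromosomes:
                for signed in chrom:
                    if abs(signed) == bid:
                        signs[sp] = 1 if signed > 0 else -1
        counts = Counter(signs.values())
        if len(counts) == 1:
            out.append(WholeBlockOrientation(bid, frozenset(), False, "consistent"))
            continue
        minority_sign = min(counts, key=lambda s: (counts[s], s))
        minority = frozenset(sp for sp, s in signs.items() if s == minority_sign)
        if len(minority) >= 2:
            out.append(WholeBlockOrientation(bid, minority, True, "true_inversion"))
        else:
            out.append(WholeBlockOrientation(bid, minority, False, "orientation_unknown"))
    return out
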