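"""Synthetic rearrangement histories with full ground truth.

The generator emulates the study system: a bird-like root karyotype of about
forty chromosomes (a few block-rich macrochromosomes and many small
microchromosomes, 2n close to 80) evolving along a dated six-leaf tree by
inversions, reciprocal translocations, fusions and fissions, with optional
breakpoint reuse.  It also fabricates the side data the downstream statistics
consume: Mb-scale genetic maps whose rates can be coupled to true breakpoint
positions, and per-chromosome gene annotations with an optionally seeded
enriched (chromosome, term) pair.

Everything is driven by a single seed; independent random streams are spawned
per purpose (events, genetic map, annotations) so changing one knob leaves the
other outputs fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .genome_io import (
    GeneAnnotation,
    GeneticMapMarker,
    PhyloTree,
    SyntenyBlock,
    packaged_tree,
)
from .rearrangement import (
    EventRecord,
    Extremity,
    GenomeArrangement,
    adjacencies,
    left_end,
    replay_scenario,
    right_end,
)

DEFAULT_RATES = {
    # events per million years per branch; inversion-dominated, interchromosomal
    # change rare, mirroring avian karyotype evolution
    "inversion": 0.12,
    "translocation": 0.010,
    "fusion": 0.005,
    "fission": 0.005,
}


@dataclass(frozen=True)
class SimulationConfig:
    n_macro: int = 10
    n_micro: int = 30
    blocks_per_macro: tuple[int, int] = (6, 12)
    blocks_per_micro: tuple[int, int] = (1, 3)
    macro_block_length: tuple[int, int] = (1_000_000, 10_000_000)
    micro_block_length: tuple[int, int] = (1_000_000, 5_000_000)
    tree: PhyloTree | None = None  # defaults to the packaged six-species tree
    rates: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RATES))
    events_per_branch_range: tuple[int, int] | None = None  # uniform override
    breakpoint_reuse_prob: float = 0.1
    micro_micro_weight: float = 0.1  # down-weight for micro-micro interchromosomal pairs
    hotspot_coupling: float = 0.0
    marker_spacing: int = 250_000
    seed: int = 0


@dataclass
class SimulationTruth:
    config: SimulationConfig
    tree: PhyloTree
    node_arrangements: dict[str, GenomeArrangement]
    event_log: list[EventRecord]
    block_lengths: dict[int, int]
    micro_blocks: frozenset[int]  # blocks born on root microchromosomes

    def events_on_branch(self, child: str) -> list[EventRecord]:
        return [e for e in self.event_log if e.branch == child]

    def lineage_events(self, leaf: str) -> list[EventRecord]:
        parent_of = {c: p for p, c, _ in self.tree.branches()}
        path, node = [], leaf
        while node in parent_of:
            path.append(node)
            node = parent_of[node]
        out: list[EventRecord] = []
        for n in reversed(path):
            out.extend(self.events_on_branch(n))
        return out

    # -- reference-coordinate helpers -------------------------------------
    def reference_layout(self, reference_leaf: str):
        """Coordinates of every block on the reference leaf's chromosomes.

        Returns (placement, chrom_lengths) where placement maps block id to
        (chrom_name, start, end, ref_sign, index within chromosome).
        """
        genome = self.node_arrangements[reference_leaf]
        placement: dict[int, tuple[str, int, int, int, int]] = {}
        chrom_lengths: dict[str, int] = {}
        for ci, chrom in enumerate(genome.chromosomes):
            name = f"chr{ci + 1}"
            pos = 0
            for idx, signed in enumerate(chrom):
                bid = abs(signed)
                length = self.block_lengths[bid]
                placement[bid] = (name, pos, pos + length, 1 if signed > 0 else -1, idx)
                pos += length
            chrom_lengths[name] = pos
        return placement, chrom_lengths

    def breakpoint_positions(self, reference_leaf: str) -> dict[str, list[int]]:
        """Reference positions where at least one other leaf breaks adjacency."""
        ref = self.node_arrangements[reference_leaf]
        leaf_adjs = {
            leaf: adjacencies(self.node_arrangements[leaf]).adjacencies
            for leaf in self.tree.leaves
            if leaf != reference_leaf
        }
        placement, _ = self.reference_layout(reference_leaf)
        out: dict[str, list[int]] = {}
        for ci, chrom in enumerate(ref.chromosomes):
            name = f"chr{ci + 1}"
            positions = []
            for a, b in zip(chrom, chrom[1:]):
                pair = frozenset({right_end(a), left_end(b)})
                if any(pair not in adj for adj in leaf_adjs.values()):
                    positions.append(placement[abs(b)][1])
            out[name] = positions
        return out

    def expected_mshsb_count(self, reference_leaf: str) -> int:
        """Blocks remaining after collapsing adjacencies preserved in every leaf."""
        ref = self.node_arrangements[reference_leaf]
        leaf_adjs = [
            adjacencies(self.node_arrangements[leaf]).adjacencies
            for leaf in self.tree.leaves
            if leaf != reference_leaf
        ]
        count = 0
        for chrom in ref.chromosomes:
            count += 1
            for a, b in zip(chrom, chrom[1:]):
                pair = frozenset({right_end(a), left_end(b)})
                if any(pair not in adj for adj in leaf_adjs):
                    count += 1
        return count


def _draw_root(cfg: SimulationConfig, rng: np.random.Generator):
    chroms: list[list[int]] = []
    lengths: dict[int, int] = {}
    micro: set[int] = set()
    next_id = 1
    for i in range(cfg.n_macro + cfg.n_micro):
        is_micro = i >= cfg.n_macro
        lo, hi = cfg.blocks_per_micro if is_micro else cfg.blocks_per_macro
        n_blocks = int(rng.integers(lo, hi + 1))
        llo, lhi = cfg.micro_block_length if is_micro else cfg.macro_block_length
        chrom = []
        for _ in range(n_blocks):
            lengths[next_id] = int(rng.integers(llo, lhi + 1))
            chrom.append(next_id)
            if is_micro:
                micro.add(next_id)
            next_id += 1
        chroms.append(chrom)
    root = GenomeArrangement.from_lists("root", chroms)
    return root, lengths, frozenset(micro)


class _MutableGenome:
    def __init__(self, genome: GenomeArrangement):
        self.chroms: list[list[int]] = [list(c) for c in genome.chromosomes]

    def arrangement(self, name: str) -> GenomeArrangement:
        return GenomeArrangement.from_lists(name, [c for c in self.chroms if c])

    def adjacency_pairs(self) -> frozenset:
        return adjacencies(self.arrangement("tmp")).adjacencies


def _diff_event(
    branch: str, etype: str, before: frozenset, after: frozenset, step: int,
    n_chroms: int,
) -> EventRecord:
    cut = before - after
    created = after - before
    ends: set[Extremity] = set()
    for pair in cut | created:
        ends.update(pair)
    return EventRecord(
        branch=branch,
        event_type=etype,
        broken_ends=frozenset(ends),
        chroms_involved=frozenset(range(n_chroms)),
        step=step,
        new_adjacencies=frozenset(created),
    )


def _pick_inversion(g: _MutableGenome, rng, reuse_pool, reuse_prob):
    candidates = [ci for ci, c in enumerate(g.chroms) if c]
    weights = np.array([len(g.chroms[ci]) for ci in candidates], dtype=float)
    i = j = 0
    ci = int(rng.choice(candidates, p=weights / weights.sum()))
    chrom = g.chroms[ci]
    n = len(chrom)
    if n == 1:
        return None  # a lone-block flip has no adjacency signature
    use_reuse = reuse_pool and rng.random() < reuse_prob
    if use_reuse:
        pool = sorted(reuse_pool)
        ext = pool[int(rng.integers(len(pool)))]
        loc = _locate(g, ext)
        if loc is not None:
            ci, pos, side = loc
            chrom = g.chroms[ci]
            n = len(chrom)
            if side == "right" and pos + 1 <= n - 1:
                i = pos + 1
                j = int(rng.integers(i, n))
            elif side == "left" and pos - 1 >= 0:
                j = pos - 1
                i = int(rng.integers(0, j + 1))
            else:
                use_reuse = False
        else:
            use_reuse = False
    if not use_reuse:
        i = int(rng.integers(0, n))
        j = int(rng.integers(i, n))
    if i == 0 and j == n - 1:
        # a whole-chromosome flip leaves no adjacency signature; shrink one end
        if rng.random() < 0.5:
            i = 1
        else:
            j = n - 2
    if j < i:
        return None
    return ci, i, j


def _locate(g: _MutableGenome, ext: Extremity):
    bid, side = ext
    for ci, chrom in enumerate(g.chroms):
        for pos, signed in enumerate(chrom):
            if abs(signed) == bid:
                # which genomic side does this extremity face here?
                facing_right = (signed > 0) == (side == "h")
                return ci, pos, ("right" if facing_right else "left")
    return None


def _apply_inversion(g: _MutableGenome, ci: int, i: int, j: int) -> None:
    seg = g.chroms[ci][i : j + 1]
    g.chroms[ci][i : j + 1] = [-s for s in reversed(seg)]


def _pick_two_chromosomes(g: _MutableGenome, rng, micro_blocks, micro_weight):
    live = [ci for ci, c in enumerate(g.chroms) if c]
    if len(live) < 2:
        return None
    pairs = []
    weights = []
    is_micro = [all(abs(s) in micro_blocks for s in g.chroms[ci]) for ci in range(len(g.chroms))]
    for a in range(len(live)):
        for b in range(a + 1, len(live)):
            ca, cb = live[a], live[b]
            pairs.append((ca, cb))
            weights.append(micro_weight if (is_micro[ca] and is_micro[cb]) else 1.0)
    w = np.array(weights) / np.sum(weights)
    k = int(rng.choice(len(pairs), p=w))
    return pairs[k]


def simulate_history(cfg: SimulationConfig | None = None, seed: int | None = None) -> SimulationTruth:
    """Evolve a root karyotype along the tree; returns full ground truth.

    Event counts per branch are Poisson(rate x branch length) per type, or
    uniform in ``events_per_branch_range`` (type then drawn by rate weights).
    Inversion endpoints may reuse previously broken extremities with
    probability ``breakpoint_reuse_prob``.
    """
    cfg = cfg or SimulationConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    tree = cfg.tree or packaged_tree()
    streams = np.random.SeedSequence(cfg.seed).spawn(2)
    rng = np.random.default_rng(streams[0])

    root, lengths, micro = _draw_root(cfg, rng)
    n_blocks = root.n_blocks
    arrangements: dict[str, GenomeArrangement] = {tree.root_label: root}
    event_log: list[EventRecord] = []
    reuse_pool: set[Extremity] = set()
    etypes = sorted(cfg.rates)
    rate_vec = np.array([cfg.rates[t] for t in etypes], dtype=float)

    for parent, child, length in tree.branches():
        g = _MutableGenome(arrangements[parent])
        if cfg.events_per_branch_range is not None:
            lo, hi = cfg.events_per_branch_range
            total = int(rng.integers(lo, hi + 1))
            if rate_vec.sum() == 0:
                total = 0
                draw = []
            else:
                draw = list(rng.choice(etypes, size=total, p=rate_vec / rate_vec.sum()))
        else:
            counts = rng.poisson(rate_vec * length)
            draw = [t for t, c in zip(etypes, counts) for _ in range(int(c))]
            rng.shuffle(draw)
        if len(draw) > 10 * n_blocks:
            raise ValueError(
                f"degenerate configuration: {len(draw)} events on branch {child} "
                f"for {n_blocks} blocks"
            )
        step = 0
        for etype in draw:
            before = g.adjacency_pairs()
            applied = _apply_event(g, etype, rng, micro, cfg, reuse_pool)
            if applied is None:
                continue
            etype_actual, n_chroms = applied
            after = g.adjacency_pairs()
            if after == before:
                continue
            step += 1
            ev = _diff_event(child, etype_actual, before, after, step, n_chroms)
            event_log.append(ev)
            reuse_pool.update(ev.broken_ends)
        arrangements[child] = g.arrangement(child)

    truth = SimulationTruth(cfg, tree, arrangements, event_log, lengths, micro)
    _assert_replay(truth)
    return truth


def _apply_event(g, etype, rng, micro, cfg, reuse_pool):
    if etype == "inversion":
        pick = _pick_inversion(g, rng, reuse_pool, cfg.breakpoint_reuse_prob)
        if pick is None:
            return None
        ci, i, j = pick
        _apply_inversion(g, ci, i, j)
        return "inversion", 1
    if etype == "translocation":
        pick = _pick_two_chromosomes(g, rng, micro, cfg.micro_micro_weight)
        if pick is None:
            return None
        ca, cb = pick
        for _ in range(10):
            pa = int(rng.integers(0, len(g.chroms[ca]) + 1))
            pb = int(rng.integers(0, len(g.chroms[cb]) + 1))
            new_a = g.chroms[ca][:pa] + g.chroms[cb][pb:]
            new_b = g.chroms[cb][:pb] + g.chroms[ca][pa:]
            if new_a and new_b and (pa, pb) not in {(0, 0)}:
                g.chroms[ca], g.chroms[cb] = new_a, new_b
                return "translocation", 2
        return None
    if etype == "fusion":
        pick = _pick_two_chromosomes(g, rng, micro, cfg.micro_micro_weight)
        if pick is None:
            return None
        ca, cb = pick
        tail = g.chroms[cb] if rng.random() < 0.5 else [-s for s in reversed(g.chroms[cb])]
        g.chroms[ca] = g.chroms[ca] + tail
        g.chroms[cb] = []
        return "fusion", 2
    if etype == "fission":
        candidates = [ci for ci, c in enumerate(g.chroms) if len(c) >= 2]
        if not candidates:
            return None
        ci = int(rng.choice(candidates))
        cut = int(rng.integers(1, len(g.chroms[ci])))
        g.chroms.append(g.chroms[ci][cut:])
        g.chroms[ci] = g.chroms[ci][:cut]
        return "fission", 1
    raise ValueError(f"unknown event type {etype!r}")


def _assert_replay(truth: SimulationTruth) -> None:
    root = truth.node_arrangements[truth.tree.root_label]
    for leaf in truth.tree.leaves:
        replayed = replay_scenario(root, truth.lineage_events(leaf), name=leaf)
        if replayed.canonical().chromosomes != truth.node_arrangements[leaf].canonical().chromosomes:
            raise AssertionError(f"event-log replay does not reproduce leaf {leaf}")


# -- emitted tables --------------------------------------------------------

def emit_leaf_tables(
    truth: SimulationTruth, reference_leaf: str
) -> dict[str, list[SyntenyBlock]]:
    """Express every leaf as pairwise synteny blocks on reference coordinates.

    Maximal runs of blocks contiguous and co-oriented in both the target leaf
    and the reference become one block row, exactly as a pairwise synteny map
    presents a target genome against a reference assembly.
    """
    if reference_leaf not in truth.tree.leaves:
        raise KeyError(f"unknown leaf {reference_leaf!r}")
    placement, _ = truth.reference_layout(reference_leaf)
    out: dict[str, list[SyntenyBlock]] = {}
    for leaf in truth.tree.leaves:
        genome = truth.node_arrangements[leaf]
        blocks: list[SyntenyBlock] = []
        for ci, chrom in enumerate(genome.chromosomes):
            tname = f"{leaf}_chr{ci + 1}"
            # target coordinates: cumulative along this chromosome
            tpos = 0
            runs: list[list[tuple[int, int, int]]] = []  # (bid, rel_sign, t_start)
            run: list[tuple[int, int, int]] = []
            prev = None
            for signed in chrom:
                bid = abs(signed)
                sign = 1 if signed > 0 else -1
                rchrom, _, _, rsign, ridx = placement[bid]
                rel = sign * rsign
                item = (bid, rel, tpos)
                if prev is not None:
                    pbid, prel, _ = prev
                    prchrom, _, _, _, pridx = placement[pbid]
                    contiguous = (
                        rchrom == prchrom
                        and rel == prel
                        and ridx == pridx + rel
                    )
                    if not contiguous:
                        runs.append(run)
                        run = []
                run.append(item)
                prev = item
                tpos += truth.block_lengths[bid]
            if run:
                runs.append(run)
            for r in runs:
                bids = [bid for bid, _, _ in r]
                rel = r[0][1]
                rchrom = placement[bids[0]][0]
                ref_lo = min(placement[b][1] for b in bids)
                ref_hi = max(placement[b][2] for b in bids)
                t_lo = r[0][2]
                t_hi = r[-1][2] + truth.block_lengths[bids[-1]]
                blocks.append(
                    SyntenyBlock(
                        species=leaf,
                        ref_chrom=rchrom,
                        ref_start=ref_lo,
                        ref_end=ref_hi,
                        target_chrom=tname,
                        target_start=t_lo,
                        target_end=t_hi,
                        orientation=rel,
                    )
                )
        blocks.sort(key=lambda b: (b.ref_chrom, b.ref_start))
        out[leaf] = blocks
    return out


def simulate_genetic_map(
    truth: SimulationTruth,
    reference_leaf: str,
    marker_spacing: int | None = None,
    hotspot_coupling: float | None = None,
    seed: int | None = None,
) -> list[GeneticMapMarker]:
    """A marker map over reference coordinates with log-normal window rates.

    Per-Mb window rates are log-normal (median ~2.5 cM/Mb); windows containing
    a true breakpoint position have their rate multiplied by
    ``1 + hotspot_coupling``.  Markers are laid every ``marker_spacing`` bp
    with genetic positions accumulated from the window rates.
    """
    cfg = truth.config
    spacing = marker_spacing if marker_spacing is not None else cfg.marker_spacing
    coupling = hotspot_coupling if hotspot_coupling is not None else cfg.hotspot_coupling
    seed_val = seed if seed is not None else cfg.seed
    rng = np.random.default_rng(np.random.SeedSequence((seed_val, 91)))
    _, chrom_lengths = truth.reference_layout(reference_leaf)
    breakpoints = truth.breakpoint_positions(reference_leaf)
    markers: list[GeneticMapMarker] = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        n_windows = max(1, math.ceil(length / 1_000_000))
        rates = rng.lognormal(mean=math.log(2.5), sigma=0.5, size=n_windows)
        if coupling > 0:
            for pos in breakpoints.get(chrom, []):
                rates[min(pos // 1_000_000, n_windows - 1)] *= 1 + coupling
        # cumulative genetic position, piecewise linear per window
        pos = 0
        while pos <= length:
            wi = min(pos // 1_000_000, n_windows - 1)
            full_windows = rates[:wi].sum()
            partial = rates[wi] * (pos - wi * 1_000_000) / 1_000_000
            markers.append(
                GeneticMapMarker(reference_leaf, chrom, int(pos), float(full_windows + partial))
            )
            pos += spacing
    return markers


def simulate_annotations(
    truth: SimulationTruth,
    reference_leaf: str,
    genes_per_chrom: int = 120,
    n_terms: int = 30,
    seeded_term_enrichment: float = 1.0,
    seed: int | None = None,
    seeded_chrom: str | None = None,
) -> tuple[list[GeneAnnotation], tuple[str, str]]:
    """Gene annotations with family structure and an optionally seeded pair.

    Every gene carries two uniformly drawn terms; genes on the designated
    chromosome additionally carry the seeded term with elevated probability
    when ``seeded_term_enrichment > 1``.  About 15% of genes share a family
    with a same-chromosome neighbour, exercising family collapse.  Returns the
    annotations and the (chromosome, term) pair that was seeded.
    """
    if genes_per_chrom <= 0 or n_terms < 0:
        raise ValueError("counts must be positive")
    seed_val = seed if seed is not None else truth.config.seed
    rng = np.random.default_rng(np.random.SeedSequence((seed_val, 137)))
    _, chrom_lengths = truth.reference_layout(reference_leaf)
    chroms = sorted(chrom_lengths)
    target_chrom = seeded_chrom or chroms[0]
    target_term = "term000"
    base_p = 2 / n_terms if n_terms else 0.0
    extra_p = min(1.0, max(0.0, (seeded_term_enrichment - 1.0) * base_p))
    out: list[GeneAnnotation] = []
    fam_counter = 0
    for chrom in chroms:
        prev_family: str | None = None
        for i in range(genes_per_chrom):
            gid = f"{chrom}_g{i:04d}"
            if prev_family is not None and rng.random() < 0.15:
                family = prev_family
            else:
                family = f"fam{fam_counter:05d}"
                fam_counter += 1
            prev_family = family
            if n_terms:
                terms = {f"term{int(t):03d}" for t in rng.choice(n_terms, size=2, replace=False)}
            else:
                terms = set()
            if chrom == target_chrom and extra_p > 0 and rng.random() < extra_p:
                terms.add(target_term)
            out.append(GeneAnnotation(gid, chrom, family, frozenset(terms)))
    return out, (target_chrom, target_term)
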