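"""Tree-guided ancestral arrangement inference and per-branch event counting.

Each internal node's karyotype is assembled from adjacencies: every adjacency
observed in any leaf is scored presence/absence at internal nodes by unit-cost
small parsimony on the rooted tree (ties resolved toward the parent state, and
at the root toward the outgroup's state).  Adjacencies deemed present are then
selected greedily — leaf support first, lexicographic tie-break — under the
constraints that each extremity is used once and no chain closes into a
circle, and chained into CARs (contiguous ancestral regions).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import dendropy

from .genome_io import PhyloTree, ValidationError
from .rearrangement import (
    EventRecord,
    Extremity,
    GenomeArrangement,
    _GenomeState,
    adjacencies,
    dcj_distance,
    sorting_scenario,
)

Adjacency = frozenset  # frozenset[Extremity]


@dataclass
class AncestralReconstruction:
    """Arrangements at every tree node; internal-node chromosomes are CARs."""

    node_arrangements: dict[str, GenomeArrangement]
    support: dict[Adjacency, float]
    tree: PhyloTree
    conflicts: dict[str, list[Adjacency]] = field(default_factory=dict)


@dataclass(frozen=True)
class BranchEventSummary:
    branch: str
    counts: Mapping[str, int]
    branch_length: float
    rate: float

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def _leaf_adjacency_sets(
    leaves: Mapping[str, GenomeArrangement],
) -> dict[str, frozenset[Adjacency]]:
    return {sp: adjacencies(g).adjacencies for sp, g in leaves.items()}


def _parsimony_margins(
    tree: dendropy.Tree,
    leaf_has: Mapping[str, bool],
) -> dict[str, float]:
    """Unit-cost presence/absence parsimony margins at every internal node.

    For each node the margin is ``cost(best labeling with the adjacency
    absent) - cost(best labeling with it present)``: positive means presence
    is required in every most-parsimonious labeling, zero that it is present
    in some but not all of them, negative that it is absent from all.
    Computed by the standard inside/outside dynamic program.
    """
    INF = math.inf
    up: dict[int, tuple[float, float]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            present = leaf_has[node.taxon.label]
            up[id(node)] = (INF, 0.0) if present else (0.0, INF)
        else:
            c0 = c1 = 0.0
            for child in node.child_nodes():
                k0, k1 = up[id(child)]
                c0 += min(k0, k1 + 1)
                c1 += min(k1, k0 + 1)
            up[id(node)] = (c0, c1)
    down: dict[int, tuple[float, float]] = {id(tree.seed_node): (0.0, 0.0)}
    for node in tree.preorder_node_iter():
        d0, d1 = down[id(node)]
        children = node.child_nodes()
        for child in children:
            # parent context for this child: outside cost + other children
            a0, a1 = d0, d1
            for sib in children:
                if sib is child:
                    continue
                k0, k1 = up[id(sib)]
                a0 += min(k0, k1 + 1)
                a1 += min(k1, k0 + 1)
            down[id(child)] = (min(a0, a1 + 1), min(a1, a0 + 1))
    margins: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        k0, k1 = up[id(node)]
        d0, d1 = down[id(node)]
        margins[node.label] = (k0 + d0) - (k1 + d1)
    return margins


def _greedy_matching(ranked: list[Adjacency]) -> tuple[list[Adjacency], list[Adjacency]]:
    """Select a conflict-free, acyclic subset of adjacencies in rank order.

    Each extremity may appear once and no selection may close a chain into a
    circle (union-find over block ids).  Returns (selected, dropped).
    """
    used: set[Extremity] = set()
    comp: dict[int, int] = {}

    def find(x: int) -> int:
        while comp.get(x, x) != x:
            comp[x] = comp.get(comp[x], comp[x])
            x = comp[x]
        return x

    selected: list[Adjacency] = []
    dropped: list[Adjacency] = []
    for adj in ranked:
        a, b = tuple(adj)
        if a in used or b in used:
            dropped.append(adj)
            continue
        ra, rb = find(a[0]), find(b[0])
        if ra == rb:
            dropped.append(adj)
            continue
        comp[ra] = rb
        used.update((a, b))
        selected.append(adj)
    return selected, dropped


def _chain_cars(
    selected: list[Adjacency], block_ids: frozenset[int], name: str
) -> GenomeArrangement:
    partner: dict[Extremity, Extremity] = {}
    for pair in selected:
        a, b = tuple(pair)
        partner[a] = b
        partner[b] = a
    genome = GenomeArrangement.from_lists(name, [[bid] for bid in sorted(block_ids)])
    state = _GenomeState(genome)
    for e, p in partner.items():
        state.partner[e] = p
    return state.to_arrangement(name).canonical()


def reconstruct_ancestors(
    leaves: Mapping[str, GenomeArrangement],
    tree: PhyloTree,
    outgroup: str,
    refine_rounds: int = 10,
) -> AncestralReconstruction:
    """Infer internal-node arrangements (CARs) by adjacency parsimony.

    Presence of every leaf-observed adjacency is scored at each internal node
    by unit-cost small parsimony; mandatory-then-optional candidates are
    chained into CARs under one-use-per-extremity and no-circle constraints,
    and a median-style local search (``refine_rounds`` sweeps) then minimises
    the summed DCJ distance along branches.
    """
    if len(leaves) < 3:
        raise ValidationError("need at least three leaves")
    if outgroup not in leaves:
        raise ValidationError(f"outgroup {outgroup!r} is not a leaf")
    if set(tree.leaves) != set(leaves):
        raise ValidationError("tree leaves and arrangement set differ")
    block_sets = {sp: g.block_ids for sp, g in leaves.items()}
    reference_set = next(iter(block_sets.values()))
    for sp, bs in block_sets.items():
        if bs != reference_set:
            raise ValidationError(
                f"block set of {sp} differs; symmetric difference "
                f"{sorted(bs ^ reference_set)}"
            )

    leaf_adj = _leaf_adjacency_sets(leaves)
    candidates = sorted({adj for s in leaf_adj.values() for adj in s}, key=sorted)
    n_leaves = len(leaves)
    support = {adj: sum(adj in s for s in leaf_adj.values()) / n_leaves for adj in candidates}

    dtree = tree.dendropy_tree
    node_margins: dict[str, dict[Adjacency, float]] = {}
    for adj in candidates:
        leaf_has = {sp: adj in leaf_adj[sp] for sp in leaves}
        for label, margin in _parsimony_margins(dtree, leaf_has).items():
            node_margins.setdefault(label, {})[adj] = margin

    node_arrangements: dict[str, GenomeArrangement] = {
        sp: g.canonical() for sp, g in leaves.items()
    }
    conflicts: dict[str, list[Adjacency]] = {}
    for node in dtree.preorder_node_iter():
        if node.is_leaf():
            continue
        label = node.label
        # mandatory adjacencies (present in every optimal labeling) first,
        # then optional ones (present in some), ranked by leaf support
        present = [adj for adj in candidates if node_margins[label][adj] >= 0]
        present.sort(
            key=lambda adj: (
                0 if node_margins[label][adj] > 0 else 1,
                -support[adj],
                sorted(adj),
            )
        )
        selected, dropped = _greedy_matching(present)
        node_arrangements[label] = _chain_cars(selected, reference_set, label)
        if dropped:
            conflicts[label] = dropped
    recon = AncestralReconstruction(node_arrangements, support, tree, conflicts)
    if refine_rounds:
        _refine_arrangements(recon, refine_rounds)
    return recon


def _refine_arrangements(recon: AncestralReconstruction, max_rounds: int) -> None:
    """Median-style local search: re-select each internal node's adjacencies by
    neighbour vote (parent and children arrangements), accepting a proposal only
    when it lowers the summed DCJ distance to the neighbours.  Deterministic and
    monotone, so it terminates."""
    tree = recon.tree
    arrs = recon.node_arrangements
    support = recon.support
    parent_of = {c: p for p, c, _ in tree.branches()}
    children_of: dict[str, list[str]] = {}
    for p, c, _ in tree.branches():
        children_of.setdefault(p, []).append(c)
    internal = [n for n in arrs if n in children_of]
    block_ids = next(iter(arrs.values())).block_ids

    def neighbours(n: str) -> list[str]:
        out = list(children_of.get(n, []))
        if n in parent_of:
            out.append(parent_of[n])
        return out

    def objective(n: str, arr: GenomeArrangement) -> tuple[int, float]:
        # primary: summed DCJ to neighbours; secondary (to break ties in a
        # leaf-set-stable way): negated total leaf support of the adjacencies
        dist = sum(dcj_distance(arr, arrs[m]) for m in neighbours(n))
        sup = sum(support.get(adj, 0.0) for adj in adjacencies(arr).adjacencies)
        return (dist, -round(sup, 9))

    for _ in range(max_rounds):
        changed = False
        for n in internal:
            votes: dict[Adjacency, int] = {}
            for m in neighbours(n):
                for adj in adjacencies(arrs[m]).adjacencies:
                    votes[adj] = votes.get(adj, 0) + 1
            ranked = sorted(
                votes, key=lambda a: (-votes[a], -support.get(a, 0.0), sorted(a))
            )
            selected, _ = _greedy_matching(ranked)
            proposal = _chain_cars(selected, block_ids, n)
            if objective(n, proposal) < objective(n, arrs[n]):
                arrs[n] = proposal
                changed = True
        if not changed:
            break


def infer_deeper_ancestor(
    recon: AncestralReconstruction, node_a: str, node_b: str
) -> GenomeArrangement | str:
    """Lift a reconstruction one node deeper when two flanking arrangements agree.

    Returns the shared arrangement when the two nodes are identical up to
    chromosome order and flips, else the sentinel string ``"undetermined"``.
    """
    arrs = recon.node_arrangements
    for label in (node_a, node_b):
        if label not in arrs:
            raise KeyError(f"unknown node {label!r}")
    a, b = arrs[node_a], arrs[node_b]
    if a.equivalent(b):
        return a
    return "undetermined"


def count_branch_events(recon: AncestralReconstruction) -> list[BranchEventSummary]:
    """DCJ scenario length per branch, split by event type; rate in events/MY."""
    out = []
    arrs = recon.node_arrangements
    for parent, child, length in recon.tree.branches():
        scenario = sorting_scenario(arrs[parent], arrs[child], branch=child)
        counts: dict[str, int] = {}
        for ev in scenario:
            counts[ev.event_type] = counts.get(ev.event_type, 0) + 1
        total = len(scenario)
        if length > 0:
            rate = total / length
        else:
            rate = math.inf if total else 0.0
            if total:
                warnings.warn(f"zero-length branch {child} carries {total} events")
        out.append(BranchEventSummary(child, counts, length, rate))
    return out


def branch_scenarios(recon: AncestralReconstruction) -> dict[str, list[EventRecord]]:
    """Per-branch DCJ scenarios keyed by the child node label."""
    arrs = recon.node_arrangements
    return {
        child: sorting_scenario(arrs[parent], arrs[child], branch=child)
        for parent, child, _ in recon.tree.branches()
    }


def lineage_scenarios(recon: AncestralReconstruction) -> dict[str, list[EventRecord]]:
    """Root-to-leaf event lists (concatenated branch scenarios) per lineage."""
    per_branch = branch_scenarios(recon)
    out: dict[str, list[EventRecord]] = {}
    parent_of = {child: parent for parent, child, _ in recon.tree.branches()}
    for leaf in recon.tree.leaves:
        path: list[str] = []
        node = leaf
        while node in parent_of:
            path.append(node)
            node = parent_of[node]
        events: list[EventRecord] = []
        for node in reversed(path):
            events.extend(per_branch[node])
        out[leaf] = events
    return out


@dataclass(frozen=True)
class ExclusionResult:
    excluded: str
    car_count: int
    shared_adjacency_fraction: float


def leave_one_out(
    leaves: Mapping[str, GenomeArrangement],
    tree: PhyloTree,
    outgroup: str,
) -> list[ExclusionResult]:
    """Reconstruction robustness to dropping one species at a time.

    For each non-outgroup species, the reconstruction is repeated without it
    and the root ancestor compared with the all-species root by the fraction
    of its adjacencies retained.
    """
    if len(leaves) < 4:
        raise ValidationError("need at least four leaves for leave-one-out")
    full = reconstruct_ancestors(leaves, tree, outgroup)
    root = tree.root_label
    full_adj = adjacencies(full.node_arrangements[root]).adjacencies
    out = []
    for sp in sorted(leaves):
        if sp == outgroup:
            continue
        subset = {s: g for s, g in leaves.items() if s != sp}
        sub_tree = tree.pruned(sp)
        sub = reconstruct_ancestors(subset, sub_tree, outgroup)
        sub_root_arr = sub.node_arrangements[sub_tree.root_label]
        sub_adj = adjacencies(sub_root_arr).adjacencies
        frac = len(full_adj & sub_adj) / len(full_adj) if full_adj else 1.0
        out.append(ExclusionResult(sp, len(sub_root_arr.chromosomes), frac))
    return out


def exclude_outgroup_guard(excluded: str, outgroup: str) -> None:
    if excluded == outgroup:
        raise ValidationError("cannot exclude the outgroup; choose an alternate outgroup first")
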