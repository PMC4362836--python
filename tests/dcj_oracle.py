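"""Independent breadth-first-search oracle over single-DCJ moves.

States are adjacency sets (telomeres implicit); moves enumerate every double
cut and join: cutting one or two adjacencies, rejoining with each other or
with telomeric extremities, and joining two telomeres.  Used to verify the
closed-form DCJ distance on every small instance.
"""

import itertools
from collections import deque


def neighbours(state, n_blocks):
    paired = {e for p in state for e in p}
    exts = [(b, s) for b in range(1, n_blocks + 1) for s in ("t", "h")]
    tels = [e for e in exts if e not in paired]
    out = set()
    for p in state:  # cut one adjacency
        out.add(state - {p})
    for x, y in itertools.combinations(tels, 2):  # join two telomeres
        out.add(state | {frozenset({x, y})})
    for p in state:  # adjacency + telomere
        a, b = tuple(p)
        for t in tels:
            out.add((state - {p}) | {frozenset({a, t})})
            out.add((state - {p}) | {frozenset({b, t})})
    for p, q in itertools.combinations(state, 2):  # two adjacencies
        a, b = tuple(p)
        c, d = tuple(q)
        base = state - {p, q}
        out.add(base | {frozenset({a, c}), frozenset({b, d})})
        out.add(base | {frozenset({a, d}), frozenset({b, c})})
    out.discard(state)
    return out


def bfs_distance(src, dst, n_blocks):
    """Shortest number of single DCJ moves from one adjacency set to another."""
    if src == dst:
        return 0
    seen = {src}
    queue = deque([(src, 0)])
    while queue:
        state, d = queue.popleft()
        for nxt in neighbours(state, n_blocks):
            if nxt == dst:
                return d + 1
            if nxt not in seen:
                seen.add(nxt)
                queue.append((nxt, d + 1))
    raise RuntimeError("state space exhausted without reaching the target")


def bfs_distances_from(src, n_blocks):
    """Distances from ``src`` to every reachable adjacency-set state."""
    dist = {src: 0}
    queue = deque([src])
    while queue:
        state = queue.popleft()
        for nxt in neighbours(state, n_blocks):
            if nxt not in dist:
                dist[nxt] = dist[state] + 1
                queue.append(nxt)
    return dist


def enumerate_linear_genomes(n_blocks, max_chroms=2):
    """All linear genomes over blocks 1..n with at most ``max_chroms``
    chromosomes, one representative per reverse-complement class."""
    from karyograph.rearrangement import GenomeArrangement

    out = []
    seen = set()
    ids = list(range(1, n_blocks + 1))

    def signed_orders(items):
        for perm in itertools.permutations(items):
            for signs in itertools.product((1, -1), repeat=len(items)):
                yield tuple(s * b for s, b in zip(signs, perm))

    def add(chroms):
        g = GenomeArrangement("g", tuple(chroms))
        key = g.canonical().chromosomes
        if key not in seen:
            seen.add(key)
            out.append(g)

    for order in signed_orders(ids):
        add([order])
    if max_chroms >= 2 and n_blocks >= 2:
        for k in range(1, n_blocks):
            for subset in itertools.combinations(ids, k):
                rest = tuple(b for b in ids if b not in subset)
                for o1 in signed_orders(subset):
                    for o2 in signed_orders(rest):
                        add([o1, o2])
    return out
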