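"""Independent brute-force oracles used to validate the implementation.

These deliberately re-derive expected values by exhaustive enumeration or
naive algorithms, sharing as little code as possible with the package
(translation goes through Bio.Seq, chains and linkages are enumerated
recursively).
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from Bio.Seq import Seq

NUCS = "ACGT"


def aa_of(codon: str) -> str:
    return str(Seq(codon).translate())


def ng86_sites_oracle(codon: str) -> float:
    """Synonymous site count by explicit enumeration of the 9 changes."""
    total = 0.0
    for pos in range(3):
        syn = nonstop = 0
        for nt in NUCS:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1:]
            if aa_of(alt) == "*":
                continue
            nonstop += 1
            if aa_of(alt) == aa_of(codon):
                syn += 1
        if nonstop:
            total += syn / nonstop
    return total


def ng86_differences_oracle(ca: str, cb: str) -> tuple[float, float]:
    """Pathway-averaged (Sd, Nd) by enumerating substitution orders."""
    diffs = [i for i in range(3) if ca[i] != cb[i]]
    if not diffs:
        return 0.0, 0.0
    complete, partial = [], []
    for order in permutations(diffs):
        cur, syn, nsyn, hit_stop = ca, 0.0, 0.0, False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if aa_of(nxt) == "*" and nxt != cb:
                hit_stop = True
            if aa_of(cur) != "*" and aa_of(nxt) != "*":
                if aa_of(cur) == aa_of(nxt):
                    syn += 1
                else:
                    nsyn += 1
            cur = nxt
        (partial if hit_stop else complete).append((syn, nsyn))
    chosen = complete or partial
    return (sum(p[0] for p in chosen) / len(chosen),
            sum(p[1] for p in chosen) / len(chosen))


def window_score_oracle(columns: np.ndarray, background_len: int,
                        aa_index: dict[str, int], protein: str) -> float:
    """Best gapless window by trying every offset with plain loops."""
    L = len(columns)
    n = len(protein)
    best = None
    for offset in range(-(L - 1), n):
        s = 0.0
        for i in range(L):
            p = offset + i
            if 0 <= p < n:
                j = aa_index.get(protein[p].upper())
                if j is not None:
                    s += columns[i][j]
        if best is None or s > best:
            best = s
    return best


def longest_chain_oracle(points: list[tuple[int, int, int]], u: int,
                         inverted: bool) -> tuple[int, ...]:
    """Exhaustive longest chain under the anchor-ordinal gap rule.

    Returns the anchor-index tuple of the maximum-length chain, ties
    broken by lexicographically smallest index sequence.
    """
    best: list[tuple[int, ...]] = []

    def extend(chain: list[tuple[int, int, int]]):
        last = chain[-1]
        extended = False
        for p in points:
            if p is last or p in chain:
                continue
            da = p[0] - last[0]
            db = (last[1] - p[1]) if inverted else (p[1] - last[1])
            if 1 <= da <= u + 1 and 1 <= db <= u + 1:
                extend(chain + [p])
                extended = True
        if not extended:
            best.append(tuple(c[2] for c in chain))

    for p in points:
        extend([p])
    if not best:
        return ()
    max_len = max(len(b) for b in best)
    return min(b for b in best if len(b) == max_len)


def greedy_blocks_oracle(points: list[tuple[int, int, int]], u: int,
                         min_block: int) -> list[tuple[str, tuple[int, ...]]]:
    """Greedy longest-first block extraction with the exhaustive chain oracle."""
    live = list(points)
    blocks = []
    while live:
        cands = []
        for inverted in (False, True):
            chain = longest_chain_oracle(live, u, inverted)
            cands.append((len(chain), not inverted, chain))
        cands.sort(key=lambda c: (-c[0], not c[1], c[2]))
        length, same, chain = cands[0]
        if length < min_block:
            break
        blocks.append(("same" if same else "inverted", chain))
        used = set(chain)
        live = [p for p in live if p[2] not in used]
    return blocks


def complete_linkage_oracle(d: np.ndarray) -> list[float]:
    """Merge heights of naive complete-linkage agglomeration."""
    clusters = [{i} for i in range(len(d))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                h = max(d[a][b] for a in clusters[i] for b in clusters[j])
                if best is None or h < best[0]:
                    best = (h, i, j)
        h, i, j = best
        heights.append(h)
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return heights


def random_additive_tree(rng, n_taxa: int):
    """Random binary tree by sequential edge attachment; returns (edges,
    distance matrix dict, labels). Edges are (node, node, length)."""
    labels = [f"t{i}" for i in range(n_taxa)]
    # adjacency with branch lengths; internal node ids are negative ints
    edges: dict[tuple, float] = {}
    next_internal = -1

    def add_edge(a, b, ln):
        edges[(a, b)] = ln
        edges[(b, a)] = ln

    def drop_edge(a, b):
        del edges[(a, b)]
        del edges[(b, a)]

    ln = lambda: float(rng.uniform(0.1, 1.0))
    center = next_internal
    next_internal -= 1
    for lab in labels[:3]:
        add_edge(center, lab, ln())
    for lab in labels[3:]:
        pairs = [k for k in edges if str(k[0]) < str(k[1])]
        a, b = pairs[int(rng.integers(len(pairs)))]
        mid = next_internal
        next_internal -= 1
        old = edges[(a, b)]
        drop_edge(a, b)
        split = float(rng.uniform(0.2, 0.8))
        add_edge(a, mid, old * split)
        add_edge(mid, b, old * (1 - split))
        add_edge(mid, lab, ln())

    # path distances by BFS
    def dist_from(src):
        out = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for (p, q), w in edges.items():
                if p == x and q not in out:
                    out[q] = out[x] + w
                    stack.append(q)
        return out

    dmat = {}
    for a in labels:
        da = dist_from(a)
        for b in labels:
            if (b, a) in dmat:
                dmat[(a, b)] = dmat[(b, a)]   # exact symmetry
            else:
                dmat[(a, b)] = da[b]
    return edges, dmat, labels


def tree_bipartitions(edges, labels) -> set[frozenset]:
    """Non-trivial unrooted bipartitions of an edge-list tree."""
    label_set = set(labels)
    parts = set()
    seen = set()
    for (a, b) in edges:
        if (b, a) in seen:
            continue
        seen.add((a, b))
        # leaves on the b-side when edge (a,b) is cut
        side = set()
        stack = [b]
        visited = {a, b}
        while stack:
            x = stack.pop()
            if isinstance(x, str):
                side.add(x)
            for (p, q) in edges:
                if p == x and q not in visited:
                    visited.add(q)
                    stack.append(q)
        if 1 < len(side) < len(label_set) - 1:
            parts.add(frozenset({frozenset(side),
                                 frozenset(label_set - side)}))
    return parts


def treenode_bipartitions(tree, labels) -> set[frozenset]:
    """Non-trivial unrooted bipartitions of a scikit-bio TreeNode."""
    label_set = set(labels)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if 1 < len(side) < len(label_set) - 1:
            parts.add(frozenset({frozenset(side),
                                 frozenset(label_set - side)}))
    return parts
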