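"""Distance-based phylogenetics: p-distances, neighbor joining, clade summaries.

Neighbor joining (Saitou & Nei 1987, with Studier–Keppler distance
updates) on protein p-distances serves as the desk-scale reconstruction
method; externally computed maximum-likelihood trees can be loaded from
Newick and annotated with the same clade summaries. Trees are scikit-bio
``TreeNode`` objects throughout, so Newick round-trips come for free.
"""

from __future__ import annotations

import io
import logging

import numpy as np
from skbio import DistanceMatrix, TreeNode

logger = logging.getLogger(__name__)


def p_distance_matrix(alignment: dict[str, str]) -> DistanceMatrix:
    """Pairwise p-distances over columns where neither sequence is gapped."""
    if len(alignment) < 3:
        raise ValueError("need at least 3 sequences")
    labels = sorted(alignment)
    lengths = {len(alignment[x]) for x in labels}
    if len(lengths) != 1:
        raise ValueError("sequences differ in aligned length")
    seqs = [np.frombuffer(alignment[x].upper().encode(), dtype="S1") for x in labels]
    gap = np.bytes_("-")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (seqs[i] != gap) & (seqs[j] != gap)
            m = int(ok.sum())
            if m == 0:
                logger.warning("no comparable columns for %s/%s; distance 1",
                               labels[i], labels[j])
                d[i, j] = d[j, i] = 1.0
            else:
                diff = int((seqs[i][ok] != seqs[j][ok]).sum())
                d[i, j] = d[j, i] = diff / m
    return DistanceMatrix(d, ids=labels)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Canonical neighbor joining with deterministic tie-breaking.

    The Q criterion picks the pair to join; ties go to the smallest
    (label, label) pair. Negative branch lengths are clamped to zero with
    the deficit moved to the sister branch. Returns an unrooted tree (the
    root is the final trifurcation).
    """
    d = np.asarray(dm.data, dtype=float)
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix not symmetric")
    labels = list(dm.ids)
    nodes = [TreeNode(name=lab) for lab in labels]
    # canonical label of each live node for tie-breaking
    canon = list(labels)
    while len(nodes) > 3:
        n = len(nodes)
        row_sums = d.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - row_sums[i] - row_sums[j]
                key = (q, *sorted((canon[i], canon[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = d[i, j]
        bi = 0.5 * dij + (row_sums[i] - row_sums[j]) / (2 * (n - 2))
        bj = dij - bi
        # clamp negatives, moving the deficit to the sister branch
        if bi < 0:
            bj += bi
            bi = 0.0
        if bj < 0:
            bi += bj
            bj = 0.0
        bi, bj = max(bi, 0.0), max(bj, 0.0)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = bi
        child_j.length = bj
        new = TreeNode(children=[child_i, child_j])
        new_d = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(n) if k not in (i, j)]
        d2 = np.zeros((len(keep) + 1, len(keep) + 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = new_d[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [new]
        canon = [canon[k] for k in keep] + [min(canon[i], canon[j])]
    if len(nodes) == 3:
        d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
        b0 = max(0.0, (d01 + d02 - d12) / 2)
        b1 = max(0.0, (d01 + d12 - d02) / 2)
        b2 = max(0.0, (d02 + d12 - d01) / 2)
        for node, b in zip(nodes, (b0, b1, b2)):
            node.length = b
        return TreeNode(children=nodes)
    if len(nodes) == 2:
        nodes[0].length = 0.0
        nodes[1].length = d[0, 1]
        return TreeNode(children=nodes)
    return nodes[0]


def annotate_clades(tree: TreeNode, subfamily: dict[str, str]) -> dict[str, dict]:
    """Smallest clade containing each subfamily and its monophyly fraction.

    A leaf missing from ``subfamily`` is labelled "species-specific".
    Fraction = (subfamily members in the clade) / (clade leaf count).
    """
    leaf_label = {leaf.name: subfamily.get(leaf.name, "species-specific")
                  for leaf in tree.tips()}
    out: dict[str, dict] = {}
    for label in sorted(set(leaf_label.values())):
        members = sorted(n for n, lab in leaf_label.items() if lab == label)
        if len(members) == 1:
            out[label] = {"members": 1, "clade_size": 1, "fraction": 1.0}
            continue
        lca = tree.lca(members)
        clade = [t.name for t in lca.tips()]
        out[label] = {
            "members": len(members),
            "clade_size": len(clade),
            "fraction": len(members) / len(clade),
        }
    return out


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def tree_to_newick_string(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
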