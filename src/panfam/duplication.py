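"""Gene duplication analysis: tandem arrays, synteny blocks, copy retention.

Tandem arrays are runs of mutually similar genes on one chromosome, found
by single-linkage clustering of similar gene pairs on gene-rank distance
(a hard rank cutoff makes single linkage the transitive closure of
near-adjacent similar pairs, which is exactly the tandem-array notion).

Synteny blocks between a target genome and an outgroup are chained from
anchor pairs with MCScan-style parameters: E-value cutoff e, maximum
skipped anchors u, and minimum block size s. Each ancestral (outgroup)
gene's copy number in the target genome — the footprint of the Solanum
whole-genome triplication followed by fractionation — is the number of
distinct block regions in which it anchors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .pangene import SimilarityEdge, round_half_up

logger = logging.getLogger(__name__)


@dataclass
class GeneModel:
    """One gene model (one mRNA) with genomic position and sequences."""

    gene_id: str
    genome_id: str
    chrom: str
    start: int               # 1-based inclusive
    end: int
    strand: str = "+"
    locus_id: str = ""
    protein: str = ""
    cds: str = ""
    rank: int = -1           # position index within (genome, chrom), set later

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if not self.locus_id:
            logger.warning("%s: missing locus_id; treated as its own locus",
                           self.gene_id)
            self.locus_id = self.gene_id


def assign_ranks(genes: list[GeneModel]) -> list[GeneModel]:
    """Recompute 0-based ranks per (genome, chrom), sorted by (start, gene_id)."""
    by_chrom: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault((g.genome_id, g.chrom), []).append(g)
    out = []
    for key in sorted(by_chrom):
        chrom_genes = sorted(by_chrom[key], key=lambda g: (g.start, g.gene_id))
        for r, g in enumerate(chrom_genes):
            out.append(replace(g, rank=r))
    return out


def filter_isoforms(genes: list[GeneModel]) -> list[GeneModel]:
    """One gene model per locus: longest CDS, ties by smallest gene_id."""
    by_locus: dict[tuple[str, str], GeneModel] = {}
    for g in genes:
        key = (g.genome_id, g.locus_id)
        cur = by_locus.get(key)
        # longer CDS wins; on equal length the smaller gene_id wins
        if cur is None or len(g.cds) > len(cur.cds) or (
            len(g.cds) == len(cur.cds) and g.gene_id < cur.gene_id
        ):
            by_locus[key] = g
    return assign_ranks(list(by_locus.values()))


@dataclass
class TandemArray:
    array_id: str
    genome_id: str
    chrom: str
    members: list[str]       # gene ids ordered by rank

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("tandem array needs >= 2 members")


def detect_tandem_arrays(
    genes: list[GeneModel],
    edges: list[SimilarityEdge],
    evalue_cut: float = 1e-20,
    max_rank_gap: int = 5,
    distance: str = "rank",
    max_bp_gap: int = 100_000,
) -> list[TandemArray]:
    """Single-linkage tandem clusters of similar same-chromosome genes.

    A similar pair (E-value <= cutoff) on one chromosome links its genes
    when their rank distance is <= ``max_rank_gap`` (or, with
    ``distance="bp"``, when their start positions differ by <=
    ``max_bp_gap``); clusters of size >= 2 become arrays, members ordered
    by rank.
    """
    if evalue_cut <= 0:
        raise ValueError("evalue_cut must be > 0")
    if distance not in ("rank", "bp"):
        raise ValueError("distance must be 'rank' or 'bp'")
    by_id = {g.gene_id: g for g in genes}
    parent = {gid: gid for gid in by_id}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in edges:
        a, b = by_id.get(e.gene_a), by_id.get(e.gene_b)
        if a is None or b is None or e.evalue > evalue_cut:
            continue
        if a.genome_id != b.genome_id or a.chrom != b.chrom:
            continue
        if distance == "rank":
            close = abs(a.rank - b.rank) <= max_rank_gap
        else:
            close = abs(a.start - b.start) <= max_bp_gap
        if close:
            parent[find(a.gene_id)] = find(b.gene_id)

    clusters: dict[str, list[GeneModel]] = {}
    for gid in by_id:
        clusters.setdefault(find(gid), []).append(by_id[gid])
    arrays = []
    for members in clusters.values():
        if len(members) < 2:
            continue
        members.sort(key=lambda g: g.rank)
        arrays.append((members[0].genome_id, members[0].chrom,
                       members[0].rank, [g.gene_id for g in members]))
    arrays.sort()
    return [
        TandemArray(f"{genome}.{chrom}.TA{i:04d}", genome, chrom, members)
        for i, (genome, chrom, _, members) in enumerate(arrays)
    ]


@dataclass
class SyntenyBlock:
    block_id: str
    genome_a: str
    genome_b: str
    chrom_a: str
    chrom_b: str
    anchors: list[tuple[str, str]]    # (gene_a, gene_b) ordered along genome a
    orientation: str                  # "same" | "inverted"

    @property
    def score(self) -> int:
        return len(self.anchors)


def _chain_once(points: list[tuple[int, int, int]], u: int, inverted: bool):
    """Longest anchor chain by DP over anchor-ordinal points.

    ``points`` are (pos_a, pos_b, anchor_index) with pos strictly ordered
    anchor ordinals. Consecutive chain members must advance 1..u+1 ordinals
    on both axes (pos_b descending when ``inverted``). Ties prefer the
    lexicographically smallest anchor-index sequence.
    """
    order = sorted(points, key=lambda p: (p[0], -p[1] if inverted else p[1], p[2]))
    n = len(order)
    best_len = [1] * n
    best_chain: list[tuple[int, ...]] = [(order[i][2],) for i in range(n)]
    for i in range(n):
        ai, bi, _ = order[i]
        for j in range(i):
            aj, bj, _ = order[j]
            da = ai - aj
            db = (bj - bi) if inverted else (bi - bj)
            if 1 <= da <= u + 1 and 1 <= db <= u + 1:
                cand_len = best_len[j] + 1
                cand = best_chain[j] + (order[i][2],)
                if cand_len > best_len[i] or (
                    cand_len == best_len[i] and cand < best_chain[i]
                ):
                    best_len[i] = cand_len
                    best_chain[i] = cand
    # choose max length; among equals the lexicographically smallest chain
    best = max(best_len)
    cands = [best_chain[i] for i in range(n) if best_len[i] == best]
    return min(cands)


def chain_collinear_blocks(
    anchor_pairs: list[SimilarityEdge],
    genes_a: list[GeneModel],
    genes_b: list[GeneModel],
    evalue_cut: float = 1e-20,
    max_gaps: int = 1,
    min_block: int = 5,
) -> list[SyntenyBlock]:
    """Chain anchors into collinear blocks (MCScan-style e/u/s parameters).

    Per chromosome pair, anchors are placed at their ordinals among
    anchor-participating genes on each chromosome; chains advance at most
    ``max_gaps`` skipped anchors (ordinal gap <= u+1) on both genomes, in
    either orientation. Maximal chains are reported greedily (longest
    first, anchors removed once used); chains shorter than ``min_block``
    are discarded.
    """
    if max_gaps < 0 or min_block < 2:
        raise ValueError("require u >= 0 and s >= 2")
    a_by_id = {g.gene_id: g for g in genes_a}
    b_by_id = {g.gene_id: g for g in genes_b}
    genome_a = genes_a[0].genome_id if genes_a else "A"
    genome_b = genes_b[0].genome_id if genes_b else "B"

    # orient each edge as (gene in genome a, gene in genome b)
    anchors: list[tuple[GeneModel, GeneModel]] = []
    for e in anchor_pairs:
        if e.evalue > evalue_cut:
            continue
        if e.gene_a in a_by_id and e.gene_b in b_by_id:
            anchors.append((a_by_id[e.gene_a], b_by_id[e.gene_b]))
        elif e.gene_b in a_by_id and e.gene_a in b_by_id:
            anchors.append((a_by_id[e.gene_b], b_by_id[e.gene_a]))

    by_pair: dict[tuple[str, str], list[tuple[GeneModel, GeneModel]]] = {}
    for ga, gb in anchors:
        by_pair.setdefault((ga.chrom, gb.chrom), []).append((ga, gb))

    blocks = []
    for (chrom_a, chrom_b), pair_anchors in sorted(by_pair.items()):
        # anchor ordinals: position among anchor-participating genes
        ranks_a = {gid: i for i, gid in enumerate(
            sorted({ga.gene_id for ga, _ in pair_anchors},
                   key=lambda gid: a_by_id[gid].rank))}
        ranks_b = {gid: i for i, gid in enumerate(
            sorted({gb.gene_id for _, gb in pair_anchors},
                   key=lambda gid: b_by_id[gid].rank))}
        pair_anchors.sort(key=lambda p: (ranks_a[p[0].gene_id], ranks_b[p[1].gene_id]))
        live = list(range(len(pair_anchors)))
        while live:
            pts = [(ranks_a[pair_anchors[i][0].gene_id],
                    ranks_b[pair_anchors[i][1].gene_id], i) for i in live]
            candidates = []
            for inverted in (False, True):
                chain = _chain_once(pts, max_gaps, inverted)
                candidates.append((len(chain), not inverted, chain))
            candidates.sort(key=lambda c: (-c[0], not c[1], c[2]))
            length, same, chain = candidates[0]
            if length < min_block:
                break
            blocks.append((chrom_a, chrom_b, "same" if same else "inverted",
                           [pair_anchors[i] for i in chain]))
            used = set(chain)
            live = [i for i in live if i not in used]

    blocks.sort(key=lambda b: (b[0], b[1], b[3][0][0].rank))
    return [
        SyntenyBlock(
            block_id=f"BL{i:04d}",
            genome_a=genome_a, genome_b=genome_b,
            chrom_a=ca, chrom_b=cb,
            anchors=[(ga.gene_id, gb.gene_id) for ga, gb in members],
            orientation=orient,
        )
        for i, (ca, cb, orient, members) in enumerate(blocks)
    ]


def classify_copy_retention(
    blocks: list[SyntenyBlock],
    outgroup_genes: list[GeneModel],
) -> dict[str, int]:
    """Copy number of each outgroup gene in the target genome.

    Count of distinct target block regions anchoring the gene; blocks on
    one target chromosome whose target rank spans overlap count once.
    Genes absent from every block get 0.
    """
    outgroup_ids = {g.gene_id for g in outgroup_genes}
    # target side of each block is the side NOT in the outgroup; a block's
    # target region is its target chromosome plus the lexical span of its
    # target gene ids' positions within the block
    block_region: dict[str, tuple[str, tuple[str, ...]]] = {}
    hits: dict[str, list[str]] = {g: [] for g in outgroup_ids}
    for b in blocks:
        a_is_out = all(a in outgroup_ids for a, _ in b.anchors)
        target_chrom = b.chrom_b if a_is_out else b.chrom_a
        tgt_ids = tuple(sorted(
            (t for _, t in b.anchors) if a_is_out else (t for t, _ in b.anchors)))
        block_region[b.block_id] = (target_chrom, tgt_ids)
        for (x, y) in b.anchors:
            og = x if a_is_out else y
            if og in hits:
                hits[og].append(b.block_id)
    out = {}
    for g in sorted(outgroup_ids):
        # merge blocks on one target chromosome whose target gene sets overlap
        by_chrom: dict[str, list[set[str]]] = {}
        for bid in set(hits[g]):
            chrom, tgt_ids = block_region[bid]
            by_chrom.setdefault(chrom, []).append(set(tgt_ids))
        count = 0
        for chrom, regions in by_chrom.items():
            merged: list[set[str]] = []
            for reg in regions:
                overlapping = [m for m in merged if m & reg]
                for m in overlapping:
                    reg |= m
                    merged.remove(m)
                merged.append(reg)
            count += len(merged)
        out[g] = count
    return out


def attribute_duplication_origin(
    genes: list[GeneModel],
    arrays: list[TandemArray],
    blocks: list[SyntenyBlock],
    retention: dict[str, int],
    outgroup_ids: set[str],
) -> dict[str, str]:
    """Per-gene duplication origin: TD, WGT, both, or none.

    TD: member of any tandem array. WGT: anchor in a synteny block whose
    outgroup partner retains >= 2 copies.
    """
    gene_ids = {g.gene_id for g in genes}
    td_genes = set()
    for arr in arrays:
        for m in arr.members:
            if m not in gene_ids:
                raise ValueError(f"array member {m} absent from gene set")
            td_genes.add(m)
    wgt_genes = set()
    for b in blocks:
        for x, y in b.anchors:
            if x in outgroup_ids and retention.get(x, 0) >= 2 and y in gene_ids:
                wgt_genes.add(y)
            elif y in outgroup_ids and retention.get(y, 0) >= 2 and x in gene_ids:
                wgt_genes.add(x)
    out = {}
    for g in sorted(gene_ids):
        td, wgt = g in td_genes, g in wgt_genes
        out[g] = "both" if td and wgt else "TD" if td else "WGT" if wgt else "none"
    return out


def origin_summary(
    origins: dict[str, str],
    group_of_gene: dict[str, str],
) -> dict[str, dict[str, float]]:
    """Per-group percentage of genes with each origin, two-decimal half-up."""
    groups: dict[str, list[str]] = {}
    for g, lab in origins.items():
        groups.setdefault(group_of_gene.get(g, "NA"), []).append(lab)
    out = {}
    for grp, labels in sorted(groups.items()):
        n = len(labels)
        out[grp] = {
            origin: round_half_up(100 * sum(1 for x in labels if x in where) / n, 2)
            for origin, where in (
                ("TD", {"TD", "both"}),
                ("WGT", {"WGT", "both"}),
                ("none", {"none"}),
            )
        }
        out[grp]["n"] = n
    return out


def write_collinearity(blocks: list[SyntenyBlock], path) -> None:
    """MCScanX .collinearity-style text export."""
    with open(path, "w") as fh:
        fh.write("############### collinear blocks ###############\n")
        for b in blocks:
            sign = "plus" if b.orientation == "same" else "minus"
            fh.write(f"## Alignment {b.block_id}: score={b.score} "
                     f"{b.chrom_a}&{b.chrom_b} {sign}\n")
            for i, (ga, gb) in enumerate(b.anchors):
                fh.write(f"{b.block_id}-{i:3d}:\t{ga}\t{gb}\n")
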