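"""Readers and writers for the standard flat formats the pipeline consumes:
protein/CDS FASTA, GFF3 gene models, BLAST outfmt-6 hit tables, and the
toolkit's own TSV products. Coordinates are 1-based inclusive throughout,
as in GFF3.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .duplication import GeneModel, assign_ranks
from .pangene import SimilarityEdge

logger = logging.getLogger(__name__)

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=k, description="") for k, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def _validate_gff3_lines(path) -> None:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, "
                                 f"got {len(fields)}")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start > end or start < 1:
                raise ValueError(f"{path}:{lineno}: invalid span {start}..{end}")


def read_gff3(
    path,
    genome_id: str,
    proteins: dict[str, str] | None = None,
    cds: dict[str, str] | None = None,
) -> list[GeneModel]:
    """Parse gene/mRNA/CDS features into one GeneModel per mRNA.

    The mRNA's Parent gene id becomes the locus id (isoforms share it);
    protein and CDS sequences are attached by mRNA id when given. Ranks
    are assigned deterministically by (chrom, start, gene_id).
    """
    _validate_gff3_lines(path)
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    genes = []
    for mrna in db.features_of_type("mRNA"):
        parents = mrna.attributes.get("Parent", [])
        if not parents:
            logger.warning("mRNA %s has no Parent; treated as its own locus",
                           mrna.id)
        locus = parents[0] if parents else mrna.id
        genes.append(GeneModel(
            gene_id=mrna.id,
            genome_id=genome_id,
            chrom=mrna.seqid,
            start=mrna.start,
            end=mrna.end,
            strand=mrna.strand if mrna.strand in "+-" else "+",
            locus_id=locus,
            protein=(proteins or {}).get(mrna.id, ""),
            cds=(cds or {}).get(mrna.id, ""),
        ))
    return assign_ranks(genes)


def write_gff3(genes: list[GeneModel], path) -> None:
    """Emit gene/mRNA/CDS rows, one locus per gene id group."""
    by_locus: dict[tuple[str, str], list[GeneModel]] = {}
    for g in genes:
        by_locus.setdefault((g.chrom, g.locus_id), []).append(g)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for (chrom, locus), models in sorted(
            by_locus.items(), key=lambda kv: (kv[0][0], min(m.start for m in kv[1]))
        ):
            start = min(m.start for m in models)
            end = max(m.end for m in models)
            strand = models[0].strand
            fh.write(f"{chrom}\tpanfam\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
                     f"ID={locus}\n")
            for m in sorted(models, key=lambda x: x.gene_id):
                fh.write(f"{chrom}\tpanfam\tmRNA\t{m.start}\t{m.end}\t.\t"
                         f"{m.strand}\t.\tID={m.gene_id};Parent={locus}\n")
                fh.write(f"{chrom}\tpanfam\tCDS\t{m.start}\t{m.end}\t.\t"
                         f"{m.strand}\t0\tID={m.gene_id}.cds;Parent={m.gene_id}\n")


def read_blast6(path) -> list[SimilarityEdge]:
    """Read a 12-column BLAST outfmt-6 table into undirected edges.

    Self-hits are dropped; reciprocal duplicates merge keeping the best
    bitscore (and its E-value).
    """
    with open(path) as fh:
        rows = []
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, "
                                 f"got {len(fields)}")
            rows.append(fields)
    best: dict[tuple[str, str], tuple[float, float]] = {}
    for fields in rows:
        q, s = fields[0], fields[1]
        if q == s:
            continue
        evalue, bitscore = float(fields[10]), float(fields[11])
        key = (min(q, s), max(q, s))
        cur = best.get(key)
        if cur is None or bitscore > cur[0] or (
            bitscore == cur[0] and evalue < cur[1]
        ):
            best[key] = (bitscore, evalue)
    return [SimilarityEdge(a, b, bitscore=bs, evalue=ev)
            for (a, b), (bs, ev) in sorted(best.items())]


def write_blast6(edges: list[SimilarityEdge], path) -> None:
    """Minimal outfmt-6 export (placeholder alignment columns)."""
    with open(path, "w") as fh:
        for e in sorted(edges, key=lambda e: (e.gene_a, e.gene_b)):
            fh.write(f"{e.gene_a}\t{e.gene_b}\t100.00\t100\t0\t0\t1\t100\t1\t100\t"
                     f"{e.evalue:.2e}\t{e.bitscore:.1f}\n")


def read_groups_tsv(path) -> dict[str, tuple[str, int]]:
    """genome_id -> (group label, group order) from a 3-column TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "group": str,
                                            "group_order": int})
    return {r.genome_id: (r.group, int(r.group_order)) for r in df.itertuples()}


def write_groups_tsv(groups: dict[str, tuple[str, int]], path) -> None:
    df = pd.DataFrame(
        [(g, lab, order) for g, (lab, order) in sorted(groups.items())],
        columns=["genome_id", "group", "group_order"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_pav_tsv(pav, path) -> None:
    pav.presence.to_csv(path, sep="\t")


def read_pav_tsv(path, groups: dict[str, tuple[str, int]]):
    from .pangene import PAVMatrix
    df = pd.read_csv(path, sep="\t", index_col=0)
    return PAVMatrix(df, groups)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
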