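"""End-to-end pan-gene-family pipeline over a directory of genome inputs.

Stage order: family identification -> isoform filtering -> orthogroup
clustering -> presence/absence classification and group-frequency trends
-> tandem arrays -> synteny/copy retention against the outgroup -> Ka/Ks
with stratified summaries -> expression clustering. Each stage writes TSV
products; the final report aggregates counts and percentages.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as pio
from .duplication import (
    attribute_duplication_origin,
    chain_collinear_blocks,
    classify_copy_retention,
    detect_tandem_arrays,
    filter_isoforms,
    origin_summary,
    write_collinearity,
)
from .expression import cluster_genes, read_expression_tsv, write_clustered_tsv
from .family import (
    SubfamilyReference,
    assign_subfamily,
    build_profile,
    iterative_scan,
)
from .pangene import (
    build_pav,
    category_counts,
    classify_oggs,
    cluster_orthogroups,
    detect_monotone_trends,
    gene_share_pct,
    group_frequencies,
)
from .selection import back_translate, ng86_pair, summarize_strata, write_kaks_tsv

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full pipeline run."""

    input_dir: str
    output_dir: str
    genome_ids: list[str] = field(default_factory=list)
    outgroup_id: str = "VVI"
    target_genome: str = ""            # genome compared to the outgroup
    seed: int = 0
    # family identification
    scan_rounds: int = 2
    inclusion_threshold: float = 15.0
    confident_threshold: float = 25.0
    min_identity: float = 0.4
    # clustering / PAV
    evalue_cut: float = 1e-20
    min_bitscore: float = 0.0
    trend_min_delta: float = 10.0
    # tandem / synteny
    max_rank_gap: int = 5
    synteny_max_gaps: int = 1          # MCScan-style u
    synteny_min_block: int = 5         # MCScan-style s
    # selection
    kaks_tol: float = 1e-9

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


def _load_genome(indir: Path, genome_id: str):
    proteins = pio.read_fasta(indir / "genomes" / f"{genome_id}.pep.fa")
    cds = pio.read_fasta(indir / "genomes" / f"{genome_id}.cds.fa")
    genes = pio.read_gff3(indir / "genomes" / f"{genome_id}.gff3",
                          genome_id, proteins, cds)
    return genes, proteins, cds


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the summary report (also written)."""
    indir = Path(config.input_dir)
    outdir = pio.ensure_dir(config.output_dir)
    if not config.genome_ids:
        raise ValueError("no genomes configured")
    for required in ("groups.tsv", "edges.tsv", "seed_alignment.fa"):
        if not (indir / required).exists():
            raise ValueError(f"missing required input {required}")

    groups = pio.read_groups_tsv(indir / "groups.tsv")
    seed_aln = list(pio.read_fasta(indir / "seed_alignment.fa").values())
    seed_profile = build_profile(seed_aln)
    references = []
    ref_path = indir / "references.fa"
    if ref_path.exists():
        references = [SubfamilyReference(lab, (seq,))
                      for lab, seq in sorted(pio.read_fasta(ref_path).items())]
    edges = pio.read_blast6(indir / "edges.tsv")

    logger.info("stage identify: thresholds inclusion=%s confident=%s",
                config.inclusion_threshold, config.confident_threshold)
    family_genes = []
    id_rows = []
    for gid in config.genome_ids:
        genes, proteins, _ = _load_genome(indir, gid)
        hits, _ = iterative_scan(
            seed_profile, proteins, rounds=config.scan_rounds,
            inclusion_threshold=config.inclusion_threshold,
            confident_threshold=config.confident_threshold)
        kept = filter_isoforms([g for g in genes if g.gene_id in hits])
        for g in kept:
            subfam = (assign_subfamily(g.protein, references, config.min_identity)
                      if references else "")
            id_rows.append({"gene_id": g.gene_id, "genome_id": gid,
                            "score": round(hits[g.gene_id], 3),
                            "subfamily": subfam})
        family_genes.extend(kept)
    pd.DataFrame(id_rows).to_csv(outdir / "family_members.tsv",
                                 sep="\t", index=False)
    subfamily_of = {r["gene_id"]: r["subfamily"] for r in id_rows}

    logger.info("stage pangene: evalue_cut=%s", config.evalue_cut)
    family_ids = {g.gene_id for g in family_genes}
    oggs = cluster_orthogroups(
        [e for e in edges if e.gene_a in family_ids and e.gene_b in family_ids],
        family_ids, config.evalue_cut, config.min_bitscore)
    gene_genome = {g.gene_id: g.genome_id for g in family_genes}
    pav = build_pav(oggs, gene_genome, groups)
    classification = classify_oggs(pav)
    cat_counts = category_counts(classification)
    freqs = group_frequencies(pav)
    trends = detect_monotone_trends(freqs, pav.ordered_group_labels(),
                                    config.trend_min_delta)
    pio.write_pav_tsv(pav, outdir / "pav_matrix.tsv")
    pd.DataFrame(sorted(classification.items()),
                 columns=["ogg_id", "category"]).to_csv(
        outdir / "ogg_classification.tsv", sep="\t", index=False)
    freqs.to_csv(outdir / "group_frequencies.tsv", sep="\t")

    logger.info("stage tandem: max_rank_gap=%s", config.max_rank_gap)
    arrays = detect_tandem_arrays(family_genes, edges,
                                  config.evalue_cut, config.max_rank_gap)
    pd.DataFrame([{"array_id": a.array_id, "genome_id": a.genome_id,
                   "chrom": a.chrom, "members": ",".join(a.members)}
                  for a in arrays]).to_csv(outdir / "tandem_arrays.tsv",
                                           sep="\t", index=False)

    logger.info("stage synteny: u=%s s=%s", config.synteny_max_gaps,
                config.synteny_min_block)
    target_id = config.target_genome or config.genome_ids[0]
    blocks, retention, kaks_results = [], {}, []
    anchors_path = indir / "anchors.tsv"
    if anchors_path.exists():
        anchors = pio.read_blast6(anchors_path)
        out_genes, out_prot, out_cds = _load_genome(indir, config.outgroup_id)
        out_genes = filter_isoforms(out_genes)
        target_genes = [g for g in family_genes if g.genome_id == target_id]
        blocks = chain_collinear_blocks(
            anchors, target_genes, out_genes, config.evalue_cut,
            config.synteny_max_gaps, config.synteny_min_block)
        retention = classify_copy_retention(blocks, out_genes)
        write_collinearity(blocks, outdir / "blocks.collinearity")
        pd.DataFrame(sorted(retention.items()),
                     columns=["outgroup_gene", "copies"]).to_csv(
            outdir / "copy_retention.tsv", sep="\t", index=False)

        logger.info("stage kaks: NG86, tol=%s", config.kaks_tol)
        by_id = {g.gene_id: g for g in target_genes}
        out_by_id = {g.gene_id: g for g in out_genes}
        for b in blocks:
            for x, y in b.anchors:
                tgt, og = (x, y) if x in by_id else (y, x)
                tg, vg = by_id[tgt], out_by_id[og]
                if len(tg.protein) == len(vg.protein):
                    prot_a, prot_b = vg.protein, tg.protein
                else:  # substitution-free alignment unavailable; global align
                    from .family import _aligner
                    aln = _aligner().align(vg.protein, tg.protein)[0]
                    prot_a, prot_b = str(aln[0]), str(aln[1])
                ca = back_translate(prot_a, prot_b, vg.cds, tg.cds, og, tgt)
                kaks_results.append(ng86_pair(ca, og, tgt))
        write_kaks_tsv(kaks_results, outdir / "kaks.tsv")
        strata = summarize_strata(
            kaks_results, retention, {g: lab for g, (lab, _) in groups.items()},
            genome_of={g.gene_id: g.genome_id for g in family_genes})
        strata.to_csv(outdir / "kaks_strata.tsv", sep="\t", index=False)

    origins = attribute_duplication_origin(
        family_genes, arrays, blocks, retention,
        {g for g in retention})
    pd.DataFrame(sorted(origins.items()),
                 columns=["gene_id", "origin"]).to_csv(
        outdir / "duplication_origin.tsv", sep="\t", index=False)
    group_of_gene = {g.gene_id: groups[g.genome_id][0] for g in family_genes}
    origin_pct = origin_summary(origins, group_of_gene)

    expr_report = {}
    expr_path = indir / "expression.tsv"
    if expr_path.exists():
        logger.info("stage expression: Spearman + complete linkage")
        m = read_expression_tsv(expr_path, indir / "samples.tsv")
        _, order = cluster_genes(m)
        write_clustered_tsv(m, order, outdir / "expression_clustered.tsv")
        expr_report = {"n_genes": int(m.values.shape[0]),
                       "n_samples": int(m.values.shape[1])}

    n_family = len(family_genes)
    genes_per_cat = {c: 0 for c in cat_counts}
    for ogg_id, members in oggs.items():
        genes_per_cat[classification[ogg_id]] += len(members)
    td_genes = sum(1 for o in origins.values() if o in ("TD", "both"))
    wgt_genes = sum(1 for o in origins.values() if o in ("WGT", "both"))
    report = {
        "n_genomes": len(config.genome_ids),
        "n_family_genes": n_family,
        "n_oggs": len(oggs),
        "category_counts": cat_counts,
        "category_gene_counts": genes_per_cat,
        "category_gene_pct": {c: gene_share_pct(genes_per_cat[c], n_family)
                              for c in genes_per_cat},
        "rising_oggs": trends["rising"],
        "falling_oggs": trends["falling"],
        "n_tandem_arrays": len(arrays),
        "td_gene_pct": gene_share_pct(td_genes, n_family),
        "wgt_gene_pct": gene_share_pct(wgt_genes, n_family),
        "origin_pct_by_group": origin_pct,
        "n_synteny_blocks": len(blocks),
        "n_kaks_pairs": len(kaks_results),
        "expression": expr_report,
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
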