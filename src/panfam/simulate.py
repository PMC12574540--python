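"""Synthetic multi-genome pangenome with ground truth for every stage.

The simulator emulates the structure of a domesticated crop pangenome
study: several dozen genomes partitioned into ordered population groups
(wild relatives through cultivated accessions), a gene family defined by a
conserved protein domain, orthologous gene groups (OGGs) with a controlled
core/softcore/dispensable/private category mix, implanted tandem arrays at
configured rank spacings, an outgroup genome whose genes were triplicated
by a whole-genome event and then fractionated back to 3/2/1 copies, codon
sequences evolved toward target Ka/Ks ratios per retention stratum, and a
tissue x stage expression matrix with archetypal profiles.

Everything is deterministic for a fixed seed, and every downstream module
has a truth table to recover: OGG membership and category, tandem arrays,
retention copy numbers, per-pair Ka/Ks targets, expression archetypes.

What it does not emulate: realistic chromosome sizes, GC content, codon
usage bias, intron structure, or alignment noise in the similarity graph
(hit tables carry idealised E-values).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .codons import (
    CODON_TO_AA,
    codon_neighbors,
    syn_site_count,
    synonymous_codons,
    translate_cds,
    translate_codon,
    STOP_CODONS,
)
from .duplication import GeneModel, TandemArray, assign_ranks
from .expression import ExpressionMatrix
from .family import AA_ALPHABET, SubfamilyReference
from .pangene import CATEGORIES, SimilarityEdge

DOMAIN_LENGTH = 60
FLANK_LENGTH = 20
ISOFORM_EVERY = 20   # every 20th locus gets a second, shorter mRNA


@dataclass
class SimConfig:
    """Study-design parameters of the simulated pangenome."""

    n_genomes: int = 10
    group_sizes: tuple[int, ...] = (3, 2, 2, 3)
    group_labels: tuple[str, ...] = ("WDR", "SP", "SLC", "SLL")
    n_oggs: int = 50
    category_mix: dict = field(default_factory=lambda: {
        "core": 0.5, "softcore": 0.2, "dispensable": 0.2, "private": 0.1})
    n_chromosomes: int = 3
    tandem_arrays: tuple[tuple[int, int], ...] = ((3, 1), (2, 1), (4, 2))
    wgt_fraction: float = 0.6
    loss_probs: tuple[float, float, float] = (0.2, 0.3, 0.5)  # retain 3/2/1
    target_kaks: dict = field(default_factory=lambda: {1: 0.1, 2: 0.3, 3: 0.6})
    subs_per_kb: float = 50.0
    n_outgroup_genes: int = 60
    n_background_genes: int = 20
    n_subfamilies: int = 8
    seed: int = 0

    def __post_init__(self):
        if sum(self.group_sizes) != self.n_genomes:
            raise ValueError("group_sizes must sum to n_genomes")
        if len(self.group_labels) != len(self.group_sizes):
            raise ValueError("group_labels must match group_sizes")
        if abs(sum(self.category_mix.values()) - 1.0) > 1e-9:
            raise ValueError("category_mix must sum to 1")
        if set(self.category_mix) - set(CATEGORIES):
            raise ValueError("category_mix has unknown categories")
        if abs(sum(self.loss_probs) - 1.0) > 1e-9:
            raise ValueError("loss_probs must sum to 1")
        if any(v < 0 for v in self.category_mix.values()):
            raise ValueError("category_mix proportions must be >= 0")
        if self.category_mix.get("dispensable", 0) > 0 and self.n_genomes < 4:
            raise ValueError("dispensable OGGs need n_genomes >= 4")
        if any(r < 0 or r > 2 for r in self.target_kaks.values()):
            raise ValueError("target_kaks ratios must lie in [0, 2]")


@dataclass
class Genome:
    genome_id: str
    group: str
    group_order: int
    genes: list[GeneModel] = field(default_factory=list)


@dataclass
class PangenomeTruth:
    config: SimConfig
    genomes: list[Genome]
    outgroup: Genome
    ogg_truth: dict[str, tuple[str, frozenset]]      # ogg -> (category, genomes)
    ogg_members: dict[str, list[str]]                # ogg -> gene ids
    subfamily_truth: dict[str, str]                  # ogg -> subfamily label
    tandem_truth: list[TandemArray]
    retention_truth: dict[str, int]                  # outgroup gene -> copies
    kaks_truth: dict[tuple[str, str], float]         # (outgroup, target) -> ratio
    edges: list[SimilarityEdge]                      # within-pangenome hits
    anchor_edges: list[SimilarityEdge]               # outgroup vs target hits
    seed_alignment: list[str]
    references: list[SubfamilyReference]
    background_genes: set[str]

    @property
    def gene_genome(self) -> dict[str, str]:
        out = {}
        for genome in self.genomes:
            for g in genome.genes:
                out[g.gene_id] = genome.genome_id
        return out

    @property
    def groups(self) -> dict[str, tuple[str, int]]:
        return {g.genome_id: (g.group, g.group_order) for g in self.genomes}

    def family_gene_ids(self) -> set[str]:
        return {gid for members in self.ogg_members.values() for gid in members}


# ---------------------------------------------------------------------------
# sequence helpers

def _random_protein(rng, length: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def _mutate_protein(rng, protein: str, fraction: float) -> str:
    out = list(protein)
    n_mut = int(round(fraction * len(out)))
    if n_mut == 0:
        return protein
    positions = rng.choice(len(out), size=n_mut, replace=False)
    for p in positions:
        choices = [a for a in AA_ALPHABET if a != out[p]]
        out[p] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def _cds_for_protein(rng, protein: str) -> str:
    codons = []
    for aa in protein:
        options = synonymous_codons(aa)
        codons.append(options[int(rng.integers(len(options)))])
    return "".join(codons)


def evolve_codons(cds: str, target_kaks: float, n_subs: int, seed: int) -> str:
    """Introduce point substitutions steering the pair toward a target Ka/Ks.

    The synonymous/nonsynonymous split of the introduced substitutions is
    chosen so the expected NG86 ratio of (original, mutated) approaches
    ``target_kaks``: with S and N the NG86 site counts of the sequence, a
    substitution is nonsynonymous with probability r*N / (S + r*N). Changes
    creating stop codons are never proposed.
    """
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    if target_kaks < 0:
        raise ValueError("target_kaks must be >= 0")
    original = cds
    cds = cds.upper()
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    for i, c in enumerate(codons[:-1]):
        if c in STOP_CODONS:
            raise ValueError(f"internal stop codon at codon {i}")
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
        had_stop = cds[-3:]
    else:
        had_stop = ""
    if n_subs == 0:
        return original
    S = sum(syn_site_count(c) for c in codons)
    N = 3 * len(codons) - S
    phi = (target_kaks * N) / (S + target_kaks * N) if (S + target_kaks * N) > 0 else 0.0
    rng = np.random.default_rng(seed)
    for _ in range(n_subs):
        want_nonsyn = bool(rng.random() < phi)
        for attempt_nonsyn in (want_nonsyn, not want_nonsyn):
            cands = []
            for ci, codon in enumerate(codons):
                aa = translate_codon(codon)
                for _, alt in codon_neighbors(codon):
                    if alt in STOP_CODONS:
                        continue
                    if (translate_codon(alt) != aa) == attempt_nonsyn:
                        cands.append((ci, alt))
            if cands:
                ci, alt = cands[int(rng.integers(len(cands)))]
                codons[ci] = alt
                break
    return "".join(codons) + had_stop


# ---------------------------------------------------------------------------
# pangenome assembly

def _allocate_counts(n: int, mix: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of n items to the category mix."""
    raw = {c: n * mix.get(c, 0.0) for c in CATEGORIES}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    remainders = sorted(CATEGORIES, key=lambda c: (-(raw[c] - counts[c]), c))
    for c in remainders[:short]:
        counts[c] += 1
    return counts


class _GenomeBuilder:
    """Accumulates loci for one genome, then lays them onto chromosomes."""

    def __init__(self, genome_id: str, group: str, order: int, n_chromosomes: int):
        self.genome_id = genome_id
        self.group = group
        self.order = order
        self.n_chromosomes = n_chromosomes
        self.loci: list[tuple[str, str, str]] = []   # (gene_id, protein, cds)
        self.arrays: list[tuple[int, int, list[int]]] = []  # (chrom, spacing, locus idx)
        self._serial = 0

    def new_locus(self, protein: str, cds: str) -> tuple[int, str]:
        gid = f"{self.genome_id}_g{self._serial:05d}"
        self._serial += 1
        self.loci.append((gid, protein, cds))
        return len(self.loci) - 1, gid

    def layout(self, rng, extra_chroms: dict[str, list[int]] | None = None,
               shuffle: bool = True) -> list[GeneModel]:
        """Place loci on chromosomes; arrays first (contiguous with their
        spacing), remaining loci shuffled round-robin; emit isoform pairs."""
        in_array = {i for _, _, idxs in self.arrays for i in idxs}
        in_extra = {i for idxs in (extra_chroms or {}).values() for i in idxs}
        pool = [i for i in range(len(self.loci))
                if i not in in_array and i not in in_extra]
        if shuffle:
            pool = [pool[k] for k in rng.permutation(len(pool))]
        chrom_orders: dict[str, list[int]] = {
            f"chr{c + 1:02d}": [] for c in range(self.n_chromosomes)}
        names = list(chrom_orders)
        for chrom_i, spacing, idxs in self.arrays:
            order = chrom_orders[names[chrom_i % len(names)]]
            for k, idx in enumerate(idxs):
                order.append(idx)
                if k < len(idxs) - 1:
                    for _ in range(spacing - 1):
                        order.append(pool.pop() if pool else -1)
        for k, idx in enumerate(pool):
            chrom_orders[names[k % len(names)]].append(idx)
        for chrom, idxs in (extra_chroms or {}).items():
            chrom_orders[chrom] = list(idxs)

        genes: list[GeneModel] = []
        for chrom in sorted(chrom_orders):
            pos = 1
            for locus_i, idx in enumerate(chrom_orders[chrom]):
                if idx < 0:
                    continue
                gid, protein, cds = self.loci[idx]
                start = pos
                end = start + len(cds) - 1
                pos = end + 1 + 50 + int(rng.geometric(1.0 / 300.0))
                locus = gid.replace("_g", "_L")
                genes.append(GeneModel(
                    gene_id=gid, genome_id=self.genome_id, chrom=chrom,
                    start=start, end=end, strand="+" if rng.random() < 0.5 else "-",
                    locus_id=locus, protein=protein, cds=cds))
                if (idx + 1) % ISOFORM_EVERY == 0:
                    k = (2 * (len(cds) // 3)) // 3
                    if k >= 3:
                        iso_cds = cds[: 3 * k]
                        genes.append(GeneModel(
                            gene_id=gid + "i", genome_id=self.genome_id,
                            chrom=chrom, start=start, end=start + len(iso_cds) - 1,
                            strand=genes[-1].strand, locus_id=locus,
                            protein=protein[:k], cds=iso_cds))
        return assign_ranks(genes)


def simulate_pangenome(config: SimConfig) -> PangenomeTruth:
    """Generate the full pangenome with ground truth (see module docstring)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genomes

    genome_specs = []
    i = 0
    for label, size in zip(config.group_labels, config.group_sizes):
        for _ in range(size):
            genome_specs.append((f"G{i:02d}", label))
            i += 1
    order_of = {lab: k for k, lab in enumerate(config.group_labels)}

    # family scaffold: one conserved domain, subfamilies, OGG ancestors
    domain = _random_protein(rng, DOMAIN_LENGTH)
    seed_alignment = [_mutate_protein(rng, domain, 0.10) for _ in range(8)]
    labels = [f"UGT{71 + k}" for k in range(config.n_subfamilies)]
    subfam_prot = {}
    for lab in labels:
        flank_n = _random_protein(rng, FLANK_LENGTH)
        flank_c = _random_protein(rng, FLANK_LENGTH)
        subfam_prot[lab] = flank_n + _mutate_protein(rng, domain, 0.15) + flank_c
    references = [SubfamilyReference(lab, (subfam_prot[lab],)) for lab in labels]

    counts = _allocate_counts(config.n_oggs, config.category_mix)
    categories = [c for c in CATEGORIES for _ in range(counts[c])]

    ogg_truth: dict[str, tuple[str, frozenset]] = {}
    ogg_members: dict[str, list[str]] = {}
    subfamily_truth: dict[str, str] = {}
    ogg_ancestor: dict[str, str] = {}
    presence: dict[str, list[str]] = {}
    genome_ids = [gid for gid, _ in genome_specs]

    for k, cat in enumerate(categories):
        ogg = f"T{k:04d}"
        if cat == "core":
            genomes = list(genome_ids)
        elif cat == "softcore":
            drop = int(rng.integers(n))
            genomes = [g for j, g in enumerate(genome_ids) if j != drop]
        elif cat == "dispensable":
            size = int(rng.integers(2, n - 1))          # 2 .. n-2
            genomes = sorted(str(g) for g in
                             rng.choice(genome_ids, size=size, replace=False))
        else:
            genomes = [genome_ids[int(rng.integers(n))]]
        lab = labels[k % len(labels)]
        subfamily_truth[ogg] = lab
        ogg_ancestor[ogg] = _mutate_protein(rng, subfam_prot[lab], 0.10)
        ogg_truth[ogg] = (cat, frozenset(genomes))
        ogg_members[ogg] = []
        presence[ogg] = genomes

    builders = {gid: _GenomeBuilder(gid, lab, order_of[lab], config.n_chromosomes)
                for gid, lab in genome_specs}

    locus_of: dict[tuple[str, str], int] = {}   # (genome, ogg) -> locus index
    for ogg in ogg_truth:
        for gid in presence[ogg]:
            b = builders[gid]
            protein = _mutate_protein(rng, ogg_ancestor[ogg], 0.02)
            idx, gene_id = b.new_locus(protein, _cds_for_protein(rng, protein))
            locus_of[(gid, ogg)] = idx
            ogg_members[ogg].append(gene_id)

    # implanted tandem arrays: extra same-OGG copies at configured spacing
    tandem_plan: list[tuple[str, int, list[str]]] = []
    core_oggs = [o for o, (cat, _) in ogg_truth.items() if cat == "core"]
    used: set[tuple[str, str]] = set()
    for a_i, (size, spacing) in enumerate(config.tandem_arrays):
        gid = genome_ids[a_i % n]
        ogg = next(o for o in core_oggs if (gid, o) not in used)
        used.add((gid, ogg))
        b = builders[gid]
        base_idx = locus_of[(gid, ogg)]
        base_gene = b.loci[base_idx]
        members = [base_idx]
        member_ids = [base_gene[0]]
        for _ in range(size - 1):
            protein = _mutate_protein(rng, base_gene[1], 0.01)
            idx, gene_id = b.new_locus(protein, _cds_for_protein(rng, protein))
            members.append(idx)
            member_ids.append(gene_id)
            ogg_members[ogg].append(gene_id)
        b.arrays.append((a_i, spacing, members))
        tandem_plan.append((gid, a_i, member_ids))

    # background (non-family) genes
    background_genes: set[str] = set()
    for gid, _ in genome_specs:
        b = builders[gid]
        for _ in range(config.n_background_genes):
            protein = _random_protein(rng, DOMAIN_LENGTH + 2 * FLANK_LENGTH)
            _, gene_id = b.new_locus(protein, _cds_for_protein(rng, protein))
            background_genes.add(gene_id)

    # outgroup and whole-genome-triplication retention in the first genome
    outgroup = Genome("VVI", "OUT", -1)
    og_builder = _GenomeBuilder("VVI", "OUT", -1, 1)
    target = builders[genome_ids[0]]
    retention_truth: dict[str, int] = {}
    kaks_truth: dict[tuple[str, str], float] = {}
    anchor_edges: list[SimilarityEdge] = []
    wgt_ogg_count = 0
    subgenome_loci: dict[str, list[int]] = {"chrS1": [], "chrS2": [], "chrS3": []}
    sub_names = list(subgenome_loci)
    wgt_members: dict[str, list[str]] = {}
    for _ in range(config.n_outgroup_genes):
        flank_n = _random_protein(rng, FLANK_LENGTH)
        flank_c = _random_protein(rng, FLANK_LENGTH)
        protein = flank_n + _mutate_protein(rng, domain, 0.12) + flank_c
        cds = _cds_for_protein(rng, protein)
        _, og_gid = og_builder.new_locus(protein, cds)
        if rng.random() < config.wgt_fraction:
            copies = int(rng.choice([3, 2, 1], p=list(config.loss_probs)))
        else:
            copies = 1
        subs = sorted(rng.choice(3, size=copies, replace=False))
        retention_truth[og_gid] = copies
        target_ratio = config.target_kaks.get(copies, 0.2)
        n_subs = max(1, int(round(config.subs_per_kb * len(cds) / 1000.0)))
        ogg = f"W{wgt_ogg_count:04d}"
        wgt_ogg_count += 1
        members = []
        for s in subs:
            child_seed = int(rng.integers(2 ** 31))
            cds_t = evolve_codons(cds, target_ratio, n_subs, child_seed)
            prot_t = translate_cds(cds_t)
            idx, t_gid = target.new_locus(prot_t, cds_t)
            subgenome_loci[sub_names[s]].append(idx)
            members.append(t_gid)
            kaks_truth[(og_gid, t_gid)] = target_ratio
            anchor_edges.append(SimilarityEdge(og_gid, t_gid, 400.0, 1e-120))
        ogg_truth[ogg] = ("private", frozenset([genome_ids[0]]))
        subfamily_truth[ogg] = "species-specific"
        ogg_members[ogg] = members
        wgt_members[ogg] = members

    # lay out chromosomes
    genomes = []
    for gid, lab in genome_specs:
        b = builders[gid]
        extra = subgenome_loci if gid == genome_ids[0] else None
        genes = b.layout(rng, extra_chroms=extra)
        genomes.append(Genome(gid, lab, order_of[lab], genes))
    outgroup.genes = og_builder.layout(rng, shuffle=False)  # ancestral order

    # tandem truth against final layouts
    tandem_truth = []
    for t_i, (gid, chrom_i, member_ids) in enumerate(tandem_plan):
        genome = next(g for g in genomes if g.genome_id == gid)
        ranks = {g.gene_id: (g.chrom, g.rank) for g in genome.genes}
        chrom = ranks[member_ids[0]][0]
        ordered = sorted(member_ids, key=lambda m: ranks[m][1])
        tandem_truth.append(TandemArray(f"truthTA{t_i:03d}", gid, chrom, ordered))

    # similarity graph: strong within OGGs, weak between same-subfamily OGGs
    edges: list[SimilarityEdge] = []
    for ogg, members in ogg_members.items():
        for a_i in range(len(members)):
            for b_i in range(a_i + 1, len(members)):
                edges.append(SimilarityEdge(members[a_i], members[b_i],
                                            300.0, 1e-100))
    by_subfam: dict[str, list[str]] = {}
    for ogg, lab in subfamily_truth.items():
        if ogg in wgt_members or not ogg_members[ogg]:
            continue
        by_subfam.setdefault(lab, []).append(ogg_members[ogg][0])
    for lab, reps in sorted(by_subfam.items()):
        for a_i in range(len(reps) - 1):
            edges.append(SimilarityEdge(reps[a_i], reps[a_i + 1], 50.0, 1e-5))

    return PangenomeTruth(
        config=config, genomes=genomes, outgroup=outgroup,
        ogg_truth=ogg_truth, ogg_members=ogg_members,
        subfamily_truth=subfamily_truth, tandem_truth=tandem_truth,
        retention_truth=retention_truth, kaks_truth=kaks_truth,
        edges=edges, anchor_edges=anchor_edges,
        seed_alignment=seed_alignment, references=references,
        background_genes=background_genes,
    )


# ---------------------------------------------------------------------------
# expression simulation

ARCHETYPES = ("ubiquitous-high", "tissue-specific", "stage-ramp", "silent")

DEFAULT_TISSUES = ("root", "stem", "leaf", "flower_bud", "flower", "fruit")
DEFAULT_STAGES = ("30", "45", "55", "65", "75", "80", "85", "88", "92", "95", "100")


def simulate_expression(
    truth: PangenomeTruth,
    tissues: tuple[str, ...] = DEFAULT_TISSUES,
    stages: tuple[str, ...] = DEFAULT_STAGES,
    seed: int = 0,
    noise_sd: float = 0.2,
    n_replicates: int = 1,
    genes: list[str] | None = None,
) -> ExpressionMatrix:
    """Archetypal expression for the first genome's family genes.

    Archetypes cycle through ubiquitous-high (flat 100), tissue-specific
    (100 in one tissue, 0.5 elsewhere), stage-ramp (geometric 1 -> 100
    across stages in every tissue), and silent (exact 0). Non-silent
    values get multiplicative noise 2**N(0, noise_sd).
    """
    import pandas as pd

    if len(tissues) < 2:
        raise ValueError("need at least 2 tissues")
    rng = np.random.default_rng(seed)
    if genes is None:
        family = truth.family_gene_ids()
        genes = sorted(g.gene_id for g in truth.genomes[0].genes
                       if g.gene_id in family and not g.gene_id.endswith("i"))
    sample_ids, meta_rows = [], []
    for t in tissues:
        for s in stages:
            for r in range(1, n_replicates + 1):
                sid = f"{t}.{s}.r{r}"
                sample_ids.append(sid)
                meta_rows.append({"sample_id": sid, "tissue": t, "stage": s,
                                  "replicate": r})
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")

    ramp = np.geomspace(1.0, 100.0, num=len(stages))
    archetypes: dict[str, str] = {}
    values = np.zeros((len(genes), len(sample_ids)))
    for g_i, gid in enumerate(genes):
        arch = ARCHETYPES[g_i % len(ARCHETYPES)]
        if arch == "tissue-specific":
            t_assigned = tissues[(g_i // len(ARCHETYPES)) % len(tissues)]
            archetypes[gid] = f"tissue-specific:{t_assigned}"
        else:
            archetypes[gid] = arch
        for s_i, sid in enumerate(sample_ids):
            t = metadata.loc[sid, "tissue"]
            stage_idx = stages.index(metadata.loc[sid, "stage"])
            if arch == "ubiquitous-high":
                base = 100.0
            elif arch == "tissue-specific":
                base = 100.0 if t == t_assigned else 0.5
            elif arch == "stage-ramp":
                base = ramp[stage_idx]
            else:
                base = 0.0
            if base > 0:
                base *= 2.0 ** rng.normal(0.0, noise_sd)
            values[g_i, s_i] = base
    df = pd.DataFrame(values, index=genes, columns=sample_ids)
    return ExpressionMatrix(df, metadata, archetypes)


def simulate_proteome(
    n_family: int, n_background: int, seed: int,
    divergence: float = 0.12,
) -> tuple[dict[str, str], set[str], list[str]]:
    """Standalone proteome of family + background sequences for scan tests.

    Returns (proteome, family ids, seed alignment rows).
    """
    rng = np.random.default_rng(seed)
    domain = _random_protein(rng, DOMAIN_LENGTH)
    seed_alignment = [_mutate_protein(rng, domain, 0.10) for _ in range(8)]
    proteome: dict[str, str] = {}
    family_ids = set()
    for k in range(n_family):
        gid = f"fam{k:04d}"
        flanks = (_random_protein(rng, FLANK_LENGTH),
                  _random_protein(rng, FLANK_LENGTH))
        proteome[gid] = flanks[0] + _mutate_protein(rng, domain, divergence) + flanks[1]
        family_ids.add(gid)
    for k in range(n_background):
        gid = f"bg{k:04d}"
        proteome[gid] = _random_protein(rng, DOMAIN_LENGTH + 2 * FLANK_LENGTH)
    return proteome, family_ids, seed_alignment


# ---------------------------------------------------------------------------
# writing the simulated study to disk

def write_pangenome(truth: PangenomeTruth, outdir,
                    expression: ExpressionMatrix | None = None) -> Path:
    """Write per-genome FASTA/GFF3, hit tables, truth tables, and labels."""
    from . import io as pio

    out = Path(outdir)
    (out / "genomes").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)
    for genome in [*truth.genomes, truth.outgroup]:
        stem = out / "genomes" / genome.genome_id
        pio.write_fasta({g.gene_id: g.protein for g in genome.genes},
                        f"{stem}.pep.fa")
        pio.write_fasta({g.gene_id: g.cds for g in genome.genes},
                        f"{stem}.cds.fa")
        pio.write_gff3(genome.genes, f"{stem}.gff3")
    pio.write_blast6(truth.edges, out / "edges.tsv")
    pio.write_blast6(truth.anchor_edges, out / "anchors.tsv")
    pio.write_fasta({f"seed{k}": s for k, s in enumerate(truth.seed_alignment)},
                    out / "seed_alignment.fa")
    pio.write_fasta({r.label: r.sequences[0] for r in truth.references},
                    out / "references.fa")
    pio.write_groups_tsv(truth.groups, out / "groups.tsv")

    with open(out / "truth" / "ogg_truth.tsv", "w") as fh:
        fh.write("ogg_id\tcategory\tsubfamily\tgenomes\tmembers\n")
        for ogg in sorted(truth.ogg_truth):
            cat, genomes = truth.ogg_truth[ogg]
            fh.write(f"{ogg}\t{cat}\t{truth.subfamily_truth[ogg]}\t"
                     f"{','.join(sorted(genomes))}\t"
                     f"{','.join(sorted(truth.ogg_members[ogg]))}\n")
    with open(out / "truth" / "tandem_truth.tsv", "w") as fh:
        fh.write("array_id\tgenome_id\tchrom\tmembers\n")
        for arr in truth.tandem_truth:
            fh.write(f"{arr.array_id}\t{arr.genome_id}\t{arr.chrom}\t"
                     f"{','.join(arr.members)}\n")
    with open(out / "truth" / "retention_truth.tsv", "w") as fh:
        fh.write("outgroup_gene\tcopies\n")
        for g in sorted(truth.retention_truth):
            fh.write(f"{g}\t{truth.retention_truth[g]}\n")
    with open(out / "truth" / "kaks_truth.tsv", "w") as fh:
        fh.write("outgroup_gene\ttarget_gene\ttarget_kaks\n")
        for (a, b) in sorted(truth.kaks_truth):
            fh.write(f"{a}\t{b}\t{truth.kaks_truth[(a, b)]}\n")
    if expression is not None:
        expression.values.to_csv(out / "expression.tsv", sep="\t")
        expression.metadata.to_csv(out / "samples.tsv", sep="\t")
        with open(out / "truth" / "expression_archetypes.tsv", "w") as fh:
            fh.write("gene_id\tarchetype\n")
            for g in sorted(expression.archetypes):
                fh.write(f"{g}\t{expression.archetypes[g]}\n")
    return out
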