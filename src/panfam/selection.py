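"""Ka/Ks estimation for orthologous gene pairs by Nei–Gojobori (1986) counting.

The workflow mirrors the classic codeml/yn00-style pipeline but uses the
counting estimator: a protein-level pairwise alignment is back-translated
onto the coding sequences, synonymous and nonsynonymous sites and
differences are counted codon by codon, proportions are Jukes–Cantor
corrected, and the Ka/Ks ratio is classified into selection modes
(purifying < 1, neutral = 1, positive > 1).

Sites use the stop-excluding convention (per position, the synonymous
fraction among non-stop single-nucleotide changes, averaged over the two
sequences). Differences are averaged over all minimal substitution pathways
that avoid stop codons. Ambiguous nucleotides (N) void the containing codon
column. Terminal stop codons are trimmed before validation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codons import (
    STOP_CODONS,
    pairwise_differences,
    syn_site_count,
    translate_codon,
)

logger = logging.getLogger(__name__)

GAP_CODON = "---"


@dataclass(frozen=True)
class CodonAlignment:
    """A pair of gapped codon sequences (gaps in whole-codon units)."""

    seq_a: str
    seq_b: str
    source_id: str = ""

    def __post_init__(self):
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("codon alignment rows differ in length")
        if len(self.seq_a) % 3:
            raise ValueError("codon alignment length not divisible by 3")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def columns(self):
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i : i + 3], self.seq_b[i : i + 3]


@dataclass
class KaKsResult:
    gene_a: str
    gene_b: str
    S_sites: float
    N_sites: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float | None
    Ka: float | None
    ratio: float | None
    selection_class: str = field(default="undefined")


def _trim_terminal_stop(cds: str) -> str:
    if len(cds) >= 3 and cds[-3:].upper() in STOP_CODONS:
        return cds[:-3]
    return cds


def back_translate(
    protein_a: str, protein_b: str, cds_a: str, cds_b: str,
    gene_a: str = "a", gene_b: str = "b",
) -> CodonAlignment:
    """Thread ungapped CDSs onto a gapped pairwise protein alignment.

    Each amino acid becomes its codon, each protein gap one codon gap; the
    translation of the output equals the input protein alignment.
    """
    if len(protein_a) != len(protein_b):
        raise ValueError("protein alignment rows differ in length")
    rows = []
    for gene, prot, cds in ((gene_a, protein_a, cds_a), (gene_b, protein_b, cds_b)):
        cds = _trim_terminal_stop(cds.upper())
        n_res = sum(1 for c in prot if c != "-")
        if n_res * 3 != len(cds):
            raise ValueError(
                f"{gene}: ungapped protein length {n_res} x 3 != CDS length {len(cds)}"
            )
        out = []
        k = 0
        for pos, aa in enumerate(prot):
            if aa == "-":
                out.append(GAP_CODON)
                continue
            codon = cds[3 * k : 3 * k + 3]
            k += 1
            if "N" not in codon and translate_codon(codon) != aa.upper():
                raise ValueError(
                    f"{gene}: codon {codon} at alignment column {pos} does not "
                    f"encode aligned residue {aa}"
                )
            out.append(codon)
        rows.append("".join(out))
    return CodonAlignment(rows[0], rows[1], source_id=f"{gene_a}|{gene_b}")


def _jc_correct(p: float) -> float | None:
    """Jukes–Cantor rate from a proportion; None when p >= 3/4 (saturated)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def ng86_pair(aln: CodonAlignment, gene_a: str = "", gene_b: str = "") -> KaKsResult:
    """Nei–Gojobori Ka/Ks for one codon alignment.

    Columns with a gap or an ambiguous nucleotide are excluded from both
    sites and differences; an internal stop in an ungapped column is an
    input error.
    """
    S = N = Sd = Nd = 0.0
    n_used = 0
    for idx, (ca, cb) in enumerate(aln.columns()):
        if ca == GAP_CODON or cb == GAP_CODON:
            continue
        if "N" in ca or "N" in cb:
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError(f"internal stop codon at codon column {idx}")
        S += (syn_site_count(ca) + syn_site_count(cb)) / 2.0
        sd, nd = pairwise_differences(ca, cb)
        Sd += sd
        Nd += nd
        n_used += 1
    if n_used == 0:
        raise ValueError("no ungapped codon columns to compare")
    N = 3.0 * n_used - S
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks = _jc_correct(pS)
    Ka = _jc_correct(pN)
    if Ka is None:
        logger.warning("pN >= 3/4 for %s|%s: Ka undefined (JC divergence)",
                       gene_a, gene_b)
    ratio = None
    if Ka is not None and Ks is not None and Ks > 0:
        ratio = Ka / Ks
    res = KaKsResult(
        gene_a=gene_a or aln.source_id.split("|")[0],
        gene_b=gene_b or (aln.source_id.split("|")[1] if "|" in aln.source_id else ""),
        S_sites=S, N_sites=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN,
        Ks=Ks, Ka=Ka, ratio=ratio,
    )
    res.selection_class = classify_selection(res)
    return res


def classify_selection(result: KaKsResult, tol: float = 1e-9) -> str:
    """Selection mode from the Ka/Ks ratio: >1 positive, <1 purifying, =1 neutral."""
    r = result.ratio
    if r is None:
        return "undefined"
    if r > 1.0 + tol:
        return "positive"
    if r < 1.0 - tol:
        return "purifying"
    return "neutral"


def summarize_strata(
    results: list[KaKsResult],
    retention: dict[str, int],
    groups: dict[str, str],
    genome_of: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Mean/median/n of Ka/Ks per (population group x copy-retention class).

    ``retention`` maps the outgroup member of each pair (gene_a) to its
    retained copy count; ``groups`` maps genomes to group labels and
    ``genome_of`` maps the target member (gene_b) to its genome (defaults to
    the prefix before the first '_' of the gene id). Pairs with undefined
    ratios are excluded and counted separately.
    """
    rows = []
    n_excluded = 0
    for r in results:
        if r.ratio is None:
            n_excluded += 1
            continue
        genome = (genome_of or {}).get(r.gene_b, r.gene_b.split("_")[0])
        rows.append({
            "group": groups.get(genome, "NA"),
            "copy_class": retention.get(r.gene_a, 0),
            "ratio": r.ratio,
        })
    df = pd.DataFrame(rows, columns=["group", "copy_class", "ratio"])
    all_groups = sorted(set(groups.values()))
    all_classes = sorted(set(retention.values())) or [0]
    cells = []
    for g in all_groups:
        for c in all_classes:
            sub = df[(df["group"] == g) & (df["copy_class"] == c)]["ratio"]
            cells.append({
                "group": g,
                "copy_class": c,
                "n": len(sub),
                "mean": round(float(sub.mean()), 6) if len(sub) else np.nan,
                "median": round(float(sub.median()), 6) if len(sub) else np.nan,
            })
    out = pd.DataFrame(cells)
    out.attrs["n_excluded_undefined"] = n_excluded
    return out


def write_kaks_tsv(results: list[KaKsResult], path) -> None:
    df = pd.DataFrame([{
        "gene_a": r.gene_a, "gene_b": r.gene_b,
        "S_sites": r.S_sites, "N_sites": r.N_sites,
        "Sd": r.Sd, "Nd": r.Nd,
        "Ka": "" if r.Ka is None else f"{r.Ka:.6f}",
        "Ks": "" if r.Ks is None else f"{r.Ks:.6f}",
        "ratio": "" if r.ratio is None else f"{r.ratio:.6f}",
        "selection_class": r.selection_class,
    } for r in results])
    df.to_csv(path, sep="\t", index=False)


def read_axt_pairs(path) -> list[tuple[str, str, str, str]]:
    """Read AXT-style pairwise blocks: header line, seq a, seq b, blank.

    Returns (name_a, name_b, seq_a, seq_b) tuples; the header's second and
    third whitespace-separated fields are taken as the pair names when
    present, else the whole header names the pair.
    """
    out = []
    with open(path) as fh:
        block: list[str] = []
        for raw in fh:
            line = raw.strip()
            if not line:
                if block:
                    out.append(_axt_block(block))
                    block = []
                continue
            block.append(line)
        if block:
            out.append(_axt_block(block))
    return out


def _axt_block(block: list[str]) -> tuple[str, str, str, str]:
    if len(block) != 3:
        raise ValueError(f"malformed AXT block of {len(block)} lines")
    fields = block[0].split()
    if len(fields) >= 3:
        name_a, name_b = fields[1], fields[2]
    else:
        name_a = name_b = fields[0]
    return name_a, name_b, block[1].upper(), block[2].upper()
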