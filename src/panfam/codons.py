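"""Genetic-code helpers shared by the selection module and the simulator.

Everything here is derived once, at import time, from the standard genetic
code (NCBI table 1) via Biopython. The Nei–Gojobori site fractions use the
stop-excluding convention: at each codon position the synonymous fraction is
counted over the single-nucleotide changes that do not create a stop codon.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

from Bio.Data.CodonTable import unambiguous_dna_by_id

NUCS = "ACGT"

_TABLE = unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))


def translate_codon(codon: str) -> str:
    """Amino acid for a sense codon, '*' for a stop."""
    if codon in STOP_CODONS:
        return "*"
    return CODON_TO_AA[codon]


def translate_cds(cds: str) -> str:
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    return "".join(translate_codon(cds[i : i + 3]) for i in range(0, len(cds), 3))


def codon_neighbors(codon: str):
    """All single-nucleotide neighbours as (position, new_codon) pairs."""
    out = []
    for pos in range(3):
        for nt in NUCS:
            if nt != codon[pos]:
                out.append((pos, codon[:pos] + nt + codon[pos + 1 :]))
    return out


@lru_cache(maxsize=None)
def syn_site_count(codon: str) -> float:
    """NG86 synonymous site count of one sense codon.

    Per position: (synonymous non-stop changes) / (non-stop changes); stop
    neighbours are excluded from the denominator. A position whose three
    changes all create stops contributes 0.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site count")
    aa = CODON_TO_AA[codon]
    total = 0.0
    for pos in range(3):
        syn = 0
        nonstop = 0
        for nt in NUCS:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            nonstop += 1
            if CODON_TO_AA[alt] == aa:
                syn += 1
        if nonstop:
            total += syn / nonstop
    return total


@lru_cache(maxsize=None)
def pairwise_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """NG86 (synonymous, nonsynonymous) difference counts for a codon pair.

    Averaged over all minimal substitution pathways that avoid stop codons
    at intermediate steps. If every pathway passes through a stop, pathways
    are retained but only their non-stop steps are counted.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[float, float]] = []
    degraded: list[tuple[float, float]] = []
    for order in permutations(diff_pos):
        cur = codon_a
        syn = nsyn = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != codon_b:
                ok = False
            step_counts = not (cur in STOP_CODONS or nxt in STOP_CODONS)
            if step_counts:
                if translate_codon(cur) == translate_codon(nxt):
                    syn += 1
                else:
                    nsyn += 1
            cur = nxt
        (valid if ok else degraded).append((syn, nsyn))
    paths = valid if valid else degraded
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def synonymous_codons(aa: str) -> tuple[str, ...]:
    return tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa)
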