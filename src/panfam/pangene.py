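"""Orthologous gene groups, presence/absence variation, and PAV trends.

Family members from many genomes are clustered into orthologous gene
groups (OGGs) as connected components of the similarity graph after E-value
and bit-score cutoffs — a deliberately simple, auditable stand-in for full
orthology inference. The binary OGG x genome presence matrix is then
classified into the standard pangenome categories:

  core        present in all N genomes
  softcore    present in exactly N - 1
  dispensable present in 2 .. N - 2
  private     present in exactly 1

and per-population-group presence frequencies are screened for monotone
trajectories along an ordered series of groups (e.g. wild -> cultivated).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

import networkx as nx
import pandas as pd

CATEGORIES = ("core", "softcore", "dispensable", "private")


@dataclass(frozen=True)
class SimilarityEdge:
    """Undirected similarity hit between two genes (gene_a < gene_b)."""

    gene_a: str
    gene_b: str
    bitscore: float
    evalue: float

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if self.gene_a > self.gene_b:
            a, b = self.gene_a, self.gene_b
            object.__setattr__(self, "gene_a", b)
            object.__setattr__(self, "gene_b", a)


def round_half_up(value, ndigits: int = 0) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero toward +inf)."""
    q = Decimal(1).scaleb(-ndigits)
    if isinstance(value, Fraction):
        d = Decimal(value.numerator) / Decimal(value.denominator)
    else:
        d = Decimal(str(value))
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def gene_share_pct(count: int, total: int, ndigits: int = 2) -> float:
    """Percentage share of a gene count, rounded half-up (e.g. 72.53)."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_up(Fraction(100 * count, total), ndigits)


def cluster_orthogroups(
    edges: list[SimilarityEdge],
    genes: set[str],
    evalue_cut: float = 1e-20,
    min_bitscore: float = 0.0,
) -> dict[str, list[str]]:
    """Connected-component orthogroups over the filtered similarity graph.

    Singleton genes form singleton OGGs. Ids follow the OG%07d convention
    in order of decreasing member count, ties by smallest member id.
    """
    g = nx.Graph()
    g.add_nodes_from(genes)
    for e in edges:
        for gid in (e.gene_a, e.gene_b):
            if gid not in genes:
                raise ValueError(f"edge references unknown gene {gid}")
        if e.evalue <= evalue_cut and e.bitscore >= min_bitscore:
            g.add_edge(e.gene_a, e.gene_b)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return {f"OG{i:07d}": members for i, members in enumerate(comps)}


@dataclass
class PAVMatrix:
    """Binary OGG x genome presence matrix with ordered group labels."""

    presence: pd.DataFrame               # index OGG ids, columns genome ids
    groups: dict[str, tuple[str, int]]   # genome -> (group label, group order)

    def __post_init__(self):
        vals = self.presence.to_numpy()
        if not ((vals == 0) | (vals == 1)).all():
            raise ValueError("presence entries must be 0/1")
        missing = set(self.presence.columns) - set(self.groups)
        if missing:
            raise ValueError(f"genomes without group label: {sorted(missing)}")
        if (vals.sum(axis=1) == 0).any():
            raise ValueError("all-zero OGG row")

    @property
    def n_genomes(self) -> int:
        return self.presence.shape[1]

    def ordered_group_labels(self) -> list[str]:
        seen = {}
        for label, order in self.groups.values():
            seen[label] = order
        return [lab for lab, _ in sorted(seen.items(), key=lambda kv: kv[1])]


def build_pav(
    oggs: dict[str, list[str]],
    gene_genome: dict[str, str],
    groups: dict[str, tuple[str, int]],
) -> PAVMatrix:
    """Presence/absence matrix from OGG membership (>=1 member = present)."""
    genomes = sorted(groups)
    data = {}
    for ogg_id, members in sorted(oggs.items()):
        present = {gene_genome[m] for m in members}
        data[ogg_id] = [1 if g in present else 0 for g in genomes]
    df = pd.DataFrame.from_dict(data, orient="index", columns=genomes)
    return PAVMatrix(df, dict(groups))


def classify_oggs(pav: PAVMatrix) -> dict[str, str]:
    """Category per OGG from its presence count (see module docstring)."""
    n = pav.n_genomes
    if n < 2:
        raise ValueError("classification undefined for fewer than 2 genomes")
    out = {}
    for ogg_id, row in pav.presence.iterrows():
        k = int(row.sum())
        if k == n:
            out[ogg_id] = "core"
        elif k == n - 1:
            out[ogg_id] = "softcore"
        elif k == 1:
            out[ogg_id] = "private"
        else:
            out[ogg_id] = "dispensable"
    return out


def category_counts(classification: dict[str, str]) -> dict[str, int]:
    return {c: sum(1 for v in classification.values() if v == c) for c in CATEGORIES}


def group_frequencies(pav: PAVMatrix) -> pd.DataFrame:
    """Per-group presence frequency of each OGG, integer percent (half-up)."""
    labels = pav.ordered_group_labels()
    members: dict[str, list[str]] = {lab: [] for lab in labels}
    for genome, (lab, _) in pav.groups.items():
        members[lab].append(genome)
    for lab, gs in members.items():
        if not gs:
            raise ValueError(f"empty group {lab}")
    data = {}
    for ogg_id, row in pav.presence.iterrows():
        data[ogg_id] = [
            int(round_half_up(Fraction(100 * int(row[members[lab]].sum()),
                                       len(members[lab]))))
            for lab in labels
        ]
    return pd.DataFrame.from_dict(data, orient="index", columns=labels)


def detect_monotone_trends(
    freqs: pd.DataFrame,
    group_order: list[str],
    min_delta: float = 10.0,
) -> dict[str, list[str]]:
    """OGGs with monotone presence-frequency trajectories across groups.

    Rising: non-decreasing along ``group_order``, not constant, with total
    change >= ``min_delta`` percentage points. Falling is symmetric.
    """
    if len(group_order) < 3:
        raise ValueError("need at least 3 ordered groups")
    unknown = set(group_order) - set(freqs.columns)
    if unknown:
        raise ValueError(f"unknown group(s) in order: {sorted(unknown)}")
    rising, falling = [], []
    for ogg_id, row in freqs[group_order].iterrows():
        vals = row.to_list()
        diffs = [b - a for a, b in zip(vals, vals[1:])]
        total = vals[-1] - vals[0]
        if all(d >= 0 for d in diffs) and any(d > 0 for d in diffs) and total >= min_delta:
            rising.append(ogg_id)
        elif all(d <= 0 for d in diffs) and any(d < 0 for d in diffs) and -total >= min_delta:
            falling.append(ogg_id)
    return {"rising": rising, "falling": falling}


def read_orthogroups_tsv(path) -> dict[str, list[str]]:
    """Adapter for OrthoFinder-style Orthogroups.tsv (OGG per row, genes by column)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = {}
    id_col = df.columns[0]
    for _, row in df.iterrows():
        members: list[str] = []
        for col in df.columns[1:]:
            members.extend(g.strip() for g in row[col].split(",") if g.strip())
        out[row[id_col]] = sorted(members)
    return out
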