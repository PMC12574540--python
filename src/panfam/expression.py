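"""Expression profiling: log transform, Spearman/complete-linkage clustering,
and gene-dosage summaries for multi-copy genes.

The clustering follows the common heatmap recipe for FPKM matrices:
log2(1 + x) transform, gene-gene distance 1 - Spearman rho (ties
mid-ranked), complete-linkage agglomeration. Because Spearman rho is
rank-based, the dendrogram is identical on raw and log-transformed values;
the transform matters only for displayed magnitudes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes x samples FPKM values with (tissue, stage, replicate) metadata."""

    values: pd.DataFrame           # index gene ids, columns sample ids
    metadata: pd.DataFrame         # index sample ids: tissue, stage, replicate
    archetypes: dict[str, str] = field(default_factory=dict)  # simulator truth

    def __post_init__(self):
        if (self.values.to_numpy() < 0).any():
            r, c = np.argwhere(self.values.to_numpy() < 0)[0]
            raise ValueError(
                f"negative expression at gene {self.values.index[r]}, "
                f"sample {self.values.columns[c]}"
            )
        missing = set(self.values.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")

    @property
    def tissues(self) -> list[str]:
        return sorted(self.metadata["tissue"].unique())


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(1 + x); metadata preserved."""
    return ExpressionMatrix(np.log2(1.0 + m.values), m.metadata.copy(),
                            dict(m.archetypes))


def condition_means(m: ExpressionMatrix) -> pd.DataFrame:
    """Average replicates per (tissue, stage) condition."""
    cond = m.metadata["tissue"].astype(str) + "|" + m.metadata["stage"].astype(str)
    grouped = m.values.T.groupby(cond.loc[m.values.columns]).mean().T
    return grouped


def spearman_distance_matrix(values: pd.DataFrame) -> np.ndarray:
    """1 - Spearman rho per gene pair; constant genes get distance 1 (warned)."""
    ranks = values.rank(axis=1, method="average")
    arr = ranks.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant gene vector(s): Spearman undefined, "
                       "distance set to 1", int(constant.sum()))
    centered = arr - arr.mean(axis=1, keepdims=True)
    denom = np.sqrt((centered ** 2).sum(axis=1))
    denom[denom == 0] = 1.0
    normed = centered / denom[:, None]
    rho = normed @ normed.T
    d = 1.0 - rho
    d[constant, :] = 1.0
    d[:, constant] = 1.0
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return d


def cluster_genes(
    m: ExpressionMatrix,
    transform: str = "log",
    average_replicates: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Complete-linkage dendrogram on Spearman distances.

    Returns the scipy linkage matrix and the ordered gene list (dendrogram
    leaf order). Genes are sorted by id first so ties resolve by gene id.
    """
    if m.values.shape[0] < 2 or m.values.shape[1] < 3:
        raise ValueError("need >= 2 genes and >= 3 samples")
    work = log_transform(m) if transform == "log" else m
    vals = condition_means(work) if average_replicates else work.values
    vals = vals.sort_index()
    d = spearman_distance_matrix(vals)
    z = hierarchy.linkage(squareform(d, checks=False), method="complete")
    order = [vals.index[i] for i in hierarchy.leaves_list(z)]
    return z, order


def tau_specificity(tissue_means: pd.Series) -> float:
    """Tissue-specificity tau: sum(1 - x/x_max)/(n-1) on non-negative means."""
    x = tissue_means.to_numpy(dtype=float)
    if len(x) < 2 or x.max() <= 0:
        return 0.0
    return float((1.0 - x / x.max()).sum() / (len(x) - 1))


def dosage_summary(
    m: ExpressionMatrix,
    copy_groups: dict[str, list[str]],
    tau_threshold: float = 0.85,
) -> pd.DataFrame:
    """Per-copy-set tissue profiles: member means, member sum, peak tissue.

    Each copy set (e.g. the retained copies of one ancestral gene) gets a
    per-tissue mean for every member and for the member sum; the tissue of
    the summed maximum is flagged, with a tau-based specificity call.
    """
    unknown = {g for genes in copy_groups.values() for g in genes
               if g not in m.values.index}
    if unknown:
        raise ValueError(f"copy set references unknown gene(s): {sorted(unknown)}")
    tissue = m.metadata["tissue"]
    by_tissue = m.values.T.groupby(tissue.loc[m.values.columns]).mean().T
    rows = []
    for set_id, genes in sorted(copy_groups.items()):
        summed = by_tissue.loc[genes].sum(axis=0)
        peak = summed.idxmax()
        tau = tau_specificity(summed)
        for g in genes:
            prof = by_tissue.loc[g]
            rows.append({
                "copy_set": set_id, "gene": g, "n_copies": len(genes),
                **{f"mean_{t}": prof[t] for t in by_tissue.columns},
                "sum_peak_tissue": peak,
                "sum_tau": round(tau, 4),
                "tissue_specific": tau >= tau_threshold,
            })
    return pd.DataFrame(rows)


def read_expression_tsv(values_path, metadata_path) -> ExpressionMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0, dtype=str)
    return ExpressionMatrix(values, metadata)


def write_clustered_tsv(m: ExpressionMatrix, order: list[str], path) -> None:
    """Heatmap-ready TSV with rows in dendrogram order."""
    m.values.loc[order].to_csv(path, sep="\t")
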