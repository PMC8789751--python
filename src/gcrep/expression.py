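"""Library-size normalization, differential expression and dot-plot summaries.

Normalization scales each cell's UMI counts to a common library size
(counts-per-10k by default); downstream statistics work on log2(1 + x) of
the normalized values.  Differential expression uses a two-sided Wilcoxon
rank-sum test per gene with BH correction, and reports fold changes as
linear-scale ratios of pseudocounted group means plus per-group detection
rates; the reporting filter keeps genes with |fold change| >= 1.2 detected
in at least 25% of either group at q <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu

from .enrichment import bh_adjust
from .io import CountMatrix


@dataclass
class NormalizedMatrix:
    """Cells x genes library-size-normalized expression (linear scale)."""

    cells: list[str]
    genes: list[str]
    values: sp.csr_matrix
    scale: float
    n_zero_cells_removed: int = 0

    def log2_dense(self, cell_idx: np.ndarray | None = None) -> np.ndarray:
        """log2(1 + normalized) for the given cell rows, densified."""
        sub = self.values if cell_idx is None else self.values[cell_idx]
        return np.log2(1.0 + np.asarray(sub.todense()))


def normalize_counts(matrix: CountMatrix, scale: float = 1e4) -> NormalizedMatrix:
    """Scale each cell's counts to a common library size.

    Cells with zero total counts cannot be normalized; they are removed and
    tallied in ``n_zero_cells_removed``.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    counts = matrix.counts.tocsr().astype(float)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    keep = totals > 0
    n_removed = int((~keep).sum())
    counts = counts[keep]
    totals = totals[keep]
    if counts.shape[0] and np.any(np.asarray(counts.sum(axis=1)).ravel() <= 0):
        raise RuntimeError("all-zero cell survived removal pass")
    inv = sp.diags(scale / totals)
    return NormalizedMatrix(
        cells=[b for b, k in zip(matrix.cells, keep) if k],
        genes=list(matrix.genes),
        values=sp.csr_matrix(inv @ counts),
        scale=scale,
        n_zero_cells_removed=n_removed,
    )


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def _cell_indices(norm: NormalizedMatrix, barcodes: Sequence[str]) -> np.ndarray:
    index = {b: i for i, b in enumerate(norm.cells)}
    missing = [b for b in barcodes if b not in index]
    if missing:
        raise KeyError(f"{len(missing)} barcodes not in matrix (e.g. {missing[0]!r})")
    return np.array([index[b] for b in barcodes], dtype=int)


def differential_expression(
    norm: NormalizedMatrix,
    cells_a: Sequence[str],
    cells_b: Sequence[str],
    min_cells: int = 10,
    fc_min: float = 1.2,
    pct_min: float = 0.25,
    q_max: float = 0.05,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Rank-based differential expression between two disjoint cell groups.

    Per gene: a two-sided Wilcoxon rank-sum p-value on log2(1 + normalized)
    values, BH-corrected across tested genes; fold change as the
    linear-scale ratio of group means with a pseudocount (scale/1000 by
    default) added to both; detection rates as the fraction of cells with a
    nonzero count per group.  ``passes_filters`` applies the reporting
    filter: fold change >= fc_min in either direction, detection >= pct_min
    in at least one group, and q <= q_max.
    """
    set_a, set_b = set(cells_a), set(cells_b)
    if set_a & set_b:
        raise ValueError("cell groups must be disjoint")
    if len(set_a) < min_cells or len(set_b) < min_cells:
        raise ValueError(
            f"each group needs at least {min_cells} cells "
            f"(got {len(set_a)} and {len(set_b)})"
        )
    pc = norm.scale / 1000.0 if pseudocount is None else pseudocount

    idx_a = _cell_indices(norm, sorted(set_a))
    idx_b = _cell_indices(norm, sorted(set_b))
    lin_a = np.asarray(norm.values[idx_a].todense())
    lin_b = np.asarray(norm.values[idx_b].todense())
    log_a = np.log2(1.0 + lin_a)
    log_b = np.log2(1.0 + lin_b)

    mean_log_a = log_a.mean(axis=0)
    mean_log_b = log_b.mean(axis=0)
    fold_change = (lin_a.mean(axis=0) + pc) / (lin_b.mean(axis=0) + pc)
    pct_a = (lin_a > 0).mean(axis=0)
    pct_b = (lin_b > 0).mean(axis=0)

    p = mannwhitneyu(log_a, log_b, axis=0, alternative="two-sided").pvalue
    # a gene constant across both groups carries no information; p := 1
    constant = (log_a.max(axis=0) == log_a.min(axis=0)) & (
        log_b.max(axis=0) == log_b.min(axis=0)
    ) & (log_a.max(axis=0) == log_b.max(axis=0))
    p = np.where(constant, 1.0, p)
    q = bh_adjust(p)

    passes = (
        ((fold_change >= fc_min) | (fold_change <= 1.0 / fc_min))
        & ((pct_a >= pct_min) | (pct_b >= pct_min))
        & (q <= q_max)
    )
    return pd.DataFrame(
        {
            "gene": norm.genes,
            "group_a_mean": mean_log_a,
            "group_b_mean": mean_log_b,
            "fold_change": fold_change,
            "pct_a": pct_a,
            "pct_b": pct_b,
            "p_value": p,
            "q_value": q,
            "passes_filters": passes,
        }
    )


# ---------------------------------------------------------------------------
# Dot-plot summaries
# ---------------------------------------------------------------------------

def dotplot_summary(
    norm: NormalizedMatrix,
    gene_panel: Sequence[str],
    cluster_labels: Mapping[str, str],
) -> tuple[pd.DataFrame, list[str]]:
    """Percent-detected and z-scored mean log2 expression per gene x cluster.

    For every panel gene and every cluster: the fraction of the cluster's
    cells with a nonzero count and the mean log2(1 + normalized) expression;
    the mean is then z-scored per gene across the clusters in the call
    (zero-variance genes get z = 0).  Genes absent from the matrix are
    returned in the second element rather than raising.
    """
    gene_index = {g: i for i, g in enumerate(norm.genes)}
    panel = [g for g in dict.fromkeys(gene_panel)]
    missing = [g for g in panel if g not in gene_index]
    present = [g for g in panel if g in gene_index]

    clusters = sorted({cluster_labels[b] for b in norm.cells if b in cluster_labels})
    rows = []
    per_gene_means: dict[str, list[float]] = {g: [] for g in present}
    for cluster in clusters:
        idx = np.array(
            [i for i, b in enumerate(norm.cells) if cluster_labels.get(b) == cluster],
            dtype=int,
        )
        sub = np.asarray(norm.values[idx].todense())
        log_sub = np.log2(1.0 + sub)
        for gene in present:
            j = gene_index[gene]
            pct = float((sub[:, j] > 0).mean()) if len(idx) else 0.0
            mean_log = float(log_sub[:, j].mean()) if len(idx) else 0.0
            per_gene_means[gene].append(mean_log)
            rows.append(
                {
                    "gene": gene,
                    "cluster": cluster,
                    "pct_detected": pct,
                    "mean_log_expr": mean_log,
                }
            )
    df = pd.DataFrame(rows, columns=["gene", "cluster", "pct_detected", "mean_log_expr"])
    if not df.empty:
        z = np.full(len(df), 0.0)
        for gene in present:
            values = np.array(per_gene_means[gene])
            sd = values.std()  # population sd across clusters
            mask = (df["gene"] == gene).to_numpy()
            if sd > 0 and len(values) >= 2:
                z[mask] = (values - values.mean()) / sd
        df["z_score"] = z
    else:
        df["z_score"] = []
    return df, missing
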