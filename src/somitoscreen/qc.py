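"""Per-cell droplet QC and cluster marker-gene testing.

QC removes low-quality droplets by four filters: UMI counts below 500,
detected genes below 200, mitochondrial fraction above 0.2, and a
complexity score — log10(genes)/log10(UMIs) — below 0.8.  The stated rules
are exclusion conditions, so cells sitting exactly on a boundary are
retained.

Marker genes are found per cluster by a two-sided Wilcoxon rank-sum test of
each gene in the cluster's cells against all other cells, with Bonferroni
correction over the genes tested in that comparison; a gene is a marker
when its log2 fold change is at least 0.25 and the adjusted p-value is
below 0.05.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import MITO_PREFIX

UMI_MIN = 500
GENES_MIN = 200
MITO_MAX = 0.2
COMPLEXITY_MIN = 0.8
LOG2FC_MIN = 0.25
P_ADJ_MAX = 0.05

#: criterion keys used in QC tables and filter reports
QC_CRITERIA = ("low_umi", "low_genes", "high_mito", "low_complexity")


def _check_counts(counts: pd.DataFrame) -> np.ndarray:
    values = counts.to_numpy()
    if np.any(values < 0):
        raise ValueError("counts must be non-negative")
    if not np.issubdtype(values.dtype, np.integer):
        if np.any(values != np.round(values)):
            raise ValueError("counts must be integers")
        values = values.astype(np.int64)
    return values


def mito_gene_mask(gene_names, mito_genes=None) -> np.ndarray:
    """Boolean mask of mitochondrial genes, by explicit list or prefix."""
    names = pd.Index(gene_names)
    if mito_genes is not None:
        mito = set(mito_genes)
        unknown = mito - set(names)
        if unknown:
            raise ValueError(f"mito genes not in matrix: {sorted(unknown)}")
        return names.isin(mito)
    return np.asarray(names.str.startswith(MITO_PREFIX))


def compute_cell_qc(counts: pd.DataFrame, mito_genes=None) -> pd.DataFrame:
    """Per-cell QC metrics and pass/fail flags for a genes × cells matrix.

    Returns a cells-indexed frame with ``umi_count``, ``gene_count``,
    ``mito_fraction``, ``complexity`` (NaN when UMIs ≤ 1, which fails the
    complexity criterion since the score is undefined), one boolean column
    per criterion in :data:`QC_CRITERIA`, and ``pass``.
    """
    values = _check_counts(counts)
    mito = mito_gene_mask(counts.index, mito_genes)

    umi = values.sum(axis=0)
    genes = (values > 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_frac = np.where(umi > 0, values[mito].sum(axis=0) / umi, 0.0)
        complexity = np.where(
            (umi > 1) & (genes > 0),
            np.log10(np.maximum(genes, 1)) / np.log10(np.maximum(umi, 2)),
            np.nan,
        )

    qc = pd.DataFrame(
        {
            "umi_count": umi,
            "gene_count": genes,
            "mito_fraction": mito_frac,
            "complexity": complexity,
        },
        index=counts.columns,
    )
    qc["low_umi"] = qc["umi_count"] < UMI_MIN
    qc["low_genes"] = qc["gene_count"] < GENES_MIN
    qc["high_mito"] = qc["mito_fraction"] > MITO_MAX
    qc["low_complexity"] = ~(qc["complexity"] >= COMPLEXITY_MIN)  # NaN fails
    qc["pass"] = ~qc[list(QC_CRITERIA)].any(axis=1)
    return qc


def filter_cells(
    qc: pd.DataFrame, counts: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Retain passing cells; report removals per criterion.

    A cell can trip several criteria, so the per-criterion counts may sum
    to more than the number of removed cells.
    """
    if not qc.index.equals(counts.columns):
        raise ValueError("QC table does not match the matrix columns")
    keep = qc["pass"].to_numpy()
    if not keep.any():
        raise ValueError("no cells pass QC")
    report = {
        "n_input": int(len(qc)),
        "n_retained": int(keep.sum()),
        "n_removed": int((~keep).sum()),
        "removed_per_criterion": {
            c: int(qc.loc[~keep, c].sum()) for c in QC_CRITERIA
        },
    }
    return counts.loc[:, keep], report


def normalize_cp10k(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-10k depth normalisation followed by log1p."""
    values = _check_counts(counts).astype(float)
    depth = values.sum(axis=0)
    if np.any(depth == 0):
        raise ValueError("cells with zero counts cannot be normalised")
    return pd.DataFrame(
        np.log1p(values / depth * 1e4), index=counts.index, columns=counts.columns
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

EXACT_MAX_N = 8


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration of all C(n+m, n) group assignments of the pooled
    ranks when both groups have at most 8 observations (valid under ties);
    otherwise the normal approximation with tie correction and no
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n < 1 or m < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w_obs = ranks[:n].sum()
    mu = n * (n + m + 1) / 2.0

    if n <= EXACT_MAX_N and m <= EXACT_MAX_N:
        dev = abs(w_obs - mu) - 1e-9  # tolerate float round-off on ties
        hits = total = 0
        for combo in itertools.combinations(range(n + m), n):
            total += 1
            if abs(ranks[list(combo)].sum() - mu) >= dev:
                hits += 1
        return hits / total

    # tie-corrected variance of the rank sum
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    big_n = n + m
    var = n * m / 12.0 * (big_n + 1 - tie_term / (big_n * (big_n - 1)))
    if var <= 0:
        return 1.0
    z = (w_obs - mu) / math.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


def _rank_sum_pvalues(values: np.ndarray, in_group: np.ndarray) -> np.ndarray:
    """Vectorised tie-corrected normal-approximation rank-sum test.

    ``values`` is genes × cells; each gene is tested in-group vs rest.
    """
    n = int(in_group.sum())
    m = values.shape[1] - n
    ranks = sps.rankdata(values, axis=1)
    w = ranks[:, in_group].sum(axis=1)
    mu = n * (n + m + 1) / 2.0
    big_n = n + m

    sorted_vals = np.sort(values, axis=1)
    new_val = np.ones_like(sorted_vals, dtype=bool)
    new_val[:, 1:] = sorted_vals[:, 1:] != sorted_vals[:, :-1]
    tie_term = np.empty(values.shape[0])
    for i in range(values.shape[0]):  # runs of equal values per gene
        counts = np.diff(np.append(np.flatnonzero(new_val[i]), big_n))
        tie_term[i] = float(np.sum(counts.astype(float) ** 3 - counts))
    var = n * m / 12.0 * (big_n + 1 - tie_term / (big_n * (big_n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (w - mu) / np.sqrt(var), 0.0)
    return 2.0 * sps.norm.sf(np.abs(z))


def marker_genes(
    normalized: pd.DataFrame,
    cluster_labels,
    log2fc_min: float = LOG2FC_MIN,
    p_adj_max: float = P_ADJ_MAX,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Cluster marker genes by two-sided Wilcoxon rank-sum test.

    ``normalized`` is a genes × cells matrix of log1p-normalised
    expression (see :func:`normalize_cp10k`); ``cluster_labels`` assigns
    one cluster per cell.  For each cluster, every gene expressed in at
    least one cell of either group is tested against all other cells;
    log2FC compares de-logged group means with a pseudocount.  Bonferroni
    correction is per cluster over its tested genes.  Clusters with fewer
    than two cells are skipped with a warning.
    """
    labels = pd.Series(np.asarray(cluster_labels), index=normalized.columns)
    clusters = labels.unique()
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")

    values = normalized.to_numpy(dtype=float)
    expr = np.expm1(values)
    rows = []
    for cluster in clusters:
        in_group = (labels == cluster).to_numpy()
        if in_group.sum() < 2:
            warnings.warn(
                f"cluster {cluster!r} has fewer than 2 cells; skipped",
                stacklevel=2,
            )
            continue
        tested = np.flatnonzero((values != 0).any(axis=1))
        n_tested = len(tested)

        mean_in = expr[tested][:, in_group].mean(axis=1)
        mean_out = expr[tested][:, ~in_group].mean(axis=1)
        log2fc = np.log2((mean_in + pseudocount) / (mean_out + pseudocount))

        if in_group.sum() <= EXACT_MAX_N and (~in_group).sum() <= EXACT_MAX_N:
            pvals = np.array(
                [
                    wilcoxon_rank_sum(values[g, in_group], values[g, ~in_group])
                    for g in tested
                ]
            )
        else:
            pvals = _rank_sum_pvalues(values[tested], in_group)
        p_adj = np.minimum(1.0, pvals * n_tested)
        for i, gi in enumerate(tested):
            rows.append(
                {
                    "gene": normalized.index[gi],
                    "cluster": cluster,
                    "log2_fold_change": float(log2fc[i]),
                    "p_value": float(pvals[i]),
                    "p_adjusted": float(p_adj[i]),
                    "is_marker": bool(
                        log2fc[i] >= log2fc_min and p_adj[i] < p_adj_max
                    ),
                }
            )
    return pd.DataFrame(rows)
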