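"""Screen-level statistics: reproducibility, rankings, sizes, qPCR ΔΔCt.

Per-organoid features (diameter, mean normalized marker intensity, rosette
count) are aggregated into per-condition summaries with a coefficient of
variation as the reproducibility metric; somite-like structure sizes are
summarised as median/IQR/whiskers; Ct tables are reduced with the ΔΔCt
method (housekeeping and reference-sample correction) to fold-changes and
per-gene Z-scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: per-organoid feature columns aggregated by condition
FEATURE_COLUMNS = ("diameter_um", "mean_normalized_marker", "rosette_count")


def cv(values) -> float:
    """Coefficient of variation in percent: 100 · sample SD (n−1) / mean."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 2:
        raise ValueError("CV needs at least two values")
    mean = float(x.mean())
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / mean)


def aggregate_screen(table: pd.DataFrame) -> pd.DataFrame:
    """Per-condition summary of a screen table.

    ``table`` holds one row per organoid replicate with a ``condition``
    column and the feature columns present among ``FEATURE_COLUMNS``.
    Returns one row per condition with mean, SD and CV per feature and a
    ``rank`` by mean rosette count (ties broken by lower rosette-count CV).
    CV is NaN for single-replicate conditions.
    """
    if "condition" not in table.columns:
        raise ValueError("table needs a 'condition' column")
    features = [c for c in FEATURE_COLUMNS if c in table.columns]
    if not features:
        raise ValueError(f"no feature columns among {FEATURE_COLUMNS}")
    if (
        "rosette_count" in features
        and (
            (table["rosette_count"] < 0)
            | (table["rosette_count"] % 1 != 0)
        ).any()
    ):
        raise ValueError("rosette counts must be non-negative integers")

    rows = []
    for cond, grp in table.groupby("condition", sort=False):
        row: dict = {"condition": cond, "n": len(grp)}
        for feat in features:
            x = grp[feat].astype(float)
            row[f"{feat}_mean"] = float(x.mean())
            row[f"{feat}_sd"] = float(x.std(ddof=1)) if len(x) > 1 else float("nan")
            try:
                row[f"{feat}_cv_pct"] = cv(x) if len(x) > 1 else float("nan")
            except ValueError:
                row[f"{feat}_cv_pct"] = float("nan")
        rows.append(row)
    out = pd.DataFrame(rows)

    if "rosette_count" in features:
        mean_col, cv_col = "rosette_count_mean", "rosette_count_cv_pct"
        tiebreak = out[cv_col].fillna(np.inf)
        order = np.lexsort((tiebreak.to_numpy(), -out[mean_col].to_numpy()))
        rank = np.empty(len(out), dtype=int)
        rank[order] = np.arange(1, len(out) + 1)
        out["rank"] = rank
        out = out.sort_values("rank").reset_index(drop=True)
    return out


@dataclass(frozen=True)
class SizeStats:
    """Box-plot summary of structure areas for one group (µm²)."""

    group: str
    n: int
    median: float
    q25: float
    q75: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if not (
            self.min <= self.q25 <= self.median <= self.q75 <= self.max
        ):
            raise ValueError("quantiles out of order")


def size_stats(areas, group: str = "") -> SizeStats:
    """Median, quartiles (linear interpolation between order statistics)
    and min/max whiskers of a list of areas."""
    x = np.asarray(list(areas), dtype=float)
    if x.size == 0:
        raise ValueError("no areas given")
    q25, med, q75 = np.percentile(x, [25, 50, 75])  # linear interpolation
    return SizeStats(
        group=group,
        n=int(x.size),
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        min=float(x.min()),
        max=float(x.max()),
    )


def ddct(
    ct_table: pd.DataFrame,
    housekeeping: str = "PP1A",
    reference_sample: str = "iPSC",
) -> pd.DataFrame:
    """Relative expression by the ΔΔCt method.

    ``ct_table`` is long format with columns gene, sample, replicate, ct.
    Technical replicates are averaged per gene×sample; then
    ΔCt = Ct_gene − Ct_housekeeping, ΔΔCt = ΔCt_sample − ΔCt_reference and
    fold change = 2^−ΔΔCt.  Z-scores are computed per gene across samples
    on log2 fold changes (symmetric in up/down regulation); they are NaN
    with fewer than two samples.

    Raises
    ------
    ValueError
        If any gene×sample cell is missing, or housekeeping/reference are
        absent.
    """
    required = {"gene", "sample", "ct"}
    if not required.issubset(ct_table.columns):
        raise ValueError(f"ct table needs columns {sorted(required)}")
    mean_ct = ct_table.groupby(["gene", "sample"])["ct"].mean().unstack("sample")

    if housekeeping not in mean_ct.index:
        raise ValueError(f"housekeeping gene {housekeeping!r} not in table")
    if reference_sample not in mean_ct.columns:
        raise ValueError(f"reference sample {reference_sample!r} not in table")
    if mean_ct.isna().any().any():
        gaps = [
            f"{g}×{s}"
            for g, row in mean_ct.iterrows()
            for s, v in row.items()
            if math.isnan(v)
        ]
        raise ValueError(f"missing Ct values for: {', '.join(gaps)}")

    dct = mean_ct.sub(mean_ct.loc[housekeeping], axis=1)
    ddct_mat = dct.sub(dct[reference_sample], axis=0)
    fold = 2.0 ** (-ddct_mat)
    log2_fold = -ddct_mat

    zscores = log2_fold.copy()
    if log2_fold.shape[1] >= 2:
        mu = log2_fold.mean(axis=1)
        sd = log2_fold.std(axis=1, ddof=1)
        zscores = log2_fold.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    else:
        zscores[:] = np.nan

    def melt(mat: pd.DataFrame, name: str) -> pd.Series:
        long = mat.reset_index().melt(
            id_vars="gene", var_name="sample", value_name=name
        )
        return long  # identical shape/order for every matrix

    out = melt(ddct_mat, "ddct")
    out["dct"] = melt(dct, "v")["v"].to_numpy()
    out["fold_change"] = melt(fold, "v")["v"].to_numpy()
    out["log2_fold_change"] = melt(log2_fold, "v")["v"].to_numpy()
    out["z_score"] = melt(zscores, "v")["v"].to_numpy()
    return out[
        ["gene", "sample", "dct", "ddct", "fold_change", "log2_fold_change", "z_score"]
    ]
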