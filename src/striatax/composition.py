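"""Compositional analysis of interneuron classes between CN and Pu.

Per-sample class fractions are mapped to centered log-ratios,
CLR_x = log(r_x / g) with g the geometric mean of the class fractions
of that sample, which removes the unit-sum constraint; each class's CLR
values are then compared across regions with an unpaired two-sided
Wilcoxon rank-sum test (exact null distribution for small sample
counts).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .taxonomy import _bh_adjust


def class_fractions(labels: pd.Series, cell_meta: pd.DataFrame) -> pd.DataFrame:
    """Sample x class count and fraction table.

    ``labels`` maps cell id -> class; ``cell_meta`` supplies sample_id
    and region per cell. Samples with zero labeled cells are dropped
    with a warning. Returns a long-format frame (sample_id, region,
    class, count, fraction).
    """
    meta = cell_meta.loc[labels.index]
    df = pd.DataFrame(
        {
            "sample_id": meta["sample_id"].to_numpy(),
            "region": meta["region"].to_numpy(),
            "class": labels.to_numpy(),
        }
    )
    all_samples = cell_meta[["sample_id", "region"]].drop_duplicates()
    counts = (
        df.groupby(["sample_id", "region", "class"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    # complete the grid: absent classes are genuine zeros
    classes = sorted(df["class"].unique())
    grid = (
        counts.pivot_table(
            index=["sample_id", "region"], columns="class", values="count", fill_value=0
        )
        .reindex(columns=classes, fill_value=0)
    )
    dropped = set(map(tuple, all_samples.values)) - set(grid.index)
    if dropped:
        warnings.warn(f"samples without labeled cells dropped: {sorted(dropped)}")
    long = grid.stack().rename("count").reset_index()
    totals = long.groupby("sample_id")["count"].transform("sum")
    long["fraction"] = long["count"] / totals
    return long


def compute_clr(table: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Add a ``clr`` column: log of fraction over geometric mean.

    ``pseudocount`` is added to the class *counts* before fractions are
    recomputed, so zero-count classes are defined; with pseudocount 0 a
    zero fraction is an error. Natural log.
    """
    table = table.copy()
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and (table["count"] == 0).any():
        raise ValueError("zero class counts present; a positive pseudocount is required")
    adj = table["count"] + pseudocount
    tot = adj.groupby(table["sample_id"]).transform("sum")
    frac = adj / tot
    logf = np.log(frac)
    gmean_log = logf.groupby(table["sample_id"]).transform("mean")
    table["clr"] = logf - gmean_log
    return table


def region_composition_test(
    table: pd.DataFrame, min_samples: int = 3
) -> pd.DataFrame:
    """Per-class unpaired two-sided Wilcoxon rank-sum on CLR, CN vs Pu.

    Exact null distribution when the two regions together have <= 25
    samples and no ties; normal approximation with tie correction
    otherwise. Degenerate all-tied classes get p = 1.
    """
    if "clr" not in table.columns:
        raise ValueError("table lacks a 'clr' column; run compute_clr first")
    regions = table["region"].unique()
    if len(regions) != 2:
        raise ValueError(f"expected exactly 2 regions, found {list(regions)}")
    samples_per_region = (
        table[["sample_id", "region"]].drop_duplicates().groupby("region").size()
    )
    if (samples_per_region < min_samples).any():
        raise ValueError(
            f"each region needs >= {min_samples} samples, got "
            f"{samples_per_region.to_dict()}"
        )
    r1, r2 = sorted(regions)
    rows = []
    for cls, sub in table.groupby("class", observed=True):
        x = sub.loc[sub["region"] == r1, "clr"].to_numpy()
        y = sub.loc[sub["region"] == r2, "clr"].to_numpy()
        if np.ptp(np.concatenate([x, y])) == 0:
            rows.append((cls, np.nan, 1.0))
            continue
        method = "exact" if (len(x) + len(y)) <= 25 else "asymptotic"
        try:
            res = mannwhitneyu(x, y, alternative="two-sided", method=method)
        except ValueError:  # ties make the exact method unavailable
            res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        rows.append((cls, float(res.statistic), float(res.pvalue)))
    out = pd.DataFrame(rows, columns=["class", "statistic", "pval"])
    out["padj"] = _bh_adjust(out["pval"].to_numpy())
    return out
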