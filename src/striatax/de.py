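"""Pseudobulk differential expression between regions, and ORA.

Nuclei are aggregated into (class, sample, region) pseudobulk count
rows; per gene, a negative-binomial GLM with a log link and library
offsets is fit with and without the region coefficient and the region
effect is tested by a 1-df likelihood-ratio chi-square. Genewise
dispersions are estimated by Cox-Reid adjusted profile likelihood and
shrunk (in log space) toward the common dispersion. DEG selection uses
the |log2 fold change| > 0.5 and BH-adjusted p < 0.05 rule;
over-representation of gene sets in a DEG list is scored with the
hypergeometric upper tail and BH correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import chi2, hypergeom

from .containers import CountMatrix
from .taxonomy import _bh_adjust

MIN_ALPHA = 1e-4
MAX_ALPHA = 10.0


@dataclass
class PseudobulkMatrix:
    """Summed raw counts per (class, sample_id, region) group."""

    matrix: pd.DataFrame  # rows indexed by (class, sample_id, region)
    n_cells: pd.Series

    @property
    def genes(self) -> np.ndarray:
        return self.matrix.columns.to_numpy()


def aggregate_pseudobulk(
    counts: CountMatrix, labels: pd.Series, min_cells: int = 10
) -> PseudobulkMatrix:
    """Sum raw counts per (class, sample, region); drop thin groups."""
    meta = counts.cell_meta.loc[labels.index]
    keys = pd.DataFrame(
        {
            "class": labels.to_numpy(),
            "sample_id": meta["sample_id"].to_numpy(),
            "region": meta["region"].to_numpy(),
        },
        index=labels.index,
    )
    idx = counts.cell_index(labels.index)
    rows, names, sizes = [], [], []
    for key, members in keys.groupby(["class", "sample_id", "region"], observed=True):
        pos = idx[keys.index.get_indexer(members.index)]
        if len(pos) < min_cells:
            continue
        rows.append(np.asarray(counts.counts[pos].sum(axis=0)).ravel())
        names.append(key)
        sizes.append(len(pos))
    if not rows:
        raise ValueError("no pseudobulk group reaches min_cells")
    mat = pd.DataFrame(
        np.vstack(rows),
        index=pd.MultiIndex.from_tuples(names, names=["class", "sample_id", "region"]),
        columns=counts.gene_names,
    )
    return PseudobulkMatrix(mat, pd.Series(sizes, index=mat.index, name="n_cells"))


# ---------------------------------------------------------------------------
# negative-binomial GLM with likelihood-ratio test
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    inv = 1.0 / alpha
    return float(
        np.sum(
            gammaln(y + inv) - gammaln(inv) - gammaln(y + 1)
            + y * np.log(alpha * mu / (1 + alpha * mu))
            - inv * np.log1p(alpha * mu)
        )
    )


def _fit_group_means(y, t, groups, alpha, n_iter=50):
    """MLE of per-group rates m_g for mu_i = t_i * m_{g(i)} (Newton in log m)."""
    mu = np.empty_like(t, dtype=float)
    for g in np.unique(groups):
        m = groups == g
        yg, tg = y[m], t[m]
        tot = yg.sum()
        if tot == 0:
            mu[m] = 1e-8 * tg
            continue
        b = np.log(tot / tg.sum())
        for _ in range(n_iter):
            mug = tg * np.exp(b)
            f = np.sum((yg - mug) / (1 + alpha * mug))
            df = -np.sum(mug * (1 + alpha * yg) / (1 + alpha * mug) ** 2)
            step = f / df
            b -= step
            if abs(step) < 1e-10:
                break
        mu[m] = tg * np.exp(b)
    return mu


def _cox_reid_apl(y, t, groups, alpha) -> float:
    mu = _fit_group_means(y, t, groups, alpha)
    w = mu / (1 + alpha * mu)
    adj = 0.0
    for g in np.unique(groups):
        adj += 0.5 * np.log(max(w[groups == g].sum(), 1e-300))
    return _nb_loglik(y, mu, alpha) - adj


def estimate_dispersion(y, t, groups) -> float:
    """Genewise dispersion by Cox-Reid adjusted profile likelihood."""
    res = minimize_scalar(
        lambda la: -_cox_reid_apl(y, t, groups, np.exp(la)),
        bounds=(np.log(MIN_ALPHA), np.log(MAX_ALPHA)),
        method="bounded",
        options={"xatol": 1e-3},
    )
    return float(np.exp(res.x))


def median_ratio_factors(mat: pd.DataFrame) -> np.ndarray:
    """DESeq-style size factors over genes positive in every sample."""
    X = mat.to_numpy(dtype=float)
    pos = (X > 0).all(axis=0)
    if pos.sum() < 10:
        return X.sum(axis=1) / np.exp(np.mean(np.log(X.sum(axis=1))))
    logx = np.log(X[:, pos])
    ref = logx.mean(axis=0)
    sf = np.exp(np.median(logx - ref, axis=1))
    return sf / np.exp(np.mean(np.log(sf)))


def nb_glm_lrt(
    pb: PseudobulkMatrix,
    cls: str | None = None,
    shrinkage_weight: float = 0.5,
    use_median_ratio: bool = True,
    min_total_count: int = 1,
) -> pd.DataFrame:
    """Region LRT per gene for one class's pseudobulk rows.

    Offsets are library sizes scaled by median-ratio factors (optional).
    Fold changes are log2 CN vs Pu with a prior count of 0.5 on the
    aggregated counts. Genes whose total count is below
    ``min_total_count`` are excluded.
    """
    mat = pb.matrix if cls is None else pb.matrix.xs(cls, level="class", drop_level=True)
    regions = mat.index.get_level_values("region").to_numpy()
    for r in ("CN", "Pu"):
        if (regions == r).sum() < 2:
            raise ValueError(f"need >= 2 samples in region {r}")
    lib = mat.sum(axis=1).to_numpy(dtype=float)
    if use_median_ratio:
        t = median_ratio_factors(mat) * np.exp(np.mean(np.log(lib)))
    else:
        t = lib.copy()
    groups = (regions == "CN").astype(int)

    Y = mat.to_numpy(dtype=float)
    expressed = Y.sum(axis=0) >= max(min_total_count, 1)
    genes = mat.columns.to_numpy()[expressed]
    Y = Y[:, expressed]

    alphas = np.array(
        [estimate_dispersion(Y[:, j], t, groups) for j in range(Y.shape[1])]
    )
    common = float(np.exp(np.mean(np.log(alphas))))
    shrunk = np.exp(
        (1 - shrinkage_weight) * np.log(alphas) + shrinkage_weight * np.log(common)
    )

    cn = groups == 1
    tot_cn, tot_pu = t[cn].sum(), t[~cn].sum()
    rows = []
    for j, gene in enumerate(genes):
        y = Y[:, j]
        a = float(shrunk[j])
        try:
            mu_full = _fit_group_means(y, t, groups, a)
            mu_null = _fit_group_means(y, t, np.zeros_like(groups), a)
            stat = 2 * (_nb_loglik(y, mu_full, a) - _nb_loglik(y, mu_null, a))
            stat = max(stat, 0.0)
            p = float(chi2.sf(stat, df=1))
        except (FloatingPointError, ValueError):
            stat, p = np.nan, np.nan
        lfc = float(
            np.log2(((y[cn].sum() + 0.5) / tot_cn) / ((y[~cn].sum() + 0.5) / tot_pu))
        )
        rows.append((gene, lfc, stat, p))
    out = pd.DataFrame(rows, columns=["gene", "log2_fold", "lrt_stat", "pval"])
    ok = out["pval"].notna()
    if (~ok).any():
        warnings.warn(f"{(~ok).sum()} genes failed to converge; excluded from BH")
    out["padj"] = np.nan
    out.loc[ok, "padj"] = _bh_adjust(out.loc[ok, "pval"].to_numpy())
    out["direction"] = np.where(out["log2_fold"] > 0, "up_CN", "up_Pu")
    out["dispersion"] = shrunk
    return out


def select_degs(
    results: pd.DataFrame, lfc_min: float = 0.5, alpha: float = 0.05
) -> tuple[list[str], list[str]]:
    """DEGs at BH-adjusted p < alpha and |log2FC| strictly above lfc_min."""
    sig = results["padj"] < alpha
    up = results.loc[sig & (results["log2_fold"] > lfc_min), "gene"].tolist()
    down = results.loc[sig & (results["log2_fold"] < -lfc_min), "gene"].tolist()
    return up, down


def ora_hypergeometric(
    deg_list,
    collection: dict[str, tuple[str, set]],
    universe,
    alpha_term: float = 0.1,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each term in a DEG list.

    P(X >= k) with N = |universe|, K = |term ∩ universe|,
    n = |DEGs ∩ universe|; BH across terms; ``selected`` marks terms
    passing the p < ``alpha_term`` rule.
    """
    universe = list(dict.fromkeys(universe))
    uset = set(universe)
    degs = [g for g in dict.fromkeys(deg_list)]
    outside = [g for g in degs if g not in uset]
    if outside:
        warnings.warn(f"{len(outside)} DEGs outside the universe dropped")
    degs = set(degs) & uset
    N, n = len(universe), len(degs)
    rows = []
    for term, (name, genes) in collection.items():
        term_genes = set(genes) & uset
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & degs)
        p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append((term, name, K, k, p))
    out = pd.DataFrame(
        rows, columns=["term", "name", "term_size", "overlap", "pval"]
    )
    if len(out):
        out["padj"] = _bh_adjust(out["pval"].to_numpy())
        out["selected"] = out["pval"] < alpha_term
        out = out.sort_values("pval", kind="stable", ignore_index=True)
    return out
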