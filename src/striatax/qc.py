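"""Quality-control cascade for snRNA-seq count matrices.

Stages, in pipeline order:

1. consensus doublet voting over repeated runs of a simulated-doublet
   k-NN scorer (a cell is discarded when flagged in strictly more than
   ``doublet_vote_fraction`` of the runs);
2. basic count filters (UMIs in [500, 250000], genes in [1200, 15000],
   mitochondrial fraction <= 10%, all bounds kept under
   strict-exceedance semantics);
3. removal of outliers from a degree-2 polynomial fit of log(n_genes)
   on log(n_umis), deviation measured in gene-count units;
4. marker-score thresholds: per cell type, the score distribution is
   modeled as a two-Gaussian mixture and thresholded at
   mu_low + 4 * sigma_low; cells above more than one type's threshold
   are multi-identity doublets and are removed;
5. removal of cells expressing regional contamination markers
   (NEUROD2, TMEM155, CARTPT, SLC17A7).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.ndimage import gaussian_filter1d
from sklearn.decomposition import TruncatedSVD
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import NearestNeighbors

from .config import QCThresholds
from .containers import CountMatrix

DEFAULT_MARKER_PANEL: dict[str, list[str]] = {
    "astrocytes": ["AQP4", "ADGRV1"],
    "microglia": ["CSF1R", "FYB1"],
    "oligodendrocytes": ["MBP", "MOG", "MAG"],
    "OPC": ["PTPRZ1", "PDGFRA", "VCAN"],
    "vascular": ["EBF1", "ABCB1", "ABCA9"],
    "neurons": ["MEG3"],
}

REGIONAL_MARKERS = ["NEUROD2", "TMEM155", "CARTPT", "SLC17A7"]


# ---------------------------------------------------------------------------
# doublet scoring and consensus voting
# ---------------------------------------------------------------------------

def consensus_doublet_filter(
    call_matrix: np.ndarray, cell_ids, vote_fraction: float = 0.10
) -> np.ndarray:
    """Keep cells flagged in at most ``vote_fraction`` of the runs.

    The discard rule is strict: a cell is removed iff
    flags / runs > vote_fraction, so a cell flagged in exactly 10% of
    100 runs is kept.
    """
    call_matrix = np.asarray(call_matrix, dtype=bool)
    if call_matrix.ndim != 2 or call_matrix.shape[1] == 0:
        raise ValueError("call_matrix must be cells x runs with at least one run")
    frac = call_matrix.mean(axis=1)
    keep = frac <= vote_fraction
    return np.asarray(cell_ids, dtype=object)[keep]


def _score_one_run(
    counts_smp: sp.csr_matrix, rng: np.random.Generator, svd_seed: int, n_hvg: int = 1000
) -> np.ndarray:
    """One simulated-doublet k-NN scoring run on a single sample."""
    n_obs = counts_smp.shape[0]
    n_sim = 2 * n_obs
    left = rng.integers(0, n_obs, size=n_sim)
    right = rng.integers(0, n_obs, size=n_sim)
    sim = counts_smp[left] + counts_smp[right]
    combined = sp.vstack([counts_smp, sim], format="csr")

    # library normalization + log1p
    totals = np.asarray(combined.sum(axis=1)).ravel()
    totals[totals == 0] = 1.0
    norm = combined.multiply(1e4 / totals[:, None]).tocsr()
    norm.data = np.log1p(norm.data)

    # top genes by variance among observed cells
    obs = norm[:n_obs]
    mean = np.asarray(obs.mean(axis=0)).ravel()
    sq = np.asarray(obs.multiply(obs).mean(axis=0)).ravel()
    var = sq - mean**2
    top = np.argsort(-var, kind="stable")[: min(n_hvg, norm.shape[1])]
    X = norm[:, top]

    n_comp = min(30, X.shape[1] - 1, combined.shape[0] - 1)
    emb = TruncatedSVD(n_components=n_comp, random_state=svd_seed).fit_transform(X)

    k = max(10, int(round(0.5 * np.sqrt(n_obs))) * 3)  # scaled for 1:2 sim ratio
    nn = NearestNeighbors(n_neighbors=min(k + 1, emb.shape[0])).fit(emb)
    _, idx = nn.kneighbors(emb)
    idx = idx[:, 1:]  # drop self
    is_sim = idx >= n_obs
    scores = is_sim.mean(axis=1)
    return scores[:n_obs], scores[n_obs:]


def _valley_threshold(sim_scores: np.ndarray) -> float | None:
    """Minimum-density valley of the simulated-doublet score distribution.

    Simulated doublets fall into an "embedded" low-score mode (parents
    from the same cluster) and a "neotypic" high-score mode; the valley
    between the lowest and highest substantial modes separates them.
    Returns None when the smoothed histogram is unimodal.
    """
    hist, edges = np.histogram(sim_scores, bins=40, range=(0.0, 1.0))
    smooth = gaussian_filter1d(hist.astype(float), sigma=2.5)
    floor = 0.05 * smooth.max()
    peaks = [
        i
        for i in range(1, len(smooth) - 1)
        if smooth[i] >= smooth[i - 1] and smooth[i] >= smooth[i + 1]
        and smooth[i] > floor
    ]
    if len(peaks) < 2 or peaks[-1] - peaks[0] < 2:
        return None
    lo, hi = peaks[0], peaks[-1]
    valley = lo + int(np.argmin(smooth[lo : hi + 1]))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return float(centers[valley])


def run_doublet_scorer(
    counts: CountMatrix,
    n_runs: int,
    expected_rate: float = 0.05,
    seed: int = 0,
    min_cells: int = 50,
) -> np.ndarray:
    """Boolean cell x run doublet call matrix, scored per sample.

    Each run simulates doublets by summing random same-sample cell
    pairs, embeds observed + simulated cells with a 30-component
    truncated SVD, scores each cell by its simulated-doublet neighbor
    fraction, and auto-thresholds at the minimum-density valley of the
    simulated-doublet score distribution (falling back to the
    ``1 - expected_rate`` quantile of observed scores when unimodal).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    calls = np.zeros((counts.n_cells, n_runs), dtype=bool)
    samples = counts.cell_meta["sample_id"].to_numpy()
    for smp in pd.unique(samples):
        members = np.flatnonzero(samples == smp)
        if len(members) < min_cells:
            warnings.warn(f"sample {smp} has <{min_cells} cells; no doublet calls")
            continue
        sub = counts.counts[members]
        for run in range(n_runs):
            rng = np.random.default_rng([seed, run, zlib.crc32(str(smp).encode())])
            svd_seed = int(rng.integers(0, 2**31 - 1))
            obs_scores, sim_scores = _score_one_run(sub, rng, svd_seed)
            thr = _valley_threshold(sim_scores)
            if thr is None:
                # unimodal simulated scores: no doublet mode to separate,
                # so flag only cells scoring above (1 - expected_rate) of
                # the simulated doublets themselves. A quantile of the
                # observed scores would flag a fixed share of cells every
                # run even on doublet-free data, and those false flags
                # repeat across runs, defeating the consensus vote.
                thr = float(np.quantile(sim_scores, 1.0 - expected_rate))
            calls[members, run] = obs_scores > thr
    return calls


# ---------------------------------------------------------------------------
# count filters
# ---------------------------------------------------------------------------

def basic_count_filter(counts: CountMatrix, t: QCThresholds) -> np.ndarray:
    """Cells kept under the UMI / gene / mitochondrial bounds."""
    n_umis = counts.n_umis
    n_genes = counts.n_genes
    mito = counts.mito_fraction
    keep = (
        (n_umis >= t.min_umis)
        & (n_umis <= t.max_umis)
        & (n_genes >= t.min_genes)
        & (n_genes <= t.max_genes)
        & (mito <= t.max_mito)
    )
    return counts.cell_ids[keep]


def fit_gene_umi_polynomial(counts: CountMatrix, degree: int = 2) -> np.ndarray:
    """Least-squares fit of log(n_genes) on log(n_umis), degree 2.

    Returns coefficients in increasing order (intercept first).
    """
    n_umis = counts.n_umis.astype(float)
    n_genes = counts.n_genes.astype(float)
    if counts.n_cells < 10:
        raise ValueError("need at least 10 cells to fit the gene-UMI polynomial")
    if (n_umis <= 0).any() or (n_genes <= 0).any():
        raise ValueError("all cells must have positive UMI and gene counts")
    x = np.log(n_umis)
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all cells have identical n_umis")
    y = np.log(n_genes)
    coeffs = np.polynomial.polynomial.polyfit(x, y, degree)
    return coeffs


def polynomial_outlier_filter(
    counts: CountMatrix, coeffs: np.ndarray, delta: float = 2000.0,
    log_scale: bool = False,
) -> np.ndarray:
    """Remove cells deviating from the gene-UMI fit by more than ``delta``.

    The deviation is measured in gene-count units after back-
    transforming the predicted log(n_genes); set ``log_scale`` to apply
    ``delta`` in log units instead.
    """
    x = np.log(counts.n_umis.astype(float))
    pred_log = np.polynomial.polynomial.polyval(x, coeffs)
    if log_scale:
        dev = np.abs(np.log(counts.n_genes.astype(float)) - pred_log)
    else:
        dev = np.abs(counts.n_genes - np.exp(pred_log))
    return counts.cell_ids[dev <= delta]


# ---------------------------------------------------------------------------
# marker-score mixture thresholds
# ---------------------------------------------------------------------------

def marker_score(
    norm_expr: pd.DataFrame, panel: dict[str, list[str]]
) -> pd.DataFrame:
    """Mean normalized expression of each type's markers, per cell.

    ``norm_expr`` is a cells x genes frame of normalized log expression
    restricted to (at least) the panel genes. Markers missing from the
    gene universe are dropped with a warning; a type losing all its
    markers is an error.
    """
    scores = {}
    for cell_type, markers in panel.items():
        present = [g for g in markers if g in norm_expr.columns]
        missing = set(markers) - set(present)
        if missing:
            warnings.warn(f"markers missing for {cell_type}: {sorted(missing)}")
        if not present:
            raise ValueError(f"no markers of type {cell_type!r} found in gene universe")
        scores[cell_type] = norm_expr[present].mean(axis=1)
    return pd.DataFrame(scores, index=norm_expr.index)


@dataclass
class MixtureThreshold:
    mu_low: float
    sigma_low: float
    mu_high: float
    sigma_high: float
    weight_low: float
    threshold: float
    fallback: bool = False


def mixture_threshold(scores: np.ndarray, min_scores: int = 100) -> MixtureThreshold:
    """Two-Gaussian mixture fit; threshold = mu_low + 4 * sigma_low.

    Components are ordered by mean so the "low" component is
    well-defined regardless of EM initialization. Degenerate inputs
    fall back to a single-Gaussian mu + 4 * sigma rule.
    """
    scores = np.asarray(scores, dtype=float).reshape(-1, 1)
    if len(scores) < min_scores:
        raise ValueError(f"need >= {min_scores} scores to fit the mixture")
    if np.ptp(scores) < 1e-12:
        mu = float(scores.mean())
        warnings.warn("constant scores; falling back to single-Gaussian threshold")
        return MixtureThreshold(mu, 0.0, mu, 0.0, 1.0, mu, fallback=True)
    try:
        gm = GaussianMixture(
            n_components=2,
            covariance_type="full",
            max_iter=200,
            tol=1e-6,
            reg_covar=1e-10,
            init_params="k-means++",
            random_state=0,
        ).fit(scores)
        mus = gm.means_.ravel()
        sds = np.sqrt(gm.covariances_.ravel())
        ws = gm.weights_.ravel()
        order = np.argsort(mus)
        mus, sds, ws = mus[order], sds[order], ws[order]
        if not np.all(np.isfinite(sds)) or sds[0] <= 0:
            raise ValueError("degenerate component variance")
        return MixtureThreshold(
            float(mus[0]), float(sds[0]), float(mus[1]), float(sds[1]),
            float(ws[0]), float(mus[0] + 4 * sds[0]),
        )
    except Exception as err:  # EM failure: single-Gaussian fallback
        warnings.warn(f"mixture fit failed ({err}); single-Gaussian fallback")
        mu, sd = float(scores.mean()), float(scores.std())
        return MixtureThreshold(mu, sd, mu, sd, 1.0, mu + 4 * sd, fallback=True)


def multi_identity_doublet_filter(
    score_table: pd.DataFrame, thresholds: dict[str, MixtureThreshold]
) -> tuple[np.ndarray, pd.Series]:
    """Type cells by their above-threshold scores; exclude multi-typed cells.

    Returns (kept cell ids, per-kept-cell type, "none" when untyped).
    """
    missing = set(score_table.columns) - set(thresholds)
    if missing:
        raise ValueError(f"no mixture threshold for types: {sorted(missing)}")
    above = pd.DataFrame(
        {t: score_table[t] > thresholds[t].threshold for t in score_table.columns}
    )
    n_above = above.sum(axis=1)
    keep = n_above <= 1
    types = pd.Series("none", index=score_table.index, dtype=object)
    single = n_above == 1
    types[single] = above.loc[single].idxmax(axis=1)
    return score_table.index.to_numpy()[keep.to_numpy()], types[keep]


def regional_marker_filter(
    norm_expr: pd.DataFrame,
    region_markers: list[str] = REGIONAL_MARKERS,
    min_expr: float = 0.0,
) -> np.ndarray:
    """Remove cells expressing any regional contamination marker above
    ``min_expr`` (default: any detection)."""
    present = [g for g in region_markers if g in norm_expr.columns]
    missing = set(region_markers) - set(present)
    if missing:
        warnings.warn(f"regional markers missing from data: {sorted(missing)}")
    if not present:
        return norm_expr.index.to_numpy()
    contaminated = (norm_expr[present] > min_expr).any(axis=1)
    return norm_expr.index.to_numpy()[~contaminated.to_numpy()]


# ---------------------------------------------------------------------------
# full cascade
# ---------------------------------------------------------------------------

def run_qc_cascade(
    counts: CountMatrix,
    t: QCThresholds | None = None,
    panel: dict[str, list[str]] | None = None,
    seed: int = 0,
    expected_doublet_rate: float = 0.05,
) -> tuple[CountMatrix, pd.DataFrame, pd.Series]:
    """Run the full QC cascade; returns (filtered counts, funnel, types).

    The funnel table records (stage, cells_in, cells_removed) for every
    stage; per-cell types come from the marker-score step.
    """
    from .taxonomy import normalize_log

    t = t or QCThresholds()
    panel = panel or DEFAULT_MARKER_PANEL
    funnel = []

    def log_stage(stage: str, before: int, after: int):
        funnel.append((stage, before, before - after))

    # 1. consensus doublet voting
    calls = run_doublet_scorer(
        counts, n_runs=t.n_doublet_runs, expected_rate=expected_doublet_rate, seed=seed
    )
    kept = consensus_doublet_filter(calls, counts.cell_ids, t.doublet_vote_fraction)
    log_stage("consensus_doublets", counts.n_cells, len(kept))
    cur = counts.subset_cells(kept)

    # 2. basic count / mito filters
    kept = basic_count_filter(cur, t)
    log_stage("count_filters", cur.n_cells, len(kept))
    cur = cur.subset_cells(kept)

    # 3. gene-UMI polynomial outliers
    coeffs = fit_gene_umi_polynomial(cur, t.poly_degree)
    kept = polynomial_outlier_filter(
        cur, coeffs, t.poly_outlier_delta, t.poly_outlier_log_scale
    )
    log_stage("poly_outliers", cur.n_cells, len(kept))
    cur = cur.subset_cells(kept)

    # 4. marker-score mixture thresholds, multi-identity removal
    panel_genes = sorted({g for gs in panel.values() for g in gs if g in set(cur.gene_names)})
    norm = normalize_log(cur)
    expr = norm.expr_frame(panel_genes)
    scores = marker_score(expr, panel)
    thresholds = {ct: mixture_threshold(scores[ct].to_numpy()) for ct in scores.columns}
    kept, types = multi_identity_doublet_filter(scores, thresholds)
    log_stage("multi_identity", cur.n_cells, len(kept))
    cur = cur.subset_cells(kept)

    # 5. regional contamination markers
    present = [g for g in REGIONAL_MARKERS if g in set(cur.gene_names)]
    if present:
        norm = normalize_log(cur)
        expr = norm.expr_frame(present)
        kept = regional_marker_filter(expr, present, t.regional_min_expr)
        log_stage("regional_markers", cur.n_cells, len(kept))
        cur = cur.subset_cells(kept)

    funnel_df = pd.DataFrame(funnel, columns=["stage", "cells_in", "cells_removed"])
    return cur, funnel_df, types.loc[[c for c in cur.cell_ids]]
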