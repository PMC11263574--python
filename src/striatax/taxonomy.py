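"""Normalization, clustering and the interneuron class taxonomy.

The classification is iterative: broad Louvain clustering (30 PCs,
resolution 0.2) labels clusters as glia or neurons by canonical
markers; neurons are re-filtered on depth; inhibitory/cholinergic
gating (GAD1/GAD2/CHAT positive, MSN and excitatory markers negative)
selects interneurons; interneurons are re-clustered (1500 HVGs, 20 PCs)
into subclasses; and subclasses whose mean expression profiles
correlate above r = 0.49 are merged into main classes, summarized by an
average-linkage dendrogram on 1 - r.
"""

from __future__ import annotations

import random
import warnings
import zlib
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import linkage
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

from .config import QCThresholds, TaxonomyParams
from .containers import CountMatrix

RIBO_PREFIXES = ("RPS", "RPL", "MRPS", "MRPL")
SEX_LINKED_GENES = frozenset(
    ["XIST", "TSIX", "RPS4Y1", "RPS4Y2", "DDX3Y", "KDM5D", "UTY",
     "USP9Y", "EIF1AY", "NLGN4Y", "TXLNGY", "ZFY", "SRY"]
)

POSITIVE_GATE = ("GAD1", "GAD2", "CHAT")
NEGATIVE_GATE = ("PPP1R1B", "DRD1", "DRD2", "MEIS2", "RORB")


@dataclass
class NormalizedMatrix:
    """Cells x genes log1p(counts scaled to ``target_sum``) matrix."""

    values: sp.csr_matrix
    cell_ids: np.ndarray
    gene_names: np.ndarray
    target_sum: float = 10_000.0
    cell_meta: pd.DataFrame = field(default=None)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def gene_index(self, names) -> np.ndarray:
        pos = pd.Index(self.gene_names).get_indexer(names)
        if (pos < 0).any():
            missing = np.asarray(names)[pos < 0][:5]
            raise KeyError(f"unknown genes: {list(missing)}")
        return pos

    def expr_frame(self, genes) -> pd.DataFrame:
        """Dense frame of selected genes (cells x genes)."""
        idx = self.gene_index(genes)
        return pd.DataFrame(
            self.values[:, idx].toarray(), index=self.cell_ids, columns=genes
        )

    def subset_cells(self, cell_ids) -> "NormalizedMatrix":
        pos = pd.Index(self.cell_ids).get_indexer(cell_ids)
        if (pos < 0).any():
            raise KeyError("unknown cell ids in subset")
        meta = None if self.cell_meta is None else self.cell_meta.iloc[pos]
        return NormalizedMatrix(
            self.values[pos], np.asarray(self.cell_ids)[pos], self.gene_names,
            self.target_sum, meta,
        )


def normalize_log(counts: CountMatrix, target_sum: float = 10_000.0) -> NormalizedMatrix:
    """Per-cell total-count scaling to ``target_sum`` followed by log1p."""
    totals = counts.n_umis.astype(float)
    if (totals == 0).any():
        bad = counts.cell_ids[totals == 0][0]
        raise ValueError(f"cell {bad!r} has zero total counts; cannot normalize")
    mat = counts.counts.astype(float).multiply(target_sum / totals[:, None]).tocsr()
    mat.data = np.log1p(mat.data)
    return NormalizedMatrix(
        mat, counts.cell_ids.copy(), counts.gene_names.copy(),
        target_sum, counts.cell_meta,
    )


def gene_exclusion_mask(
    gene_names,
    exclude: set[str] = frozenset({"sex", "mito", "ribo"}),
    sex_genes: frozenset = SEX_LINKED_GENES,
) -> np.ndarray:
    """True for genes flagged sex-linked / mitochondrial / riboprotein."""
    mask = np.zeros(len(gene_names), dtype=bool)
    for i, g in enumerate(gene_names):
        gu = g.upper()
        if "mito" in exclude and gu.startswith("MT-"):
            mask[i] = True
        elif "ribo" in exclude and gu.startswith(RIBO_PREFIXES):
            mask[i] = True
        elif "sex" in exclude and gu in sex_genes:
            mask[i] = True
    return mask


def select_hvg(
    norm: NormalizedMatrix,
    n: int,
    exclude: set[str] = frozenset({"sex", "mito", "ribo"}),
    n_bins: int = 20,
) -> list[str]:
    """Top-``n`` highly variable genes by mean-binned normalized dispersion.

    Dispersion (variance / mean of the normalized log values) is
    z-scored within 20 mean-quantile bins; flagged gene categories are
    excluded; ties break by gene-name lexicographic order.
    """
    excl = gene_exclusion_mask(norm.gene_names, exclude)
    eligible = ~excl
    if n > eligible.sum():
        raise ValueError(f"requested {n} HVGs but only {eligible.sum()} eligible genes")

    v = norm.values
    mean = np.asarray(v.mean(axis=0)).ravel()
    sq = np.asarray(v.multiply(v).mean(axis=0)).ravel()
    var = np.maximum(sq - mean**2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)

    idx = np.flatnonzero(eligible)
    m, d = mean[idx], disp[idx]
    # quantile bins on the mean; z-score dispersion within each bin
    qs = np.quantile(m, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(qs, m, side="right") - 1, 0, n_bins - 1)
    norm_disp = np.zeros_like(d)
    for b in range(n_bins):
        members = bins == b
        if not members.any():
            continue
        mu, sd = d[members].mean(), d[members].std()
        norm_disp[members] = (d[members] - mu) / (sd if sd > 0 else 1.0)
    norm_disp = np.where(var[idx] > 0, norm_disp, -np.inf)

    names = norm.gene_names[idx]
    order = sorted(range(len(idx)), key=lambda i: (-norm_disp[i], names[i]))
    return [names[i] for i in order[:n]]


def _louvain(graph: ig.Graph, resolution: float, seed: int) -> np.ndarray:
    state = random.Random(seed)
    ig.set_random_number_generator(state)
    part = graph.community_multilevel(resolution=resolution)
    ig.set_random_number_generator(random)  # restore default
    return np.asarray(part.membership)


def embed_cluster(
    norm: NormalizedMatrix,
    hvgs: list[str],
    n_pcs: int,
    resolution: float,
    seed: int = 0,
    knn: int = 15,
) -> np.ndarray:
    """PCA on standardized HVGs, k-NN graph, Louvain community labels.

    Labels are contiguous integers ordered by descending cluster size.
    """
    if norm.n_cells <= knn:
        raise ValueError(f"need more than k={knn} cells to build the k-NN graph")
    X = norm.values[:, norm.gene_index(hvgs)].toarray()
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = np.clip((X - mu) / sd, -10, 10)
    n_pcs = min(n_pcs, min(X.shape) - 1)
    pcs = PCA(
        n_components=n_pcs, svd_solver="randomized", random_state=seed % (2**31)
    ).fit_transform(X)

    adj = kneighbors_graph(pcs, n_neighbors=knn, mode="connectivity")
    adj = adj.maximum(adj.T)  # symmetrize by union
    sources, targets = adj.nonzero()
    mask = sources < targets
    graph = ig.Graph(
        n=adj.shape[0], edges=list(zip(sources[mask], targets[mask])), directed=False
    )
    labels = _louvain(graph, resolution, seed)

    # relabel by descending size
    sizes = pd.Series(labels).value_counts()
    remap = {old: new for new, old in enumerate(sizes.index)}
    return np.array([remap[x] for x in labels])


def cluster_mean_expression(
    norm: NormalizedMatrix, labels: np.ndarray, genes: list[str]
) -> pd.DataFrame:
    """Cluster x gene mean normalized expression."""
    idx = norm.gene_index(genes)
    out = {}
    for lab in pd.unique(labels):
        members = np.flatnonzero(labels == lab)
        out[lab] = np.asarray(norm.values[members][:, idx].mean(axis=0)).ravel()
    return pd.DataFrame(out, index=genes).T


def label_clusters_by_markers(
    norm: NormalizedMatrix,
    labels: np.ndarray,
    panel: dict[str, list[str]],
    margin: float = 0.05,
    min_cluster_size: int = 5,
) -> dict[int, str]:
    """Assign each cluster the best-scoring panel type, or "unassigned".

    The type's score is the mean cluster-level expression of its
    markers; assignment requires beating the runner-up by ``margin``.
    """
    universe = set(norm.gene_names)
    panel_present = {
        t: [g for g in gs if g in universe] for t, gs in panel.items()
    }
    panel_present = {t: gs for t, gs in panel_present.items() if gs}
    genes = sorted({g for gs in panel_present.values() for g in gs})
    means = cluster_mean_expression(norm, labels, genes)
    out = {}
    for lab in means.index:
        scores = {
            t: float(np.mean([means.loc[lab, g] for g in gs]))
            for t, gs in panel_present.items()
        }
        ordered = sorted(scores.items(), key=lambda kv: -kv[1])
        n_members = int((labels == lab).sum())
        if n_members < min_cluster_size:
            out[lab] = "unassigned"
        elif len(ordered) == 1 or ordered[0][1] - ordered[1][1] > margin:
            out[lab] = ordered[0][0]
        else:
            out[lab] = "unassigned"
    return out


def neuron_quality_refilter(
    counts: CountMatrix, neuron_ids, t: QCThresholds | None = None
) -> np.ndarray:
    """Depth re-filter applied to neuron-labeled nuclei only."""
    t = t or QCThresholds()
    sub = counts.subset_cells(neuron_ids)
    keep = (
        (sub.n_umis >= t.neuron_min_umis)
        & (sub.n_genes >= t.neuron_min_genes)
        & (sub.n_genes <= t.neuron_max_genes)
    )
    return sub.cell_ids[keep]


def select_interneurons(
    norm: NormalizedMatrix,
    labels: np.ndarray,
    positive: tuple = POSITIVE_GATE,
    negative: tuple = NEGATIVE_GATE,
    positive_threshold: float = 0.25,
    negative_threshold: float = 0.10,
) -> np.ndarray:
    """Cluster-level gating: any positive marker above threshold and all
    negative (MSN / excitatory) markers below threshold."""
    universe = set(norm.gene_names)
    pos = [g for g in positive if g in universe]
    neg = [g for g in negative if g in universe]
    if not pos:
        raise ValueError("no positive gating markers present in gene universe")
    means = cluster_mean_expression(norm, labels, pos + neg)
    keep_ids = []
    for lab in means.index:
        pos_ok = any(means.loc[lab, g] > positive_threshold for g in pos)
        neg_ok = all(means.loc[lab, g] < negative_threshold for g in neg)
        if pos_ok and neg_ok:
            keep_ids.extend(norm.cell_ids[labels == lab])
    return np.asarray(keep_ids, dtype=object)


def subclass_clustering(
    norm: NormalizedMatrix,
    params: TaxonomyParams | None = None,
    seed: int = 0,
) -> pd.Series:
    """Re-cluster interneurons into subclasses (1500 HVGs, 20 PCs).

    A post-hoc gate removes clusters that still express MSN or
    excitatory markers above the negative threshold. Returns per-cell
    integer subclass labels for the retained cells.
    """
    params = params or TaxonomyParams()
    if norm.n_cells < 100:
        raise ValueError("need at least 100 interneurons for subclass clustering")
    hvgs = select_hvg(norm, min(params.subclass_n_hvg, len(norm.gene_names) - 1))
    labels = embed_cluster(
        norm, hvgs, params.subclass_n_pcs, params.subclass_resolution,
        seed=seed, knn=params.knn,
    )
    universe = set(norm.gene_names)
    neg = [g for g in NEGATIVE_GATE if g in universe]
    bad = set()
    if neg:
        means = cluster_mean_expression(norm, labels, neg)
        for lab in means.index:
            if any(means.loc[lab, g] > params.negative_threshold for g in neg):
                bad.add(lab)
                warnings.warn(f"subclass cluster {lab} removed by post-hoc gate")
    keep = ~np.isin(labels, list(bad))
    kept_labels = labels[keep]
    # keep labels contiguous by size after the gate
    sizes = pd.Series(kept_labels).value_counts()
    remap = {old: new for new, old in enumerate(sizes.index)}
    return pd.Series(
        [remap[x] for x in kept_labels], index=norm.cell_ids[keep], name="subclass"
    )


# ---------------------------------------------------------------------------
# marker ranking (one-vs-rest Wilcoxon rank-sum)
# ---------------------------------------------------------------------------

def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def rank_marker_genes(norm: NormalizedMatrix, labels) -> pd.DataFrame:
    """One-vs-rest two-sided Wilcoxon rank-sum per gene and group.

    Uses the normal approximation with tie correction (the behaviour of
    standard scRNA-seq marker ranking); all-tied genes get p = 1.
    Returns a long table (group, gene, score, log2_fold, pval, padj)
    sorted by score within group; BH adjustment is within group.
    """
    labels = np.asarray(labels)
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to rank marker genes")
    for g in groups:
        if (labels == g).sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 cells")

    X = norm.values.toarray()
    n_cells, n_genes = X.shape
    ranks = rankdata(X, axis=0, method="average")

    # tie correction term per gene: sum(t^3 - t) over tied groups
    tie_term = np.zeros(n_genes)
    for j in range(n_genes):
        _, cnt = np.unique(X[:, j], return_counts=True)
        tie_term[j] = float((cnt.astype(float) ** 3 - cnt).sum())

    rows = []
    N = n_cells
    for g in groups:
        in_g = labels == g
        n1 = int(in_g.sum())
        n2 = N - n1
        r1 = ranks[in_g].sum(axis=0)
        u = r1 - n1 * (n1 + 1) / 2.0
        mean_u = n1 * n2 / 2.0
        var_u = (n1 * n2 / 12.0) * ((N + 1) - tie_term / (N * (N - 1.0)))
        var_u = np.maximum(var_u, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(var_u > 0, (u - mean_u) / np.sqrt(var_u), 0.0)
        from scipy.stats import norm as norm_dist

        p = np.where(var_u > 0, 2 * norm_dist.sf(np.abs(z)), 1.0)
        padj = _bh_adjust(p)

        mean_in = X[in_g].mean(axis=0)
        mean_out = X[~in_g].mean(axis=0)
        eps = 1e-9
        log2fold = np.log2((np.expm1(mean_in) + eps) / (np.expm1(mean_out) + eps))

        df = pd.DataFrame(
            {
                "group": g,
                "gene": norm.gene_names,
                "score": z,
                "log2_fold": log2fold,
                "pval": p,
                "padj": padj,
            }
        ).sort_values("score", ascending=False, kind="stable")
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# correlation merge into main classes
# ---------------------------------------------------------------------------

def subclass_profiles(norm: NormalizedMatrix, labels: pd.Series) -> pd.DataFrame:
    """Mean normalized expression profile per subclass (across all genes)."""
    sub = norm.subset_cells(labels.index)
    out = {}
    for lab in pd.unique(labels.to_numpy()):
        members = np.flatnonzero(labels.to_numpy() == lab)
        out[lab] = np.asarray(sub.values[members].mean(axis=0)).ravel()
    return pd.DataFrame(out, index=norm.gene_names)


def merge_subclasses(
    norm: NormalizedMatrix,
    labels: pd.Series,
    r_threshold: float = 0.49,
    mode: str = "components",
) -> tuple[pd.Series, pd.DataFrame, np.ndarray, str]:
    """Merge subclasses whose mean profiles correlate above ``r_threshold``.

    Default semantics: connected components of the graph with an edge
    wherever Pearson r strictly exceeds the threshold; ``mode="clique"``
    requires all pairwise correlations of a merged group to exceed it.
    Returns (per-cell class labels, correlation matrix, average-linkage
    linkage matrix on 1 - r, Newick dendrogram). Classes are named
    after their largest member subclass.
    """
    profiles = subclass_profiles(norm, labels)
    subs = list(profiles.columns)
    if len(subs) < 2:
        raise ValueError("need at least 2 subclasses to merge")
    corr = pd.DataFrame(
        np.corrcoef(profiles.to_numpy().T), index=subs, columns=subs
    )

    adj = (corr.to_numpy() > r_threshold).astype(int)
    np.fill_diagonal(adj, 0)
    if mode == "components":
        n_comp, comp = connected_components(sp.csr_matrix(adj), directed=False)
        groups = [np.array(subs, dtype=object)[comp == c] for c in range(n_comp)]
    elif mode == "clique":
        # greedy: repeatedly extract the largest clique in the threshold graph
        import networkx as nx

        G = nx.Graph()
        G.add_nodes_from(range(len(subs)))
        G.add_edges_from(zip(*np.nonzero(np.triu(adj))))
        remaining = set(range(len(subs)))
        groups = []
        while remaining:
            cliques = [
                c for c in nx.find_cliques(G.subgraph(remaining)) if c
            ]
            best = max(cliques, key=lambda c: (len(c), -min(c)))
            groups.append(np.array(subs, dtype=object)[sorted(best)])
            remaining -= set(best)
    else:
        raise ValueError(f"unknown merge mode {mode!r}")

    sizes = labels.value_counts()
    sub_to_class = {}
    for members in groups:
        name = str(max(members, key=lambda s: (sizes.get(s, 0), str(s))))
        for s in members:
            sub_to_class[s] = name
    class_labels = labels.map(sub_to_class).rename("class")

    dist = squareform(1.0 - corr.to_numpy(), checks=False)
    Z = linkage(dist, method="average")
    from .io import linkage_to_newick

    newick = linkage_to_newick(Z, [str(s) for s in subs])
    return class_labels, corr, Z, newick


def _stable_hash(s: str) -> int:
    return zlib.crc32(str(s).encode())
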