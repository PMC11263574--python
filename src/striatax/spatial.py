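"""Spatial annotation and neighborhood enrichment.

Cells measured on a targeted spatial panel are annotated by
hierarchical count-based marker gating (neuron: GAD1 positive, OLIG1
and MOBP absent; interneuron: additionally LHX6 or SST positive and
MEIS2 absent; subclass: a marker-positivity table). Spatial proximity
between annotated populations is quantified by a permutation z-score
of the number of neighbor-graph edges joining two labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import Delaunay, QhullError
from sklearn.neighbors import kneighbors_graph

# default subclass marker-positivity table: required markers with
# minimum copy numbers; more specific rows (more markers) win
DEFAULT_SUBCLASS_RULES: list[tuple[str, dict[str, int]]] = [
    ("CCK/VIP/CXCL14", {"CCK": 3, "VIP": 3, "CXCL14": 2}),
    ("CCK/VIP", {"CCK": 3, "VIP": 3}),
    ("CCK/CHST9", {"CCK": 3, "CHST9": 2}),
    ("CCK", {"CCK": 3, "ADARB2": 2}),
    ("PVALB/GRIK3", {"PVALB": 3, "GRIK3": 2}),
    ("PVALB", {"PVALB": 3}),
    ("SST/NPY/DACH1", {"SST": 3, "NPY": 3, "DACH1": 2}),
    ("SST/NPY", {"SST": 3, "NPY": 3}),
    ("SST/GRIK3", {"SST": 3, "GRIK3": 2}),
    ("PTHLH/MOXD1", {"PTHLH": 3, "MOXD1": 2}),
    ("PTHLH", {"PTHLH": 3}),
    ("CHAT", {"CHAT": 3}),
    ("TAC3/SEMA3A", {"TAC3": 3, "SEMA3A": 2}),
    ("TAC3", {"TAC3": 3, "PTPRK": 2}),
]


@dataclass
class SpatialDataset:
    """Per-cell 2-D coordinates with labels and optional expression."""

    coords: np.ndarray
    labels: np.ndarray
    expression: pd.DataFrame | None = None
    graph: sp.spmatrix | None = None
    graph_method: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")


@dataclass
class NeighborhoodEnrichment:
    zscores: pd.DataFrame
    observed: pd.DataFrame
    perm_mean: pd.DataFrame
    perm_sd: pd.DataFrame
    n_permutations: int
    seed: int
    degenerate_pairs: list[tuple[str, str]] = field(default_factory=list)


def annotate_spatial_cells(
    expr: pd.DataFrame,
    subclass_rules: list[tuple[str, dict[str, int]]] | None = None,
    pos_count: int = 3,
    neg_count: int = 1,
) -> pd.Series:
    """Hierarchical count-based gating of spatial cells.

    ``expr`` holds per-cell panel-gene counts. A cell is a neuron when
    GAD1 >= ``pos_count`` and both OLIG1 and MOBP are below
    ``neg_count``; an interneuron when additionally LHX6 or SST is
    >= ``pos_count`` and MEIS2 is below ``neg_count``; interneurons are
    assigned the most specific matching subclass rule, else
    "unassigned".
    """
    rules = DEFAULT_SUBCLASS_RULES if subclass_rules is None else subclass_rules
    for gene in ("GAD1", "OLIG1", "MOBP", "LHX6", "SST", "MEIS2"):
        if gene not in expr.columns:
            raise ValueError(f"gating gene {gene!r} missing from spatial panel")
    labels = pd.Series("non-neuron", index=expr.index, dtype=object)
    neuron = (
        (expr["GAD1"] >= pos_count)
        & (expr["OLIG1"] < neg_count)
        & (expr["MOBP"] < neg_count)
    )
    labels[neuron] = "neuron"
    inter = neuron & ((expr["LHX6"] >= pos_count) | (expr["SST"] >= pos_count))
    inter &= expr["MEIS2"] < neg_count
    labels[inter] = "unassigned"
    ordered = sorted(rules, key=lambda r: -len(r[1]))  # most specific first
    for name, req in ordered:
        present = {g: c for g, c in req.items() if g in expr.columns}
        missing = set(req) - set(present)
        if missing:
            warnings.warn(f"subclass {name}: markers missing from panel {sorted(missing)}")
        if not present:
            continue
        match = inter & (labels == "unassigned")
        for g, c in present.items():
            match &= expr[g] >= c
        labels[match] = name
    return labels


def build_neighbor_graph(
    coords: np.ndarray,
    method: str = "delaunay",
    k: int = 6,
    prune_quantile: float = 0.99,
) -> sp.csr_matrix:
    """Undirected neighbor graph: Delaunay (pruned) or symmetrized k-NN."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 3:
        raise ValueError("need at least 3 cells to build a neighbor graph")
    if method == "delaunay":
        try:
            tri = Delaunay(coords)
        except QhullError:
            warnings.warn("degenerate Delaunay input; falling back to k-NN")
            return build_neighbor_graph(coords, method="knn", k=min(k, n - 1))
        edges = set()
        for simplex in tri.simplices:
            for a in range(3):
                for b in range(a + 1, 3):
                    i, j = sorted((simplex[a], simplex[b]))
                    edges.add((i, j))
        edges = np.array(sorted(edges))
        lengths = np.linalg.norm(coords[edges[:, 0]] - coords[edges[:, 1]], axis=1)
        if prune_quantile is not None and len(edges) > 1:
            cut = np.quantile(lengths, prune_quantile)
            edges = edges[lengths <= cut]
        adj = sp.coo_matrix(
            (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n)
        ).tocsr()
        adj = adj + adj.T
    elif method == "knn":
        adj = kneighbors_graph(coords, n_neighbors=min(k, n - 1), mode="connectivity")
        adj = adj.maximum(adj.T)
    else:
        raise ValueError(f"unknown graph method {method!r}")
    adj.setdiag(0)
    adj.eliminate_zeros()
    adj.data[:] = 1.0
    return adj.tocsr()


def _pair_counts(adj_ij: np.ndarray, codes: np.ndarray, n_labels: int) -> np.ndarray:
    """Label-pair edge counts from an edge list (upper-triangle convention)."""
    a = codes[adj_ij[:, 0]]
    b = codes[adj_ij[:, 1]]
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    flat = np.bincount(lo * n_labels + hi, minlength=n_labels * n_labels)
    mat = flat.reshape(n_labels, n_labels).astype(float)
    return mat + np.triu(mat, 1).T  # symmetric, diagonal unduplicated


def neighborhood_enrichment(
    graph: sp.spmatrix,
    labels,
    n_perm: int = 1000,
    seed: int = 0,
) -> NeighborhoodEnrichment:
    """Permutation z-scores of label-pair edge counts on a fixed graph.

    z(a, b) = (observed(a, b) - mean_perm) / sd_perm under label
    shuffling; pairs with zero permutation sd are reported with z = 0
    and flagged.
    """
    labels = np.asarray(labels, dtype=object)
    uniq = sorted(set(labels), key=str)
    if len(uniq) < 2:
        raise ValueError("need at least 2 distinct labels")
    codes = np.array([uniq.index(x) for x in labels])
    adj = sp.triu(sp.csr_matrix(graph), k=1).tocoo()
    edge_list = np.column_stack([adj.row, adj.col])
    L = len(uniq)

    observed = _pair_counts(edge_list, codes, L)
    rng = np.random.default_rng(seed)
    perm_sum = np.zeros_like(observed)
    perm_sq = np.zeros_like(observed)
    for _ in range(n_perm):
        shuffled = rng.permutation(codes)
        c = _pair_counts(edge_list, shuffled, L)
        perm_sum += c
        perm_sq += c * c
    mean = perm_sum / n_perm
    var = np.maximum(perm_sq / n_perm - mean**2, 0.0)
    sd = np.sqrt(var)
    degenerate = []
    z = np.zeros_like(observed)
    nonzero = sd > 0
    z[nonzero] = (observed[nonzero] - mean[nonzero]) / sd[nonzero]
    for i in range(L):
        for j in range(i, L):
            if not nonzero[i, j]:
                degenerate.append((uniq[i], uniq[j]))

    def frame(m):
        return pd.DataFrame(m, index=uniq, columns=uniq)

    return NeighborhoodEnrichment(
        zscores=frame(z),
        observed=frame(observed),
        perm_mean=frame(mean),
        perm_sd=frame(sd),
        n_permutations=n_perm,
        seed=seed,
        degenerate_pairs=degenerate,
    )
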