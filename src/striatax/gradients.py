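"""Within-subclass expression gradients and functional gene subsets.

A single-latent-factor linear Gaussian model fitted to one subclass in
one region exposes coordinated continuous variation (an expression
gradient) that a discrete clustering cannot represent. Functional
profiling restricts the matrix to neurotransmitter-receptor genes
(selected by gene-symbol prefixes) or to an explicit id list such as
the genes annotated with ion-channel activity (GO:0005216).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import FactorAnalysis

from .taxonomy import NormalizedMatrix, gene_exclusion_mask, select_hvg

RECEPTOR_PREFIXES: dict[str, str] = {
    "DRD": "dopamine",
    "GABR": "GABA",
    "CHRN": "acetylcholine (nicotinic)",
    "CHRM": "acetylcholine (muscarinic)",
    "GRIA": "glutamate (AMPA)",
    "GRIN": "glutamate (NMDA)",
    "GRIK": "glutamate (kainate)",
    "GRM": "glutamate (metabotropic)",
    "GRID": "glutamate (delta)",
    "GRIP": "glutamate (receptor-interacting)",
}
# glutamate receptors whose symbols do not follow the prefix pattern
RECEPTOR_EXTRA_GENES = ["PEPL1", "POLR2M", "GCOM1"]


@dataclass
class FactorResult:
    """Fitted single-factor model for one subclass + region."""

    cell_ids: np.ndarray
    factor_values: np.ndarray
    genes: list[str]
    weights: np.ndarray
    noise_variance: np.ndarray
    subclass: str = ""
    region: str = ""

    def weight_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.genes, name="weight")


def factor_analysis_single(
    norm: NormalizedMatrix,
    n_hvg: int = 1200,
    subclass: str = "",
    region: str = "",
    seed: int = 0,
) -> FactorResult:
    """Fit a 1-latent-factor Gaussian model to one subclass's cells.

    The matrix is restricted to ``n_hvg`` highly variable genes
    (sex-linked, mitochondrial, riboprotein genes excluded), centered
    (not variance-scaled), and decomposed as x = w z + noise. The sign
    convention makes the largest-|weight| gene's weight positive.
    """
    if norm.n_cells < 50:
        raise ValueError("need at least 50 cells for factor analysis")
    n_eligible = int((~gene_exclusion_mask(norm.gene_names)).sum())
    genes = select_hvg(norm, min(n_hvg, n_eligible))
    X = norm.values[:, norm.gene_index(genes)].toarray()
    keep = X.std(axis=0) > 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} constant genes dropped before factor fit")
        genes = [g for g, k in zip(genes, keep) if k]
        X = X[:, keep]
    fa = FactorAnalysis(
        n_components=1, svd_method="lapack", max_iter=500, tol=1e-6,
        random_state=seed % (2**31),
    ).fit(X)
    weights = fa.components_[0].copy()
    scores = fa.transform(X)[:, 0]
    top = int(np.argmax(np.abs(weights)))
    if weights[top] < 0:
        weights = -weights
        scores = -scores
    return FactorResult(
        cell_ids=np.asarray(norm.cell_ids),
        factor_values=scores,
        genes=genes,
        weights=weights,
        noise_variance=fa.noise_variance_,
        subclass=subclass,
        region=region,
    )


def top_weight_genes(result: FactorResult, k: int) -> tuple[list[str], list[str]]:
    """Genes with the k most positive and k most negative factor weights."""
    if k > len(result.genes):
        raise ValueError("k exceeds the number of genes in the factor model")
    order = sorted(range(len(result.genes)),
                   key=lambda i: (-result.weights[i], result.genes[i]))
    top = [result.genes[i] for i in order[:k]]
    bottom = [result.genes[i] for i in order[::-1][:k]]
    return top, bottom


@dataclass
class GeneSubsetRule:
    """Prefix-anchored gene-symbol selection with optional explicit list."""

    prefixes: list[str] = field(default_factory=lambda: list(RECEPTOR_PREFIXES))
    extra_genes: list[str] = field(default_factory=lambda: list(RECEPTOR_EXTRA_GENES))
    id_list: list[str] | None = None

    def __post_init__(self):
        self.prefixes = [p.upper() for p in self.prefixes]


def select_gene_subset(
    gene_names, rule: GeneSubsetRule
) -> tuple[list[str], list[str]]:
    """Select the union of prefix matches, extra genes, and the id list.

    Matching is prefix-anchored on upper-cased symbols. Returns
    (selected genes in universe order, requested ids not found).
    """
    if not rule.prefixes and not rule.extra_genes and not rule.id_list:
        raise ValueError("empty gene subset rule")
    universe = list(gene_names)
    uset = set(universe)
    wanted = set()
    for g in universe:
        gu = g.upper()
        if any(gu.startswith(p) for p in rule.prefixes):
            wanted.add(g)
    missing = []
    for g in list(rule.extra_genes) + list(rule.id_list or []):
        if g in uset:
            wanted.add(g)
        else:
            missing.append(g)
    if missing:
        warnings.warn(f"{len(missing)} subset genes not found in universe")
    return [g for g in universe if g in wanted], missing
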