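"""Plain-text IO: Matrix Market count directories, GMT gene sets, Newick."""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix


def write_mtx_dir(path, counts: CountMatrix, truth: pd.DataFrame | None = None) -> None:
    """Write ``matrix.mtx`` (cells x genes) with TSV sidecars."""
    os.makedirs(path, exist_ok=True)
    scipy.io.mmwrite(os.path.join(path, "matrix.mtx"), counts.counts)
    cells = counts.cell_meta.copy()
    cells.insert(0, "cell_id", counts.cell_ids)
    cells.to_csv(os.path.join(path, "cells.tsv"), sep="\t", index=False)
    pd.DataFrame({"gene": counts.gene_names}).to_csv(
        os.path.join(path, "genes.tsv"), sep="\t", index=False
    )
    if truth is not None:
        truth.to_csv(os.path.join(path, "truth.tsv"), sep="\t", index=False)


def read_mtx_dir(path) -> tuple[CountMatrix, pd.DataFrame | None]:
    """Read a directory written by :func:`write_mtx_dir` (or 10x-style)."""
    mat = sp.csr_matrix(scipy.io.mmread(os.path.join(path, "matrix.mtx")))
    cells = pd.read_csv(os.path.join(path, "cells.tsv"), sep="\t")
    genes = pd.read_csv(os.path.join(path, "genes.tsv"), sep="\t")
    cell_ids = cells["cell_id"].to_numpy()
    meta = cells.drop(columns=["cell_id"])
    meta.index = cell_ids
    truth = None
    truth_path = os.path.join(path, "truth.tsv")
    if os.path.exists(truth_path):
        truth = pd.read_csv(truth_path, sep="\t")
    counts = CountMatrix(mat, cell_ids, genes["gene"].to_numpy(), meta)
    return counts, truth


def read_gmt(path) -> dict[str, tuple[str, set[str]]]:
    """GMT gene sets: term_id -> (description, gene set). Empty sets dropped."""
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if genes:
                out[term] = (desc, set(genes))
    return out


def read_gene_list(path) -> list[str]:
    """One gene name per line, blank lines and '#' comments ignored."""
    with open(path) as fh:
        return [
            ln.strip() for ln in fh if ln.strip() and not ln.lstrip().startswith("#")
        ]


def linkage_to_newick(linkage: np.ndarray, leaf_names: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    n = len(leaf_names)
    heights = {i: 0.0 for i in range(n)}

    def render(node: int) -> str:
        if node < n:
            return leaf_names[node].replace(" ", "_").replace(",", "_")
        row = linkage[node - n]
        left, right, h = int(row[0]), int(row[1]), float(row[2])
        heights[node] = h
        parts = []
        for child in (left, right):
            bl = h - heights.get(child, 0.0)
            parts.append(f"{render(child)}:{max(bl, 0.0):.6g}")
        return "(" + ",".join(parts) + ")"

    # post-order: ensure child heights known before parents
    for node in range(n, n + len(linkage)):
        heights[node] = float(linkage[node - n][2])
    return render(n + len(linkage) - 1) + ";"
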