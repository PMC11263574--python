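"""End-to-end orchestration of the taxonomy pipeline.

Stage order: simulate -> qc -> classify (detection + subclass
clustering + correlation merge) -> compose -> de -> gradient ->
spatial. Every stage is a thin wrapper over the library modules; a
machine-readable manifest records seeds, parameters and the per-stage
cell funnel.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import composition, de, gradients, io, qc, spatial, synthetic, taxonomy
from .config import PipelineConfig, QCThresholds, TaxonomyParams
from .containers import CountMatrix


def default_pipeline_config(seed: int = 0) -> PipelineConfig:
    """The bundled study conditions: default synthetic taxonomy dataset
    and QC thresholds, with the doublet scorer run 15 times per sample
    (the consensus voting rule is unchanged)."""
    return PipelineConfig(
        generator=synthetic.default_taxonomy_config(seed=seed),
        qc=QCThresholds(n_doublet_runs=15),
        taxonomy=TaxonomyParams(),
        seed=seed,
    )


@dataclass
class TaxonomyLabeling:
    """Per-cell subclass and merged class labels with marker table."""

    labels: pd.DataFrame  # columns: subclass, class; index: cell_id
    marker_table: pd.DataFrame
    correlation: pd.DataFrame
    linkage: np.ndarray
    newick: str
    funnel: dict = field(default_factory=dict)

    @property
    def n_subclasses(self) -> int:
        return self.labels["subclass"].nunique()

    @property
    def n_classes(self) -> int:
        return self.labels["class"].nunique()


def classify_cells(
    counts: CountMatrix,
    params: TaxonomyParams | None = None,
    thresholds: QCThresholds | None = None,
    seed: int = 0,
) -> TaxonomyLabeling:
    """Iterative marker-gated classification down to merged classes.

    Broad clustering labels glia vs neurons; neurons are depth
    re-filtered and re-clustered; inhibitory/cholinergic gating selects
    interneurons; interneurons are re-clustered into subclasses which
    are Wilcoxon-ranked for markers and merged at mean Pearson r > 0.49.
    """
    params = params or TaxonomyParams()
    thresholds = thresholds or QCThresholds()
    funnel = {"input_cells": counts.n_cells}

    norm = taxonomy.normalize_log(counts, params.target_sum)
    hvgs = taxonomy.select_hvg(norm, min(params.detect_n_hvg, len(norm.gene_names) - 1))
    broad = taxonomy.embed_cluster(
        norm, hvgs, params.detect_n_pcs, params.detect_resolution,
        seed=seed, knn=params.knn,
    )
    cluster_types = taxonomy.label_clusters_by_markers(
        norm, broad, qc.DEFAULT_MARKER_PANEL, margin=params.label_margin
    )
    neuron_clusters = {c for c, t in cluster_types.items() if t == "neurons"}
    neuron_ids = counts.cell_ids[np.isin(broad, list(neuron_clusters))]
    funnel["neuron_labeled"] = len(neuron_ids)

    neuron_ids = taxonomy.neuron_quality_refilter(counts, neuron_ids, thresholds)
    funnel["neurons_after_refilter"] = len(neuron_ids)
    if len(neuron_ids) < 100:
        raise ValueError("fewer than 100 neurons survive the quality re-filter")

    norm_neurons = norm.subset_cells(neuron_ids)
    hvgs_n = taxonomy.select_hvg(
        norm_neurons, min(params.detect_n_hvg, len(norm.gene_names) - 1)
    )
    neuron_clusters_lbl = taxonomy.embed_cluster(
        norm_neurons, hvgs_n, params.detect_n_pcs, params.detect_resolution,
        seed=seed + 1, knn=params.knn,
    )
    inter_ids = taxonomy.select_interneurons(
        norm_neurons, neuron_clusters_lbl,
        positive_threshold=params.positive_threshold,
        negative_threshold=params.negative_threshold,
    )
    funnel["interneurons"] = len(inter_ids)

    norm_inter = norm.subset_cells(inter_ids)
    sub_int = taxonomy.subclass_clustering(norm_inter, params, seed=seed + 2)
    funnel["interneurons_after_posthoc"] = len(sub_int)
    subclass = sub_int.map(lambda i: f"SC{i + 1:02d}")

    norm_final = norm.subset_cells(subclass.index)
    markers = taxonomy.rank_marker_genes(norm_final, subclass.to_numpy())
    class_labels, corr, Z, newick = taxonomy.merge_subclasses(
        norm_final, subclass, params.merge_r_threshold, params.merge_mode
    )
    labels = pd.DataFrame({"subclass": subclass, "class": class_labels})
    labels.index.name = "cell_id"
    return TaxonomyLabeling(labels, markers, corr, Z, newick, funnel)


def run_all(config: PipelineConfig, out_dir: str) -> dict:
    """Execute all enabled stages; returns the run manifest."""
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "parameters": {
        "qc": asdict(config.qc), "taxonomy": asdict(config.taxonomy),
    }}
    enabled = lambda s: config.stages.get(s, True)  # noqa: E731

    # simulate ---------------------------------------------------------
    gen = config.generator or synthetic.default_taxonomy_config(seed=config.seed)
    counts, truth = synthetic.generate_dataset(gen)
    if gen.doublet_rate > 0:
        counts, truth = synthetic.inject_doublets(
            counts, truth, gen.doublet_rate, gen.seed + 1
        )
    sim_dir = os.path.join(out_dir, "simulate")
    io.write_mtx_dir(sim_dir, counts, truth)
    manifest["stages"]["simulate"] = {
        "cells": counts.n_cells, "genes": counts.n_genes_total,
        "doublet_rate": gen.doublet_rate, "seed": gen.seed,
    }

    # qc ---------------------------------------------------------------
    if enabled("qc"):
        counts_qc, funnel, _types = qc.run_qc_cascade(
            counts, config.qc, seed=config.seed,
            expected_doublet_rate=max(gen.doublet_rate, 0.05),
        )
        qc_dir = os.path.join(out_dir, "qc")
        io.write_mtx_dir(qc_dir, counts_qc)
        funnel.to_csv(os.path.join(qc_dir, "funnel.tsv"), sep="\t", index=False)
        manifest["stages"]["qc"] = {
            "cells_in": int(funnel["cells_in"].iloc[0]),
            "cells_out": counts_qc.n_cells,
            "funnel": funnel.to_dict(orient="records"),
        }
    else:
        counts_qc = counts
        manifest["stages"]["qc"] = {"skipped": True}

    # classify ---------------------------------------------------------
    result = classify_cells(counts_qc, config.taxonomy, config.qc, seed=config.seed)
    cls_dir = os.path.join(out_dir, "classify")
    os.makedirs(cls_dir, exist_ok=True)
    result.labels.reset_index().to_csv(
        os.path.join(cls_dir, "labels.tsv"), sep="\t", index=False
    )
    result.marker_table.to_csv(
        os.path.join(cls_dir, "markers.tsv"), sep="\t", index=False
    )
    with open(os.path.join(cls_dir, "dendrogram.nwk"), "w") as fh:
        fh.write(result.newick + "\n")
    manifest["stages"]["classify"] = {
        "n_subclasses": result.n_subclasses,
        "n_classes": result.n_classes,
        "funnel": result.funnel,
    }

    # compose ----------------------------------------------------------
    if enabled("compose"):
        table = composition.class_fractions(
            result.labels["class"], counts_qc.cell_meta
        )
        table = composition.compute_clr(table, config.pseudocount)
        comp_dir = os.path.join(out_dir, "compose")
        os.makedirs(comp_dir, exist_ok=True)
        table.to_csv(os.path.join(comp_dir, "composition.tsv"), sep="\t", index=False)
        try:
            tests = composition.region_composition_test(table)
            tests.to_csv(
                os.path.join(comp_dir, "composition_test.tsv"), sep="\t", index=False
            )
            manifest["stages"]["compose"] = {
                "classes": int(table["class"].nunique()),
                "min_p": float(tests["pval"].min()),
            }
        except ValueError as err:
            manifest["stages"]["compose"] = {"test_skipped": str(err)}

    # de ---------------------------------------------------------------
    if enabled("de"):
        pb = de.aggregate_pseudobulk(
            counts_qc, result.labels["class"], config.de_min_cells
        )
        de_dir = os.path.join(out_dir, "de")
        os.makedirs(de_dir, exist_ok=True)
        de_summary = {}
        for cls in result.labels["class"].unique():
            sub = pb.matrix.xs(cls, level="class", drop_level=False)
            regions = sub.index.get_level_values("region")
            if min((regions == "CN").sum(), (regions == "Pu").sum()) < 2:
                continue
            res = de.nb_glm_lrt(pb, cls)
            safe = cls.replace("/", "_")
            res.to_csv(os.path.join(de_dir, f"de_{safe}.tsv"), sep="\t", index=False)
            up, down = de.select_degs(res)
            de_summary[cls] = {"n_up_CN": len(up), "n_up_Pu": len(down)}
        manifest["stages"]["de"] = de_summary

    # gradient ---------------------------------------------------------
    if enabled("gradient"):
        grad_dir = os.path.join(out_dir, "gradient")
        os.makedirs(grad_dir, exist_ok=True)
        norm = taxonomy.normalize_log(counts_qc, config.taxonomy.target_sum)
        largest = result.labels["subclass"].value_counts().index[0]
        grad_summary = {}
        for region in ("CN", "Pu"):
            in_sub = result.labels.index[
                (result.labels["subclass"] == largest)
                & (counts_qc.cell_meta.loc[result.labels.index, "region"] == region)
            ]
            if len(in_sub) < 50:
                continue
            fr = gradients.factor_analysis_single(
                norm.subset_cells(in_sub), subclass=largest, region=region,
                seed=config.seed,
            )
            tag = f"{largest}_{region}"
            pd.DataFrame(
                {"cell_id": fr.cell_ids, "factor": fr.factor_values}
            ).to_csv(os.path.join(grad_dir, f"factor_{tag}.tsv"), sep="\t", index=False)
            fr.weight_series().rename_axis("gene").reset_index().to_csv(
                os.path.join(grad_dir, f"weights_{tag}.tsv"), sep="\t", index=False
            )
            top, bottom = gradients.top_weight_genes(fr, 3)
            grad_summary[tag] = {"top": top, "bottom": bottom}
        manifest["stages"]["gradient"] = grad_summary

    # spatial ----------------------------------------------------------
    if enabled("spatial"):
        sp_dir = os.path.join(out_dir, "spatial")
        os.makedirs(sp_dir, exist_ok=True)
        labels_arr = result.labels["subclass"].to_numpy()
        pairs = []
        uniq = pd.unique(labels_arr)
        if len(uniq) >= 2:
            pairs = [(uniq[0], uniq[1], 5.0)]
        ds = synthetic.generate_spatial(
            labels_arr, pairs, field_size=1000.0, seed=config.seed
        )
        graph = spatial.build_neighbor_graph(ds.coords, method="delaunay")
        enr = spatial.neighborhood_enrichment(
            graph, ds.labels, n_perm=500, seed=config.seed
        )
        enr.zscores.to_csv(os.path.join(sp_dir, "enrichment_z.tsv"), sep="\t")
        manifest["stages"]["spatial"] = {
            "n_cells": len(ds.labels),
            "planted_pairs": [[a, b, s] for a, b, s in pairs],
            "max_offdiag_z": float(
                (enr.zscores.to_numpy() - np.diag(np.diag(enr.zscores.to_numpy()))).max()
            ),
        }

    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
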