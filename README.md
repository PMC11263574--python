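# striatax

Transcriptomic taxonomy of human striatal interneurons from single-nucleus
RNA-seq, with compositional, differential-expression, gradient, and spatial
analyses — plus a fully specified synthetic data generator so the entire
pipeline is testable end to end without restricted human data.

## Scientific problem

The dorsal striatum (caudate nucleus, CN; putamen, Pu) is dominated by medium
spiny projection neurons; its interneurons are rare (a few percent of
neurons), diverse, and disproportionately important for striatal computation
and disease. Classifying them from snRNA-seq requires:

1. **Quality control** that removes doublets and damaged nuclei without
   discarding rare types;
2. **Iterative, marker-gated clustering** that isolates interneurons from the
   overwhelming MSN/glia background, splits them into fine *subclasses*, and
   merges transcriptomically similar subclasses into main *classes*;
3. **Compositional comparison** of class abundance between CN and Pu, which
   must respect the unit-sum constraint of cell-type fractions;
4. **Pseudobulk differential expression** between regions within a class;
5. **Latent gradient analysis** of within-class continuous variation;
6. **Spatial neighborhood enrichment** of class co-localization on
   targeted in situ panels.

`striatax` implements each step as a small, independently tested library
module, orchestrated by a CLI. A negative-binomial count simulator with
planted populations, correlation blocks, doublets, expression gradients, and
regional fold changes provides ground truth for every claim the pipeline
makes.

## Worked example

The bundled default dataset plants 14 interneuron populations (organized in
8 correlation blocks) plus MSNs and glia across 3 CN + 3 Pu samples, with 5%
injected doublets — 5,040 nuclei in total:

```python
from striatax import qc, synthetic
from striatax.pipeline import classify_cells, default_pipeline_config

counts, truth = synthetic.simulate_default(seed=0)
cfg = default_pipeline_config(seed=0)

filtered, funnel, types = qc.run_qc_cascade(counts, cfg.qc, seed=0)
print(funnel.to_string(index=False))
labeling = classify_cells(filtered, cfg.taxonomy, cfg.qc, seed=0)
print(labeling.n_subclasses, "subclasses,", labeling.n_classes, "classes")
```

Output (seed 0):

```
             stage  cells_in  cells_removed
consensus_doublets      5040            282
     count_filters      4758              0
     poly_outliers      4758              0
    multi_identity      4758             37
  regional_markers      4721              0
14 subclasses, 8 classes
```

Against the generator's truth table, this run removes 75% of the injected
doublets while discarding only 2.9% of true singlets, recovers exactly the
14 planted subclasses (adjusted Rand index 1.0 on interneuron nuclei), and
merges them into exactly the 8 planted correlation blocks.

The same run from the command line:

```bash
striatax run-all --out runs/demo        # bundled default config, seed 0
cat runs/demo/manifest.json
```

Individual stages (`simulate`, `qc`, `classify`, `compose`, `de`,
`gradient`, `spatial`) are also exposed; see `striatax --help`. All
configuration is TOML (`src/striatax/data/default.toml` is the bundled
default; `striatax run-all --config my.toml` overrides it).

## Package layout

- `striatax.synthetic` — NB count generator with planted ground truth
- `striatax.qc` — doublet consensus, count/outlier filters, identity gating
- `striatax.taxonomy` — HVG selection, Louvain clustering, marker gating,
  subclass merging into classes (Newick dendrogram)
- `striatax.composition` — CLR transform + rank-sum regional tests
- `striatax.de` — pseudobulk NB GLM likelihood-ratio tests, DEG selection,
  over-representation analysis
- `striatax.gradients` — single-latent-factor models of within-class variation
- `striatax.spatial` — count-based gating, neighbor graphs, permutation
  enrichment z-scores
- `striatax.pipeline` / `striatax.cli` — orchestration, manifests, CLI

Methodological details, parameter defaults and their rationale are in
[`docs/methods.md`](docs/methods.md).
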