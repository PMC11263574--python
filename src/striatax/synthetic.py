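"""Synthetic snRNA-seq and spatial data with known ground truth.

The generator emulates the statistical structure the downstream
pipeline assumes: multi-sample two-region (caudate nucleus CN, putamen
Pu) negative-binomial counts with gamma-distributed library sizes,
mitochondrial content, class-structured marker blocks, correlated
baseline profiles within taxonomy blocks, planted region-specific
proportion shifts and differential expression, a planted
within-population latent gradient, injected doublets, and spatial
coordinates with planted co-localization.

Model
-----
Every gene has an unnormalized rate per population. Filler genes draw a
global log-normal baseline ``exp(N(0, gene_logmean_sigma^2))``
modulated by a population-structure term
``exp(heterogeneity_sigma * (sqrt(s) * B_block + sqrt(1-s) * E_pop))``
with block share ``s``; populations in the same ``correlation_block``
therefore have highly correlated mean profiles while populations in
different blocks do not — the knob that controls the behaviour of the
correlation-threshold class merging. Named marker genes are expressed
only in the populations that own them, at ``marker_baseline_rate *
exp(marker_log_fold)`` of each cell's transcriptome; every other named
gene is silent (the counts emulate ambient-corrected input, so no soup
leakage is modeled). Rates are normalized per cell and scaled by
a Gamma library size; counts are Gamma-Poisson (negative binomial with
global dispersion ``nb_dispersion``).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import GeneratorConfig, PopulationSpec
from .containers import CountMatrix, MITO_PREFIX

# genes the pipeline gates on; always present in the synthetic universe
KNOWN_GENES = [
    # inhibitory / cholinergic positive gates
    "GAD1", "GAD2", "CHAT",
    # MSN and excitatory negative gates
    "PPP1R1B", "DRD1", "DRD2", "MEIS2", "RORB",
    # pan-neuronal
    "MEG3",
    # regional contamination markers (Allen atlas)
    "NEUROD2", "TMEM155", "CARTPT", "SLC17A7",
    # glial / vascular panels
    "AQP4", "ADGRV1", "CSF1R", "FYB1", "MBP", "MOG", "MAG",
    "PTPRZ1", "PDGFRA", "VCAN", "EBF1", "ABCB1", "ABCA9",
    # spatial gating
    "OLIG1", "MOBP", "LHX6", "SST",
]

TRUTH_COLUMNS = [
    "cell_id", "population", "parent_populations",
    "sample_id", "region", "latent_factor_value",
]


def build_gene_universe(config: GeneratorConfig) -> tuple[np.ndarray, dict]:
    """Gene name vector: MT- genes, named (special) genes, then fillers."""
    n_mito = math.ceil(0.01 * config.n_genes)
    special = set(KNOWN_GENES)
    for pop in config.populations:
        special.update(pop.marker_genes)
        for gene, _, _ in pop.planted_de:
            if not gene.startswith("GENE"):
                special.add(gene)
    special = sorted(special)
    n_named = n_mito + len(special)
    if n_named >= config.n_genes:
        raise ValueError(
            f"n_genes={config.n_genes} too small for {n_named} named genes"
        )
    mito = [f"{MITO_PREFIX}{i + 1}" for i in range(n_mito)]
    special_set = set(special)
    fillers = []
    i = 0
    while len(fillers) < config.n_genes - n_named:
        i += 1
        name = f"GENE{i:05d}"
        if name not in special_set:  # marker names may be GENE-style
            fillers.append(name)
    names = np.array(mito + special + fillers, dtype=object)
    layout = {
        "mito": np.arange(n_mito),
        "special": np.arange(n_mito, n_mito + len(special)),
        "filler": np.arange(n_mito + len(special), config.n_genes),
        "special_names": special,
    }
    return names, layout


def _population_rates(config: GeneratorConfig, names, layout, rng) -> dict[str, np.ndarray]:
    """Unnormalized per-gene rate vector for each population."""
    n_genes = config.n_genes
    fil = layout["filler"]
    mito = layout["mito"]
    name_pos = {g: i for i, g in enumerate(names)}

    base_log = rng.normal(0.0, config.gene_logmean_sigma, size=len(fil))
    blocks = sorted({p.correlation_block for p in config.populations})
    block_eff = {
        b: rng.normal(0.0, 1.0, size=len(fil)) for b in blocks
    }
    s = config.block_share
    het = config.heterogeneity_sigma

    # mitochondrial rates: fixed lognormal profile shared by all populations
    mito_shape = np.exp(rng.normal(0.0, 1.0, size=len(mito)))

    rates = {}
    for pop in config.populations:
        pop_eff = rng.normal(0.0, 1.0, size=len(fil))
        log_rate = base_log + het * (
            math.sqrt(s) * block_eff[pop.correlation_block]
            + math.sqrt(1.0 - s) * pop_eff
        )
        r = np.zeros(n_genes)
        r[fil] = np.exp(log_rate)
        filler_total = r[fil].sum()

        # named genes: markers are expressed only in their owning
        # populations, at exp(marker_log_fold) times the reference unit
        # rate; all other named genes (other populations' markers,
        # regional contamination markers) are silent — the counts
        # emulate ambient-corrected input, so no soup leakage is modeled
        base = config.marker_baseline_rate * filler_total
        for i in layout["special"]:
            r[i] = 0.0
        for g in pop.marker_genes:
            r[name_pos[g]] = base * math.exp(pop.marker_log_fold)

        # mitochondrial share of the transcriptome
        if config.mito_fraction_mean > 0:
            target = config.mito_fraction_mean / (1 - config.mito_fraction_mean)
            r[mito] = mito_shape / mito_shape.sum() * target * (r.sum() - 0.0)
        rates[pop.name] = r
    return rates


def generate_dataset(config: GeneratorConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a synthetic dataset; deterministic given ``config.seed``.

    Returns the count matrix and a truth table with one row per cell
    (population, sample, region, planted latent factor value).
    """
    rng = np.random.default_rng(config.seed)
    names, layout = build_gene_universe(config)
    rates = _population_rates(config, names, layout, rng)
    name_pos = {g: i for i, g in enumerate(names)}
    pops = {p.name: p for p in config.populations}
    pop_names = [p.name for p in config.populations]

    lib_cv = config.library_size_dispersion
    shape = 1.0 / (lib_cv * lib_cv)
    alpha = config.nb_dispersion

    blocks_counts = []
    blocks_meta = []
    truth_rows = []
    for sample_id, region in config.samples:
        probs = np.array(
            [pops[n].proportion_by_region.get(region, 0.0) for n in pop_names]
        )
        n_per_pop = rng.multinomial(config.cells_per_sample, probs)
        cell_counter = 0
        for pop_name, n_cells in zip(pop_names, n_per_pop):
            if n_cells == 0:
                continue
            pop = pops[pop_name]
            r = rates[pop_name].copy()
            for gene, de_region, lf in pop.planted_de:
                if de_region == region:
                    r[name_pos[gene]] *= math.exp(lf)
            r = r / r.sum()

            lib = rng.gamma(shape, config.mean_library_size / shape, size=n_cells)
            if pop.gradient_genes is not None:
                z = rng.uniform(-1.0, 1.0, size=n_cells)
                R = np.tile(r, (n_cells, 1))
                gidx = np.array([name_pos[g] for g in pop.gradient_genes])
                w = np.asarray(pop.gradient_weights)
                R[:, gidx] *= np.exp(pop.gradient_strength * np.outer(z, w))
                R /= R.sum(axis=1, keepdims=True)
                mu = lib[:, None] * R
            else:
                z = np.full(n_cells, np.nan)
                mu = np.outer(lib, r)

            lam = rng.gamma(1.0 / alpha, alpha * mu)
            counts = rng.poisson(lam).astype(np.int32)
            blocks_counts.append(sp.csr_matrix(counts))
            ids = [
                f"{sample_id}_{pop_name}_{cell_counter + i:04d}"
                for i in range(n_cells)
            ]
            cell_counter += n_cells
            blocks_meta.append(
                pd.DataFrame({"sample_id": sample_id, "region": region}, index=ids)
            )
            for cid, zi in zip(ids, z):
                truth_rows.append((cid, pop_name, "", sample_id, region, zi))

    counts = sp.vstack(blocks_counts, format="csr")
    meta = pd.concat(blocks_meta)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    cm = CountMatrix(counts, np.asarray(meta.index), names, meta)
    return cm, truth


def inject_doublets(
    counts: CountMatrix, truth: pd.DataFrame, rate: float, seed: int
) -> tuple[CountMatrix, pd.DataFrame]:
    """Append ``floor(rate * n_cells)`` doublets summing same-sample parents."""
    if not (0 <= rate < 0.5):
        raise ValueError("doublet rate must be in [0, 0.5)")
    n_doub = int(rate * counts.n_cells)
    if n_doub == 0:
        return counts, truth
    rng = np.random.default_rng(seed)
    samples = counts.cell_meta["sample_id"].to_numpy()
    sample_ids, sample_sizes = np.unique(samples, return_counts=True)
    eligible = sample_ids[sample_sizes >= 2]
    skipped = set(sample_ids) - set(eligible)
    if skipped:
        warnings.warn(f"samples with <2 cells skipped for doublets: {sorted(skipped)}")
    weights = sample_sizes[sample_sizes >= 2].astype(float)
    weights /= weights.sum()
    truth_pop = truth.set_index("cell_id")["population"]

    rows, metas, new_truth = [], [], []
    for i in range(n_doub):
        smp = rng.choice(eligible, p=weights)
        members = np.flatnonzero(samples == smp)
        a, b = rng.choice(members, size=2, replace=False)
        rows.append(counts.counts[a] + counts.counts[b])
        cid = f"DBL-{i + 1:05d}"
        region = counts.cell_meta["region"].iloc[a]
        metas.append((cid, smp, region))
        parents = "|".join(
            sorted([truth_pop[counts.cell_ids[a]], truth_pop[counts.cell_ids[b]]])
        )
        new_truth.append((cid, "doublet", parents, smp, region, np.nan))

    stacked = sp.vstack([counts.counts] + rows, format="csr")
    ids = np.concatenate([counts.cell_ids, [m[0] for m in metas]])
    meta = pd.concat(
        [
            counts.cell_meta,
            pd.DataFrame(
                {"sample_id": [m[1] for m in metas], "region": [m[2] for m in metas]},
                index=[m[0] for m in metas],
            ),
        ]
    )
    truth_out = pd.concat(
        [truth, pd.DataFrame(new_truth, columns=TRUTH_COLUMNS)], ignore_index=True
    )
    return CountMatrix(stacked, ids, counts.gene_names, meta), truth_out


def generate_spatial(labels, colocal_pairs, field_size: float, seed: int):
    """Place labeled cells in a square field with planted co-localization.

    Cells of classes not named as the second member of a
    ``(classA, classB, strength)`` pair are placed uniformly; classB
    cells are attracted to classA positions with probability
    ``strength / (1 + strength)`` (Gaussian offset, sd = 2% of the
    field side).
    """
    from .spatial import SpatialDataset

    labels = np.asarray(labels, dtype=object)
    classes = set(labels)
    for a, b, strength in colocal_pairs:
        if a not in classes or b not in classes:
            raise ValueError(f"unknown class in colocal_pairs: ({a}, {b})")
        if strength < 0:
            raise ValueError("colocalization strength must be >= 0")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, field_size, size=(len(labels), 2))
    sd = 0.02 * field_size
    for a, b, strength in colocal_pairs:
        anchors = coords[labels == a]
        idx_b = np.flatnonzero(labels == b)
        attract = rng.random(len(idx_b)) < strength / (1.0 + strength)
        n_att = int(attract.sum())
        if n_att and len(anchors):
            centers = anchors[rng.integers(0, len(anchors), size=n_att)]
            pts = centers + rng.normal(0.0, sd, size=(n_att, 2))
            coords[idx_b[attract]] = np.clip(pts, 0.0, field_size)
    return SpatialDataset(coords=coords, labels=labels)


# ---------------------------------------------------------------------------
# Default study conditions: one population per interneuron subclass of the
# taxonomy (8 correlation blocks), plus glial populations and MSNs so the
# detection gates have something to remove.
# ---------------------------------------------------------------------------

INTERNEURON_SUBCLASSES: dict[str, dict] = {
    # name -> (markers, block, proportions CN/Pu)
    "CCK/VIP":          dict(markers=["ADARB2", "CCK", "VIP"], block=0, cn=0.055, pu=0.055),
    "CCK/VIP/CXCL14":   dict(markers=["ADARB2", "CCK", "VIP", "CXCL14"], block=0, cn=0.050, pu=0.050),
    "CCK":              dict(markers=["ADARB2", "CCK"], block=1, cn=0.040, pu=0.090),
    "CCK/CHST9":        dict(markers=["ADARB2", "CCK", "CHST9"], block=1, cn=0.050, pu=0.050),
    "PVALB":            dict(markers=["PVALB"], block=2, cn=0.055, pu=0.055),
    "PVALB/GRIK3":      dict(markers=["PVALB", "GRIK3"], block=2, cn=0.055, pu=0.055),
    "SST/GRIK3":        dict(markers=["SST", "GRIK3", "LHX6"], block=3, cn=0.050, pu=0.050),
    "SST/NPY":          dict(markers=["SST", "NPY", "LHX6"], block=4, cn=0.055, pu=0.055),
    "SST/NPY/DACH1":    dict(markers=["SST", "NPY", "DACH1", "LHX6"], block=4, cn=0.055, pu=0.055),
    "PTHLH":            dict(markers=["PTHLH", "OPN3", "LHX6"], block=5, cn=0.105, pu=0.055),
    "PTHLH/MOXD1":      dict(markers=["PTHLH", "OPN3", "MOXD1", "LHX6"], block=5, cn=0.050, pu=0.050),
    "CHAT":             dict(markers=["CHAT", "SLC5A7"], block=6, cn=0.050, pu=0.050),
    "TAC3":             dict(markers=["TAC3", "PTPRK", "TMEM163", "GFRA2"], block=7, cn=0.060, pu=0.060),
    "TAC3/SEMA3A":      dict(markers=["TAC3", "PTPRK", "SEMA3A"], block=7, cn=0.050, pu=0.050),
}

NON_INTERNEURON: dict[str, dict] = {
    "astrocytes":       dict(markers=["AQP4", "ADGRV1"], block=8, frac=0.05),
    "microglia":        dict(markers=["CSF1R", "FYB1"], block=9, frac=0.03),
    "oligodendrocytes": dict(markers=["MBP", "MOG", "MAG", "MOBP", "OLIG1"], block=10, frac=0.05),
    "OPC":              dict(markers=["PTPRZ1", "PDGFRA", "VCAN", "OLIG1"], block=11, frac=0.02),
    "vascular":         dict(markers=["EBF1", "ABCB1", "ABCA9"], block=12, frac=0.02),
    "MSN":              dict(markers=["MEG3", "PPP1R1B", "DRD1", "DRD2", "MEIS2"], block=13, frac=0.05),
}

N_SUBCLASSES = len(INTERNEURON_SUBCLASSES)
N_CLASSES = len({v["block"] for v in INTERNEURON_SUBCLASSES.values()})


def default_taxonomy_config(seed: int = 0, doublet_rate: float = 0.05) -> GeneratorConfig:
    """The bundled default dataset: 14 interneuron subclasses in 8
    correlation blocks, glia, and MSNs, across 3 CN + 3 Pu samples."""
    populations = []
    grad_pool = iter(f"GENE{i:05d}" for i in range(101, 301))
    de_pool = iter(f"GENE{i:05d}" for i in range(301, 401))
    for name, info in INTERNEURON_SUBCLASSES.items():
        markers = list(info["markers"]) + ["MEG3"]
        if name != "CHAT":
            markers += ["GAD1", "GAD2"]
        grad = None
        planted = []
        if name in ("PTHLH", "TAC3"):
            grad = [next(grad_pool) for _ in range(40)]
        if name == "PTHLH":
            planted = [(next(de_pool), "CN", 1.04) for _ in range(12)]
            planted += [(next(de_pool), "Pu", 1.04) for _ in range(12)]
        populations.append(
            PopulationSpec(
                name=name,
                marker_genes=markers,
                marker_log_fold=6.0,
                proportion_by_region={"CN": info["cn"], "Pu": info["pu"]},
                correlation_block=info["block"],
                gradient_genes=grad,
                gradient_strength=1.5,
                planted_de=planted,
            )
        )
    for name, info in NON_INTERNEURON.items():
        populations.append(
            PopulationSpec(
                name=name,
                marker_genes=list(info["markers"]),
                marker_log_fold=6.0,
                proportion_by_region={"CN": info["frac"], "Pu": info["frac"]},
                correlation_block=info["block"],
            )
        )
    samples = [("CN1", "CN"), ("CN2", "CN"), ("CN3", "CN"),
               ("Pu1", "Pu"), ("Pu2", "Pu"), ("Pu3", "Pu")]
    return GeneratorConfig(
        n_genes=6000,
        populations=populations,
        samples=samples,
        cells_per_sample=800,
        doublet_rate=doublet_rate,
        seed=seed,
    )


def simulate_default(seed: int = 0) -> tuple[CountMatrix, pd.DataFrame]:
    """Default dataset with doublets injected (the bundled study conditions)."""
    cfg = default_taxonomy_config(seed=seed)
    counts, truth = generate_dataset(cfg)
    if cfg.doublet_rate > 0:
        counts, truth = inject_doublets(counts, truth, cfg.doublet_rate, seed + 1)
    return counts, truth
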