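"""Configuration objects for the generator, QC cascade and pipeline.

All configuration is expressible as plain TOML; :func:`load_config`
reads a file into a :class:`PipelineConfig`. Defaults follow the
published analysis thresholds where those exist and are otherwise the
package's own documented choices.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, asdict
from typing import Optional

REGIONS = ("CN", "Pu")


@dataclass
class PopulationSpec:
    """One planted cell population (a future cluster) in the generator.

    ``marker_genes`` are elevated by ``marker_log_fold`` (natural log)
    over the low baseline shared by all named marker-type genes.
    Populations sharing a ``correlation_block`` receive a common
    component in their baseline expression profile, so their mean
    profiles correlate strongly — this is what the correlation-merge
    step of the taxonomy recovers. ``gradient_genes`` optionally plant
    a one-dimensional latent factor: each cell of the population draws
    a value z ~ U(-1, 1) which shifts those genes' log-means by
    ``gradient_strength * z * weight``.
    """

    name: str
    marker_genes: list[str] = field(default_factory=list)
    marker_log_fold: float = 6.0
    proportion_by_region: dict[str, float] = field(default_factory=dict)
    correlation_block: int = 0
    gradient_genes: Optional[list[str]] = None
    gradient_weights: Optional[list[float]] = None
    gradient_strength: float = 1.5
    planted_de: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self):
        if self.marker_log_fold < 0:
            raise ValueError(f"marker_log_fold must be >= 0 for population {self.name}")
        if self.gradient_genes is not None:
            if self.gradient_weights is None:
                w = [1.0] * len(self.gradient_genes)
            else:
                w = list(self.gradient_weights)
            if len(w) != len(self.gradient_genes):
                raise ValueError(
                    f"gradient_weights length mismatch for population {self.name}"
                )
            norm = math.sqrt(sum(x * x for x in w))
            if norm == 0:
                raise ValueError(f"gradient weight vector is zero for {self.name}")
            # skip rescaling when already unit-norm so that construction
            # is idempotent at the last-bit level (TOML round-trips
            # rebuild the population from its own normalized weights)
            if abs(norm - 1.0) > 1e-12:
                self.gradient_weights = [x / norm for x in w]
            else:
                self.gradient_weights = w
        self.planted_de = [tuple(t) for t in self.planted_de]


@dataclass
class GeneratorConfig:
    """Full specification of a synthetic multi-sample two-region dataset."""

    n_genes: int
    populations: list[PopulationSpec]
    samples: list[tuple[str, str]]
    cells_per_sample: int = 800
    mean_library_size: float = 35000.0
    library_size_dispersion: float = 0.25  # CV of the per-cell gamma
    nb_dispersion: float = 0.25  # global NB overdispersion alpha
    doublet_rate: float = 0.0
    mito_fraction_mean: float = 0.03
    # gene-level structure of baseline profiles (natural-log scale)
    gene_logmean_sigma: float = 1.0
    heterogeneity_sigma: float = 1.2
    block_share: float = 0.6
    marker_baseline_rate: float = 2e-5  # unit rate; owner expression = rate * exp(marker_log_fold)
    seed: int = 0

    def __post_init__(self):
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not self.populations:
            raise ValueError("populations must be a non-empty list")
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("population names must be unique")
        if not (0 <= self.doublet_rate < 0.5):
            raise ValueError("doublet_rate must be in [0, 0.5)")
        if not (0 <= self.mito_fraction_mean < 1):
            raise ValueError("mito_fraction_mean must be in [0, 1)")
        if self.mean_library_size <= 0:
            raise ValueError("mean_library_size must be positive")
        self.samples = [tuple(s) for s in self.samples]
        for sid, region in self.samples:
            if region not in REGIONS:
                raise ValueError(f"region of sample {sid} must be one of {REGIONS}")
        for region in {r for _, r in self.samples}:
            tot = sum(p.proportion_by_region.get(region, 0.0) for p in self.populations)
            if abs(tot - 1.0) > 1e-8:
                raise ValueError(
                    f"proportion_by_region for region {region} sums to {tot:.6f}, "
                    "expected 1"
                )


@dataclass
class QCThresholds:
    """Cutoffs of the QC cascade (strict-exceedance boundary semantics)."""

    min_umis: int = 500
    min_genes: int = 1200
    max_umis: int = 250_000
    max_genes: int = 15_000
    max_mito: float = 0.10
    neuron_min_umis: int = 5000
    neuron_min_genes: int = 3000
    neuron_max_genes: int = 12_000
    doublet_vote_fraction: float = 0.10
    n_doublet_runs: int = 100
    poly_degree: int = 2
    poly_outlier_delta: float = 2000.0
    poly_outlier_log_scale: bool = False  # literal log-unit reading, off by default
    regional_min_expr: float = 0.0

    def __post_init__(self):
        for lo, hi in [
            (self.min_umis, self.max_umis),
            (self.min_genes, self.max_genes),
        ]:
            if not lo < hi:
                raise ValueError("each min threshold must be below its max")
        for frac in (self.max_mito, self.doublet_vote_fraction):
            if not 0 < frac < 1:
                raise ValueError("fraction thresholds must lie in (0, 1)")


@dataclass
class TaxonomyParams:
    """Clustering/labeling parameters for detection and classification."""

    target_sum: float = 10_000.0
    detect_n_hvg: int = 1500
    detect_n_pcs: int = 30
    detect_resolution: float = 0.2
    subclass_n_hvg: int = 1500
    subclass_n_pcs: int = 20
    subclass_resolution: float = 1.0
    knn: int = 15
    positive_threshold: float = 0.25
    negative_threshold: float = 0.10
    label_margin: float = 0.05
    merge_r_threshold: float = 0.49
    merge_mode: str = "components"  # or "clique"


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = None
    qc: QCThresholds = field(default_factory=QCThresholds)
    taxonomy: TaxonomyParams = field(default_factory=TaxonomyParams)
    pseudocount: float = 0.5
    de_min_cells: int = 10
    seed: int = 0
    stages: dict[str, bool] = field(default_factory=dict)


def _pop_from_dict(d: dict) -> PopulationSpec:
    return PopulationSpec(**d)


def generator_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    d["populations"] = [_pop_from_dict(p) for p in d.get("populations", [])]
    d["samples"] = [tuple(s) for s in d.get("samples", [])]
    return GeneratorConfig(**d)


def load_config(path) -> PipelineConfig:
    """Read a pipeline configuration from a TOML file."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cfg = PipelineConfig()
    if "generator" in raw:
        cfg.generator = generator_from_dict(raw["generator"])
    if "qc" in raw:
        cfg.qc = QCThresholds(**raw["qc"])
    if "taxonomy" in raw:
        cfg.taxonomy = TaxonomyParams(**raw["taxonomy"])
    cfg.pseudocount = raw.get("pseudocount", cfg.pseudocount)
    cfg.de_min_cells = raw.get("de_min_cells", cfg.de_min_cells)
    cfg.seed = raw.get("seed", cfg.seed)
    cfg.stages = raw.get("stages", {})
    return cfg


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def config_to_toml(cfg: PipelineConfig) -> str:
    """Serialize a PipelineConfig to TOML text (round-trips load_config)."""
    lines: list[str] = []

    def emit_table(name: str, d: dict):
        lines.append(f"[{name}]")
        for k, v in d.items():
            if v is None:
                continue
            if isinstance(v, dict):
                lines.append(
                    f"{k} = {{"
                    + ", ".join(f"{kk} = {_toml_value(vv)}" for kk, vv in v.items())
                    + "}"
                )
            else:
                lines.append(f"{k} = {_toml_value(v)}")
        lines.append("")

    lines.append(f"seed = {cfg.seed}")
    lines.append(f"pseudocount = {cfg.pseudocount}")
    lines.append(f"de_min_cells = {cfg.de_min_cells}")
    lines.append("")
    if cfg.generator is not None:
        gd = asdict(cfg.generator)
        pops = gd.pop("populations")
        gd["samples"] = [list(s) for s in gd["samples"]]
        emit_table("generator", gd)
        for p in pops:
            p = {k: v for k, v in p.items() if v is not None and v != []}
            p["planted_de"] = [list(t) for t in p.get("planted_de", [])]
            if not p["planted_de"]:
                del p["planted_de"]
            emit_table("[generator.populations]", p)
    emit_table("qc", asdict(cfg.qc))
    emit_table("taxonomy", asdict(cfg.taxonomy))
    return "\n".join(lines)
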