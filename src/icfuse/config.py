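"""Parameter blocks for every pipeline stage, with JSON (de)serialization.

Defaults reproduce the published analysis settings of the dual-omics infant
ALL subtyping study design this pipeline implements: SNF with alpha = 0.5,
K = 10, t = 20; consensus clustering with 1000 resamples at 80% item
subsampling using spectral clustering; the KNN hyper-parameter grids; GSVA
defaults; the |log2FC| >= 2 / |delta-beta| >= 0.2 marker thresholds; and the
WES / targeted deep sequencing somatic-filter thresholds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path


class ConfigError(ValueError):
    pass


@dataclass
class SNFParams:
    alpha: float = 0.5          # kernel-width factor
    K: int = 10                 # neighborhood size
    t: int = 20                 # cross-diffusion iterations

    def validate(self, n_samples: int | None = None) -> None:
        if self.alpha <= 0:
            raise ConfigError("snf.alpha must be > 0")
        if self.K < 1:
            raise ConfigError("snf.K must be >= 1")
        if n_samples is not None and self.K >= n_samples:
            raise ConfigError("snf.K must be < number of samples")
        if self.t < 1:
            raise ConfigError("snf.t must be >= 1")


@dataclass
class ConsensusParams:
    k_min: int = 2
    k_max: int = 8
    reps: int = 1000
    p_item: float = 0.8
    pac_lower: float = 0.1
    pac_upper: float = 0.9
    final_linkage: str = "average"
    row_distance: str = "pearson"   # one-minus-Pearson between consensus rows
    seed: int = 0

    @property
    def k_range(self) -> range:
        return range(self.k_min, self.k_max + 1)

    def validate(self) -> None:
        if not (0 < self.p_item <= 1):
            raise ConfigError("consensus.p_item must be in (0, 1]")
        if self.pac_lower >= self.pac_upper:
            raise ConfigError("consensus PAC bounds must satisfy u1 < u2")
        if self.reps < 1:
            raise ConfigError("consensus.reps must be >= 1")
        if self.k_min < 2 or self.k_max < self.k_min:
            raise ConfigError("consensus k range invalid")


@dataclass
class KNNParams:
    k_grid: tuple[int, ...] = (3, 5, 10)
    feature_grid: tuple[int, ...] = (
        3, 4, 5, 10, 20, 30, 50, 100, 250, 500, 1000, 2500, 5000, 10000
    )

    def validate(self) -> None:
        if not self.k_grid or not self.feature_grid:
            raise ConfigError("knn grids must be non-empty")
        if min(self.k_grid) < 1:
            raise ConfigError("knn.k_grid values must be >= 1")


@dataclass
class GSVAParams:
    tau: float = 1.0
    bandwidth_factor: float = 4.0   # kernel bandwidth h_g = sd_g / factor
    mx_diff: bool = True
    abs_rank: bool = False

    def validate(self) -> None:
        if self.tau < 0:
            raise ConfigError("gsva.tau must be >= 0")
        if self.bandwidth_factor <= 0:
            raise ConfigError("gsva.bandwidth_factor must be > 0")


@dataclass
class MarkerThresholds:
    lfc_min: float = 2.0
    adj_p_max: float = 0.05
    delta_beta_min: float = 0.2
    top_n: int = 100

    def validate(self) -> None:
        if min(self.lfc_min, self.adj_p_max, self.delta_beta_min) <= 0 or self.top_n <= 0:
            raise ConfigError("marker thresholds must be positive")


@dataclass
class WESFilterThresholds:
    mapq_min: float = 20.0
    baseq_min: float = 15.0
    depth_min: int = 8              # tumor and normal
    alt_reads_min: int = 4
    vaf_tumor_min_snv: float = 0.04
    vaf_tumor_min_indel: float = 0.10
    vaf_normal_max: float = 0.02    # exclusive
    ebcall_p_max: float = 1e-5
    fisher_p_max: float = 1e-2


@dataclass
class HotspotThresholds:
    """Relaxed criteria for known-hotspot positions (no EBCall criterion)."""

    mapq_min: float = 20.0
    baseq_min: float = 15.0
    depth_min: int = 8
    alt_reads_min: int = 4
    vaf_tumor_min: float = 0.02     # both SNV and indel
    vaf_normal_max: float = 0.02
    fisher_p_max: float = 10 ** -1.5


@dataclass
class DeepSeqFilterThresholds:
    mapq_min: float = 20.0
    baseq_min: float = 15.0
    depth_min: int = 8
    alt_read_pairs_min: int = 4
    vaf_min: float = 0.02
    ebcall_p_max: float = 1e-4
    germline_band: tuple[float, float] = (0.45, 0.55)   # inclusive
    subclonal_vaf: float = 0.10                          # strict <


@dataclass
class PathwayDefinition:
    name: str = "RTK-RAS"
    genes: tuple[str, ...] = ("KRAS", "NRAS", "FLT3", "PTPN11", "BRAF", "NF1", "CBL")

    def validate(self) -> None:
        if not self.genes:
            raise ConfigError("pathway gene list must be non-empty")


@dataclass
class PreprocessParams:
    n_top_genes: int = 200
    n_top_probes: int = 1000
    tpm_all_threshold: float = 1.0
    tpm_mean_threshold: float = 0.5
    cell_min_counts: int = 1000
    cell_min_genes: int = 500
    cell_max_genes: int = 3000
    cell_max_mito_frac: float = 0.15
    gene_min_cells: int = 10

    def validate(self) -> None:
        if self.cell_min_genes >= self.cell_max_genes:
            raise ConfigError("cell QC: min_genes must be < max_genes")
        for v in (self.n_top_genes, self.n_top_probes, self.tpm_all_threshold,
                  self.tpm_mean_threshold, self.cell_min_counts,
                  self.cell_max_mito_frac, self.gene_min_cells):
            if v <= 0:
                raise ConfigError("preprocess thresholds must be positive")


@dataclass
class RegulonParams:
    rho_min: float = 0.5
    adj_p_max: float = 0.01
    min_targets: int = 10

    def validate(self) -> None:
        if not (0 < self.rho_min < 1):
            raise ConfigError("regulon.rho_min must be in (0, 1)")


@dataclass
class AnalysisConfig:
    """Top-level configuration mirrored one-to-one by the JSON config file."""

    snf: SNFParams = field(default_factory=SNFParams)
    consensus: ConsensusParams = field(default_factory=ConsensusParams)
    knn: KNNParams = field(default_factory=KNNParams)
    gsva: GSVAParams = field(default_factory=GSVAParams)
    markers: MarkerThresholds = field(default_factory=MarkerThresholds)
    wes_filter: WESFilterThresholds = field(default_factory=WESFilterThresholds)
    hotspot_filter: HotspotThresholds = field(default_factory=HotspotThresholds)
    deepseq_filter: DeepSeqFilterThresholds = field(default_factory=DeepSeqFilterThresholds)
    pathway: PathwayDefinition = field(default_factory=PathwayDefinition)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    regulon: RegulonParams = field(default_factory=RegulonParams)
    seed: int = 0

    def validate(self) -> None:
        for block in (self.snf, self.consensus, self.knn, self.gsva,
                      self.markers, self.pathway, self.preprocess, self.regulon):
            if hasattr(block, "validate"):
                block.validate()

    # -- JSON round trip ---------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AnalysisConfig":
        p = Path(source)
        data = json.loads(p.read_text() if p.exists() else str(source))
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in data:
                continue
            sub = data[f.name]
            if dataclasses.is_dataclass(f.type) or f.name != "seed":
                block_cls = cls.__dataclass_fields__[f.name].default_factory  # type: ignore
                block = block_cls()
                for k, v in sub.items():
                    if not hasattr(block, k):
                        raise ConfigError(f"unknown key {f.name}.{k}")
                    cur = getattr(block, k)
                    setattr(block, k, tuple(v) if isinstance(cur, tuple) else v)
                kwargs[f.name] = block
            else:
                kwargs[f.name] = sub
        if "seed" in data:
            kwargs["seed"] = int(data["seed"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg
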