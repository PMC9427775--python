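"""Synthetic cohort generator emulating the dual-omics study structure.

The generator plants a five-cluster cohort (sizes 14/14/12/9/12 by default)
with *complementary* information across the two omics layers: expression
marker genes separate only the coarse two-way split (the IRX-like vs
HOXA-like axis), while methylation marker probes refine that split to the
full partition — every cluster except the last cluster of each side owns a
differentially methylated probe block. Neither layer alone resolves all
five groups; their fusion does, reproducing the single-omics vs dual-omics
contrast the pipeline is built around.

Also simulated: fusion-partner labels statistically associated with the
clusters, per-case somatic mutation tables with clonal/subclonal VAF
mixtures and a cluster-dependent RTK-RAS burden, a two-platform batch
effect (additive in M-value space only, so batch removal is exactly
sufficient), and cluster-dependent survival with administrative censoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigError, PathwayDefinition
from .types import (
    ClinicalRecord,
    Effect,
    GeneSetCollection,
    Layer,
    OmicsMatrix,
    VariantRecord,
)

log = logging.getLogger("icfuse")

STAGE_NAMES = ("HSC/MPP", "Pre pro-B", "Pro-B", "Pre-B", "B cell")
PARTNERS = ("AFF1", "MLLT1", "MLLT3", "EPS15", "other")
PROTOCOLS = ("MLL-10", "MLL03", "MLL96/98")


def _logit2(beta: np.ndarray) -> np.ndarray:
    return np.log2(beta / (1 - beta))


def _expit2(m: np.ndarray) -> np.ndarray:
    return np.exp2(m) / (1 + np.exp2(m))


def _m_shift_for_delta_beta(mu: np.ndarray, delta: np.ndarray, sd: float
                            ) -> np.ndarray:
    """M-value shift whose *noise-averaged* beta effect equals delta.

    The logistic transform of noisy M-values compresses mean beta
    differences (E[expit(M + e)] != expit(E[M])), so the shift is computed
    on the smoothed beta scale: S(m) = E[expit2(m + sd Z)], evaluated by
    Gauss-Hermite quadrature and inverted on a grid.
    """
    nodes, weights = np.polynomial.hermite_e.hermegauss(40)
    grid = np.linspace(-12.0, 12.0, 2001)
    smoothed = (_expit2(grid[:, None] + sd * nodes[None, :]) @ weights
                ) / weights.sum()
    beta0 = np.interp(mu, grid, smoothed)
    target = np.clip(beta0 + delta, 0.02, 0.98)
    shifted_mu = np.interp(target, smoothed, grid)
    return shifted_mu - mu


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_samples: int = 61
    cluster_sizes: tuple[int, ...] = (14, 14, 12, 9, 12)
    n_genes: int = 5000
    n_probes: int = 20000
    markers_per_cluster_expr: int = 100
    markers_per_cluster_meth: int = 200
    expr_effect: float = 2.0            # mean shift, log2 expression units
    meth_effect: float = 0.3            # planted delta-beta
    dual_expr_effect: float = 3.5       # shift of the planted dual-marker genes
    n_dual_markers: int = 20            # dual-marker genes per refining cluster
    noise_sd_expr: float = 1.0
    noise_sd_m: float = 0.5             # per-probe M-value noise
    meth_base_concentration: float = 2.0  # sd of per-probe baseline M-values
    # cluster-unrelated biological variability (e.g. proliferation, immune
    # admixture, age): high-variance features with no subtype structure, so
    # MAD selection returns a realistic mix of informative and uninformative
    # features instead of a pure marker panel
    n_noise_genes: int = 200
    noise_gene_sd_range: tuple[float, float] = (1.2, 1.8)
    n_noise_probes: int = 500
    noise_probe_sd_range: tuple[float, float] = (0.45, 0.6)
    complementary_design: bool = True
    coarse_split_index: int = 2         # clusters [0, idx) form side A
    partner_probs: dict[int, tuple[float, ...]] = field(default_factory=lambda: {
        0: (0.60, 0.15, 0.05, 0.10, 0.10),
        1: (0.60, 0.20, 0.05, 0.05, 0.10),
        2: (0.10, 0.80, 0.05, 0.025, 0.025),
        3: (0.10, 0.05, 0.80, 0.025, 0.025),
        4: (0.90, 0.05, 0.025, 0.0, 0.025),
    })
    # RTK-RAS burden: one heavily burdened cluster (truncated Poisson on
    # {1..6}, mean ~2.6); the others carry a point mass at zero.
    burden_cluster: int = 1
    burden_lambda: float = 2.45
    burden_range: tuple[int, int] = (1, 6)
    background_p_zero: float = 0.4
    background_lambda: float = 0.5
    background_max: int = 4
    # VAF mixture: clonal vs subclonal (deep-seq detection floor 0.02)
    subclonal_fraction: float = 0.48
    subclonal_vaf_range: tuple[float, float] = (0.02, 0.10)
    clonal_vaf_mean: float = 0.45
    clonal_vaf_sd: float = 0.05
    non_pathway_mutation_rate: float = 0.5  # Poisson mean per case
    # survival: per-cluster exponential EFS hazards (per day)
    efs_hazards: tuple[float, ...] = (2.5e-4, 1.5e-3, 5e-4, 7e-4, 6e-4)
    os_hazard_scale: float = 0.6        # OS hazard = scale * EFS hazard
    censor_horizon_days: float = 2000.0
    remission_failure_frac: float = 0.1  # fraction of the worst cluster
    batch_fraction: float = 0.5          # probability of the second platform
    batch_effect_sd: float = 0.3         # per-probe additive M-value shift
    pathway: PathwayDefinition = field(default_factory=PathwayDefinition)
    seed: int = 0

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    def validate(self) -> None:
        if sum(self.cluster_sizes) != self.n_samples:
            raise ConfigError(
                f"cluster sizes {self.cluster_sizes} must sum to "
                f"n_samples={self.n_samples}"
            )
        for c, probs in self.partner_probs.items():
            if abs(sum(probs) - 1.0) > 1e-8:
                raise ConfigError(f"partner probabilities for cluster {c} "
                                  "must sum to 1")
        if len(self.efs_hazards) < self.n_clusters:
            raise ConfigError("one EFS hazard per cluster required")
        if min(self.efs_hazards[: self.n_clusters]) <= 0:
            raise ConfigError("hazards must be positive")
        for eff in (self.expr_effect, self.meth_effect):
            if not np.isfinite(eff):
                raise ConfigError("effects must be finite")
        if self.n_genes < self.n_clusters * self.markers_per_cluster_expr:
            raise ConfigError("too few genes for the marker blocks")
        if self.n_probes < self.n_clusters * self.markers_per_cluster_meth:
            raise ConfigError("too few probes for the marker blocks")

    def refining_clusters(self) -> list[int]:
        """Clusters owning a methylation marker block.

        Complementary design: all but the last cluster of each coarse side
        (their identity is implied by the expression split plus the other
        refiners). Full design: every cluster.
        """
        if not self.complementary_design:
            return list(range(self.n_clusters))
        side_a = list(range(self.coarse_split_index))
        side_b = list(range(self.coarse_split_index, self.n_clusters))
        return side_a[:-1] + side_b[:-1]


@dataclass
class CohortBundle:
    config: SimulationConfig
    expression: OmicsMatrix
    methylation: OmicsMatrix           # beta scale
    batch: pd.Series
    labels: pd.Series                  # case -> "IC1".."IC5"
    clinical: list[ClinicalRecord]
    variants: list[VariantRecord]
    marker_genes: dict[str, list[str]]
    marker_probes: dict[str, list[str]]
    dual_marker_genes: dict[str, list[str]]
    probe_gene_map: pd.Series
    stage_sets: GeneSetCollection
    stage_of_cluster: dict[str, str]


def _cluster_vector(config: SimulationConfig) -> np.ndarray:
    return np.repeat(np.arange(config.n_clusters), config.cluster_sizes)


def _side(config: SimulationConfig, cluster: int) -> int:
    return 0 if cluster < config.coarse_split_index else 1


def simulate_cohort(config: SimulationConfig | None = None) -> CohortBundle:
    """Draw a full cohort bundle; bit-reproducible under config.seed."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    k = config.n_clusters
    clusters = _cluster_vector(config)
    n = config.n_samples
    case_ids = [f"CASE_{i + 1:03d}" for i in range(n)]
    cluster_names = [f"IC{c + 1}" for c in range(k)]
    labels = pd.Series([cluster_names[c] for c in clusters], index=case_ids,
                       name="cluster")

    # ---- expression ------------------------------------------------------
    gene_ids = [f"GENE_{g + 1:05d}" for g in range(config.n_genes)]
    base = rng.normal(6.0, 1.5, size=config.n_genes)
    gene_sd = np.full(config.n_genes, config.noise_sd_expr)
    if config.n_noise_genes:
        lo, hi = config.noise_gene_sd_range
        gene_sd[config.n_genes - config.n_noise_genes:] = rng.uniform(
            lo, hi, size=config.n_noise_genes
        )
    X = base[:, None] + gene_sd[:, None] * rng.standard_normal(
        (config.n_genes, n)
    )
    mpc = config.markers_per_cluster_expr
    marker_genes: dict[str, list[str]] = {}
    dual_markers: dict[str, list[str]] = {}
    refiners = set(config.refining_clusters())
    for c in range(k):
        block = np.arange(c * mpc, (c + 1) * mpc)
        marker_genes[cluster_names[c]] = [gene_ids[g] for g in block]
        if config.complementary_design:
            target = np.isin(clusters, [
                cc for cc in range(k) if _side(config, cc) == _side(config, c)
            ])
            X[np.ix_(block, np.flatnonzero(target))] += config.expr_effect
        else:
            cols = np.flatnonzero(clusters == c)
            n_dual = min(config.n_dual_markers, mpc) if c in refiners else 0
            X[np.ix_(block[n_dual:], cols)] += config.expr_effect
            if n_dual:
                X[np.ix_(block[:n_dual], cols)] += config.dual_expr_effect
                dual_markers[cluster_names[c]] = [gene_ids[g]
                                                  for g in block[:n_dual]]
    expression = OmicsMatrix(
        pd.DataFrame(X, index=gene_ids, columns=case_ids), Layer.EXPRESSION_LOG
    )

    # ---- methylation -----------------------------------------------------
    probe_ids = [f"cg{p + 1:07d}" for p in range(config.n_probes)]
    mpm = config.markers_per_cluster_meth
    mu = rng.normal(0.0, config.meth_base_concentration, size=config.n_probes)
    marker_probes: dict[str, list[str]] = {}
    probe_gene: dict[str, str] = {}
    M = np.zeros((config.n_probes, n))
    shift = np.zeros((config.n_probes, n))
    n_dual = min(config.n_dual_markers, mpm, mpc)
    for c in range(k):
        block = np.arange(c * mpm, (c + 1) * mpm)
        marker_probes[cluster_names[c]] = [probe_ids[p] for p in block]
        # first n_dual probes are hypomethylated partners of the dual-marker
        # genes; the rest alternate hyper to keep both directions present
        sign = np.where(np.arange(block.size) < n_dual, -1.0,
                        np.where(np.arange(block.size) % 2 == 0, 1.0, -1.0))
        # baselines leave headroom for the planted shift in its direction,
        # staying off the compressive tails of the logistic scale
        lo = np.where(sign < 0, 0.30 + config.meth_effect, 0.20)
        hi = np.where(sign < 0, 0.85, 0.80 - config.meth_effect)
        beta0 = rng.uniform(lo, np.maximum(hi, lo + 0.05))
        mu[block] = _logit2(beta0)
        if c not in refiners:
            continue
        cols = np.flatnonzero(clusters == c)
        delta_m = _m_shift_for_delta_beta(
            mu[block], sign * config.meth_effect, config.noise_sd_m
        )
        shift[np.ix_(block, cols)] = delta_m[:, None]
        for j in range(n_dual):
            probe_gene[probe_ids[block[j]]] = gene_ids[c * mpc + j]
    probe_sd = np.full(config.n_probes, config.noise_sd_m)
    if config.n_noise_probes:
        plo, phi = config.noise_probe_sd_range
        probe_sd[config.n_probes - config.n_noise_probes:] = rng.uniform(
            plo, phi, size=config.n_noise_probes
        )
    M = mu[:, None] + shift + probe_sd[:, None] * rng.standard_normal(
        (config.n_probes, n)
    )

    # two-platform batch shift, additive in M-value space only
    batch = pd.Series(
        np.where(rng.random(n) < config.batch_fraction, "EPIC", "450K"),
        index=case_ids, name="platform",
    )
    delta_batch = rng.normal(0.0, config.batch_effect_sd, size=config.n_probes)
    M[:, (batch == "EPIC").to_numpy()] += delta_batch[:, None]
    beta = _expit2(M)
    methylation = OmicsMatrix(
        pd.DataFrame(beta, index=probe_ids, columns=case_ids),
        Layer.METHYLATION_BETA,
    )

    # ---- clinical + survival --------------------------------------------
    partners = np.empty(n, dtype=object)
    for c in range(k):
        cols = np.flatnonzero(clusters == c)
        probs = np.asarray(config.partner_probs[c], dtype=float)
        partners[cols] = rng.choice(PARTNERS, size=cols.size, p=probs)
    surv = simulate_survival(labels, config, rng=rng)
    clinical = []
    for i, case in enumerate(case_ids):
        clinical.append(ClinicalRecord(
            case_id=case,
            age_months=float(rng.uniform(0.5, 11.5)),
            sex=str(rng.choice(["F", "M"])),
            wbc=float(np.exp(rng.normal(11.0, 1.0))),
            cns_involved=bool(rng.random() < 0.2),
            protocol=str(rng.choice(PROTOCOLS)),
            fusion_partner=str(partners[i]),
            remission_failure=bool(surv["remission_failure"].iloc[i]),
            efs_time_days=float(surv["efs_time"].iloc[i]),
            efs_event=bool(surv["efs_event"].iloc[i]),
            os_time_days=float(surv["os_time"].iloc[i]),
            os_event=bool(surv["os_event"].iloc[i]),
            cluster_label=str(labels.iloc[i]),
        ))

    # ---- somatic mutation tables ----------------------------------------
    variants = _simulate_case_mutations(labels, clusters, config, rng)

    # ---- developmental stage gene sets ----------------------------------
    stage_sets = GeneSetCollection({
        STAGE_NAMES[c % len(STAGE_NAMES)]: marker_genes[cluster_names[c]]
        for c in range(k)
    })
    stage_of_cluster = {cluster_names[c]: STAGE_NAMES[c % len(STAGE_NAMES)]
                        for c in range(k)}

    return CohortBundle(
        config=config,
        expression=expression,
        methylation=methylation,
        batch=batch,
        labels=labels,
        clinical=clinical,
        variants=variants,
        marker_genes=marker_genes,
        marker_probes=marker_probes,
        dual_marker_genes=dual_markers,
        probe_gene_map=pd.Series(probe_gene, name="gene"),
        stage_sets=stage_sets,
        stage_of_cluster=stage_of_cluster,
    )


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def simulate_survival(labels: pd.Series, config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Exponential event times with per-cluster hazards and censoring.

    Administrative censoring at the configured horizon; a configurable
    fraction (exactly, by count) of the worst — highest-hazard — cluster is
    marked as remission failure, an EFS event at time 0.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    hazards = np.asarray(config.efs_hazards, dtype=float)
    if (hazards[: config.n_clusters] <= 0).any() or config.os_hazard_scale <= 0:
        raise ConfigError("hazards must be positive")
    names = sorted({str(l) for l in labels})
    cluster_index = {name: i for i, name in enumerate(names)}
    idx = np.array([cluster_index[str(l)] for l in labels])
    lam = hazards[idx]
    horizon = config.censor_horizon_days
    efs_raw = rng.exponential(1.0 / lam)
    efs_event = efs_raw < horizon
    efs_time = np.minimum(efs_raw, horizon)
    os_raw = rng.exponential(1.0 / (config.os_hazard_scale * lam))
    os_event = os_raw < horizon
    os_time = np.minimum(os_raw, horizon)
    remission = np.zeros(len(labels), dtype=bool)
    worst = int(np.argmax(hazards[: config.n_clusters]))
    worst_cols = np.flatnonzero(idx == worst)
    n_fail = int(round(config.remission_failure_frac * worst_cols.size))
    if n_fail:
        chosen = rng.choice(worst_cols, size=n_fail, replace=False)
        remission[chosen] = True
        efs_time[chosen] = 0.0
        efs_event[chosen] = True
    return pd.DataFrame({
        "efs_time": efs_time, "efs_event": efs_event,
        "os_time": os_time, "os_event": os_event,
        "remission_failure": remission,
    }, index=labels.index)


# ---------------------------------------------------------------------------
# somatic variants
# ---------------------------------------------------------------------------

_NON_PATHWAY_GENES = ("PAX5", "CDKN2A", "CCND3", "TP53", "CREBBP")


def _draw_vaf(config: SimulationConfig, rng: np.random.Generator
              ) -> tuple[float, bool]:
    """Clonal/subclonal VAF mixture; returns (vaf, is_subclonal_draw)."""
    if rng.random() < config.subclonal_fraction:
        lo, hi = config.subclonal_vaf_range
        return float(rng.uniform(lo, hi)), True
    vaf = rng.normal(config.clonal_vaf_mean, config.clonal_vaf_sd)
    return float(np.clip(vaf, 0.0, 1.0)), False


def _make_mutation(case: str, gene: str, config: SimulationConfig,
                   rng: np.random.Generator, serial: int) -> VariantRecord:
    vaf, _sub = _draw_vaf(config, rng)
    depth = int(rng.integers(800, 1200))
    alt = max(int(round(vaf * depth)), 4)
    vaf = alt / depth
    fwd = int(rng.integers(1, alt)) if alt > 1 else 1
    lo, hi = (0.45, 0.55)
    in_band = lo <= vaf <= hi
    return VariantRecord(
        case_id=case, chrom=str(rng.integers(1, 23)),
        pos=int(rng.integers(1, 2**27)) * 100 + serial,
        ref="A", alt="T", gene=gene,
        effect=Effect(rng.choice(["missense", "nonsense", "frameshift"],
                                 p=[0.8, 0.1, 0.1])),
        is_indel=False,
        depth_tumor=depth, depth_normal=int(rng.integers(800, 1200)),
        alt_reads_tumor=alt, vaf_tumor=vaf, vaf_normal=0.0,
        mapq=60.0, baseq=30.0, ebcall_p=1e-8, fisher_p=1e-6,
        reads_fwd=fwd, reads_rev=alt - fwd,
        copy_neutral=True, confirmed_somatic_by_wes=in_band,
    )


def _simulate_case_mutations(labels: pd.Series, clusters: np.ndarray,
                             config: SimulationConfig,
                             rng: np.random.Generator) -> list[VariantRecord]:
    lo, hi = config.burden_range
    records: list[VariantRecord] = []
    serial = 0
    for i, case in enumerate(labels.index):
        c = clusters[i]
        if c == config.burden_cluster:
            while True:  # truncated Poisson on {lo..hi}
                n_path = int(rng.poisson(config.burden_lambda))
                if lo <= n_path <= hi:
                    break
        else:
            if rng.random() < config.background_p_zero:
                n_path = 0
            else:
                n_path = 1 + int(rng.poisson(config.background_lambda))
                n_path = min(n_path, config.background_max)
        genes = rng.choice(config.pathway.genes, size=n_path, replace=True)
        for g in genes:
            serial += 1
            records.append(_make_mutation(str(case), str(g), config, rng, serial))
        for _ in range(int(rng.poisson(config.non_pathway_mutation_rate))):
            serial += 1
            g = str(rng.choice(_NON_PATHWAY_GENES))
            records.append(_make_mutation(str(case), g, config, rng, serial))
    return records


# ---------------------------------------------------------------------------
# filter-fidelity candidates
# ---------------------------------------------------------------------------

#: planted single-violation artifact types and the first rule each breaks
ARTIFACT_TYPES = (
    "mapq", "baseq", "depth", "alt_reads", "vaf_tumor", "ebcall_p",
    "synonymous_or_splice", "single_direction", "snp_db", "simple_repeat",
    "paired_normal", "germline_band",
)


def simulate_variant_candidates(
    config: SimulationConfig | None = None,
    n_candidates: int = 200,
    seed: int | None = None,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Candidates for the deep-seq filter: true calls plus planted artifacts.

    Half the candidates are true somatic calls satisfying every criterion;
    the rest are artifacts, each violating exactly one rule (cycled through
    ARTIFACT_TYPES). Ground truth (pass flag + expected first fail reason)
    is returned alongside. Subclonal true calls below the deep-seq VAF
    detection floor are emitted as planted "vaf_tumor" failures.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records, truth = [], []
    for i in range(n_candidates):
        case = f"CASE_{rng.integers(1, config.n_samples + 1):03d}"
        gene = str(rng.choice(config.pathway.genes))
        base = _make_mutation(case, gene, config, rng, serial=i)
        if i % 2 == 0:
            records.append(base)
            truth.append({"index": i, "should_pass": True, "fail_reason": None})
            continue
        kind = ARTIFACT_TYPES[(i // 2) % len(ARTIFACT_TYPES)]
        r = base
        if kind == "mapq":
            r.mapq = 15.0
        elif kind == "baseq":
            r.baseq = 10.0
        elif kind == "depth":
            r.depth_tumor, r.alt_reads_tumor = 7, 4
            r.vaf_tumor = 4 / 7
            r.reads_fwd, r.reads_rev = 2, 2
            r.confirmed_somatic_by_wes = True  # isolate the depth violation
        elif kind == "alt_reads":
            # depth shrunk so the VAF stays above 0.02 and only the
            # variant-read-count rule is violated
            r.depth_tumor = 100
            r.alt_reads_tumor = 3
            r.vaf_tumor = 0.03
            r.reads_fwd, r.reads_rev = 2, 1
        elif kind == "vaf_tumor":
            r.depth_tumor = 1000
            r.alt_reads_tumor = int(rng.integers(10, 20))  # VAF 0.010-0.019
            r.vaf_tumor = r.alt_reads_tumor / 1000
            r.reads_fwd = r.alt_reads_tumor - r.alt_reads_tumor // 2
            r.reads_rev = r.alt_reads_tumor // 2
        elif kind == "ebcall_p":
            r.ebcall_p = 1e-3
        elif kind == "synonymous_or_splice":
            r.effect = Effect.SYNONYMOUS
        elif kind == "single_direction":
            r.reads_fwd, r.reads_rev = r.alt_reads_tumor, 0
        elif kind == "snp_db":
            r.in_snp_db = True
        elif kind == "simple_repeat":
            r.in_simple_repeat = True
        elif kind == "paired_normal":
            r.seen_in_paired_normal = True
        elif kind == "germline_band":
            r.depth_tumor = 1000
            r.alt_reads_tumor = 500
            r.vaf_tumor = 0.5
            r.reads_fwd, r.reads_rev = 250, 250
            r.copy_neutral = True
            r.confirmed_somatic_by_wes = False
        records.append(r)
        truth.append({"index": i, "should_pass": False, "fail_reason": kind})
    return records, pd.DataFrame(truth).set_index("index")
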