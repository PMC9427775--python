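"""Single-sample enrichment, preranked GSEA, markers, stages and regulons.

The single-sample score follows the GSVA construction: per-gene expression
values are turned into smoothed empirical CDF values with a Gaussian kernel
(bandwidth sd/4), genes are ranked per sample, the ranks are folded into a
symmetric statistic, and a weighted Kolmogorov-Smirnov random walk down the
ranked list yields the enrichment score (max positive plus min negative
deviation by default). Differential marker calling uses Welch t statistics
on the variance-stabilized expression scale (and on M-values for
methylation, with delta-beta effect sizes), BH-adjusted.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr
from statsmodels.stats.multitest import multipletests

from .config import GSVAParams, MarkerThresholds, RegulonParams
from .preprocess import beta_m_convert
from .types import GeneSetCollection, Layer, OmicsMatrix, ValidationError

log = logging.getLogger("icfuse")


class EnrichmentMatrix(OmicsMatrix):
    """Gene-sets x samples single-sample enrichment scores in [-1, 1]."""

    def __init__(self, values: pd.DataFrame):
        super().__init__(values, Layer.EXPRESSION_LOG)
        arr = self.to_numpy()
        if arr.min() < -1 - 1e-9 or arr.max() > 1 + 1e-9:
            raise ValidationError("enrichment scores must lie in [-1, 1]")


# ---------------------------------------------------------------------------
# GSVA-style single-sample enrichment
# ---------------------------------------------------------------------------

def _gsva_density_scores(X: np.ndarray, bandwidth_factor: float) -> np.ndarray:
    """Gaussian-CDF-smoothed relative expression, gene by gene.

    z[g, j] = mean_k Phi((x[g, j] - x[g, k]) / h_g), h_g = sd_g / factor.
    """
    n = X.shape[1]
    sd = X.std(axis=1, ddof=1)
    h = np.maximum(sd / bandwidth_factor, 1e-8)
    diffs = (X[:, :, None] - X[:, None, :]) / h[:, None, None]
    return ndtr(diffs).mean(axis=2)


def _walk_es(order: np.ndarray, in_set: np.ndarray, weight: np.ndarray,
             tau: float, mx_diff: bool, abs_rank: bool) -> float:
    """Weighted KS random walk down one ranked gene list."""
    P = order.size
    members = in_set[order]
    w = np.abs(weight[order]) ** tau
    w_in = np.where(members, w, 0.0)
    denom_in = w_in.sum()
    m = int(members.sum())
    if denom_in <= 0 or m == 0 or m == P:
        raise ValidationError("gene set empty or spanning the whole list")
    steps = np.where(members, w_in / denom_in, -1.0 / (P - m))
    walk = np.cumsum(steps)
    if abs_rank:
        return float(np.max(walk) - np.min(walk))
    max_dev = max(float(walk.max()), 0.0)
    min_dev = min(float(walk.min()), 0.0)
    if mx_diff:
        return max_dev + min_dev
    return max_dev if max_dev > -min_dev else min_dev


def gsva_scores(X: OmicsMatrix, sets: GeneSetCollection,
                params: GSVAParams | None = None) -> EnrichmentMatrix:
    """Single-sample enrichment of each gene set in each sample."""
    params = params or GSVAParams()
    params.validate()
    if X.shape[1] < 3:
        raise ValidationError("gsva requires >= 3 samples")
    genes = X.feature_ids
    sets = sets.restrict_to(genes)
    if not len(sets):
        raise ValidationError("no gene set intersects the expression matrix")
    arr = X.to_numpy()
    z = _gsva_density_scores(arr, params.bandwidth_factor)
    P = len(genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    scores = np.zeros((len(sets), X.shape[1]))
    # per sample: rank genes by z descending, symmetric rank statistic
    for j in range(X.shape[1]):
        order = np.argsort(-z[:, j], kind="stable")
        ranks = np.empty(P)
        ranks[order] = np.arange(1, P + 1)
        r = np.abs(P / 2.0 - ranks)
        for si, (_name, members) in enumerate(sets):
            in_set = np.zeros(P, dtype=bool)
            in_set[[gene_index[g] for g in members]] = True
            scores[si, j] = _walk_es(order, in_set, r, params.tau,
                                     params.mx_diff, params.abs_rank)
    return EnrichmentMatrix(
        pd.DataFrame(scores, index=sets.names, columns=X.sample_ids)
    )


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------

def _preranked_es(metric: np.ndarray, in_set: np.ndarray) -> float:
    """Classic weighted-KS enrichment score (weight exponent 1 on |metric|)."""
    order = np.argsort(-metric, kind="stable")
    members = in_set[order]
    m = int(members.sum())
    P = metric.size
    if m == 0 or m == P:
        raise ValidationError("set must be a proper non-empty subset of genes")
    w = np.abs(metric[order])
    w_in = np.where(members, w, 0.0)
    denom = w_in.sum()
    if denom <= 0:  # all member metrics zero: fall back to unweighted steps
        steps_in = np.where(members, 1.0 / m, 0.0)
    else:
        steps_in = w_in / denom
    steps = np.where(members, steps_in, -1.0 / (P - m))
    walk = np.cumsum(steps)
    return float(walk[np.argmax(np.abs(walk))])


def preranked_gsea(rank_metric: pd.Series, gene_set: list[str],
                   n_perm: int = 1000, seed: int = 0) -> dict:
    """Preranked GSEA of one set against a signed per-gene metric.

    The null is built from `n_perm` random gene sets of equal size; NES
    divides ES by the mean |null ES| of matching sign, and the empirical P
    and FDR use the sign-matched null pool.
    """
    metric = rank_metric.to_numpy(dtype=float)
    if not np.isfinite(metric).all():
        raise ValidationError("rank metric must be finite")
    genes = [str(g) for g in rank_metric.index]
    in_set = np.isin(genes, list(gene_set))
    m = int(in_set.sum())
    if m == 0 or m == len(genes):
        raise ValidationError("gene set empty or equal to the gene universe")
    es = _preranked_es(metric, in_set)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = np.zeros(len(genes), dtype=bool)
        perm[rng.choice(len(genes), size=m, replace=False)] = True
        null[i] = _preranked_es(metric, perm)
    same_sign = null * np.sign(es) > 0 if es != 0 else np.ones(n_perm, bool)
    pool = np.abs(null[same_sign])
    # empirical two-sided p over the full null (uniform under the null)
    p = (np.sum(np.abs(null) >= abs(es)) + 1) / (n_perm + 1)
    mean_null = pool.mean() if pool.size else np.nan
    nes = es / mean_null if mean_null and np.isfinite(mean_null) else np.nan
    # single observed set: the sign-matched null-pool FDR estimate
    fdr = min(1.0, (np.sum(pool >= abs(es)) + 1) / (max(pool.size, 1) + 1))
    return {"es": es, "nes": float(nes), "p": float(p), "fdr": float(fdr)}


# ---------------------------------------------------------------------------
# differential markers
# ---------------------------------------------------------------------------

def _welch_frame(A: np.ndarray, B: np.ndarray, index, effect_name: str
                 ) -> pd.DataFrame:
    effect = A.mean(axis=1) - B.mean(axis=1)
    t, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    padj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({effect_name: effect, "p": p, "padj": padj}, index=index)


def differential_expression(X: OmicsMatrix, group_a, group_b) -> pd.DataFrame:
    """Per-gene log2FC (mean difference on the log2 scale), Welch t, BH."""
    A = X.values.loc[:, list(group_a)].to_numpy()
    B = X.values.loc[:, list(group_b)].to_numpy()
    if A.shape[1] < 2 or B.shape[1] < 2:
        raise ValidationError("each group needs >= 2 samples")
    return _welch_frame(A, B, X.values.index, "log2fc")


def differential_methylation(beta: OmicsMatrix, group_a, group_b) -> pd.DataFrame:
    """Per-probe delta-beta effect with Welch t P values on M-values."""
    if beta.layer is not Layer.METHYLATION_BETA:
        raise ValidationError("differential_methylation expects a beta matrix")
    A = beta.values.loc[:, list(group_a)].to_numpy()
    B = beta.values.loc[:, list(group_b)].to_numpy()
    if A.shape[1] < 2 or B.shape[1] < 2:
        raise ValidationError("each group needs >= 2 samples")
    M = beta_m_convert(beta, "beta_to_m")
    Ma = M.values.loc[:, list(group_a)].to_numpy()
    Mb = M.values.loc[:, list(group_b)].to_numpy()
    out = _welch_frame(Ma, Mb, beta.values.index, "t_effect_m")
    out.insert(0, "delta_beta", A.mean(axis=1) - B.mean(axis=1))
    return out.drop(columns=["t_effect_m"])


def cluster_markers(X: OmicsMatrix, labels: pd.Series,
                    thresholds: MarkerThresholds | None = None
                    ) -> dict[str, dict[str, list[str]]]:
    """Top-N up / down marker genes per cluster (each cluster vs rest)."""
    thresholds = thresholds or MarkerThresholds()
    labels = pd.Series(labels, index=X.sample_ids) if not isinstance(labels, pd.Series) else labels
    out: dict[str, dict[str, list[str]]] = {}
    for cluster in pd.unique(labels):
        in_c = labels.index[labels == cluster]
        rest = labels.index[labels != cluster]
        if len(in_c) < 2 or len(rest) < 2:
            log.warning("cluster_markers: cluster %r leaves < 2 samples on "
                        "one side; skipped", cluster)
            continue
        de = differential_expression(X, in_c, rest)
        sig = de[de["padj"] < thresholds.adj_p_max]
        up = sig[sig["log2fc"] > 0].reindex(
            sig[sig["log2fc"] > 0]["log2fc"].abs().sort_values(ascending=False).index
        )
        down = sig[sig["log2fc"] < 0].reindex(
            sig[sig["log2fc"] < 0]["log2fc"].abs().sort_values(ascending=False).index
        )
        out[str(cluster)] = {
            "up": [str(g) for g in up.index[: thresholds.top_n]],
            "down": [str(g) for g in down.index[: thresholds.top_n]],
            "table": de,
        }
    return out


def dual_omics_markers(
    expr_results: dict[str, pd.DataFrame],
    meth_results: dict[str, pd.DataFrame],
    probe_gene_map: pd.Series,
    thresholds: MarkerThresholds | None = None,
) -> dict[str, list[str]]:
    """Genes passing expression thresholds with opposite-sign methylation.

    A gene is a dual-omics marker of a cluster iff |log2FC| >= lfc_min with
    adj P < adj_p_max AND at least one mapped probe has |delta-beta| >=
    delta_beta_min (adj P < adj_p_max) in the opposite direction
    (up-expression with hypo-methylation and vice versa).
    """
    thresholds = thresholds or MarkerThresholds()
    out: dict[str, list[str]] = {}
    for cluster, de in expr_results.items():
        dm = meth_results.get(cluster)
        if dm is None:
            out[cluster] = []
            continue
        mapped = dm.join(probe_gene_map.rename("gene"), how="left")
        n_unmapped = int(mapped["gene"].isna().sum())
        if n_unmapped:
            log.info("dual_omics_markers: %d unmapped probes ignored", n_unmapped)
        mapped = mapped.dropna(subset=["gene"])
        sig_probe = mapped[
            (mapped["delta_beta"].abs() >= thresholds.delta_beta_min)
            & (mapped["padj"] < thresholds.adj_p_max)
        ]
        sig_gene = de[
            (de["log2fc"].abs() >= thresholds.lfc_min)
            & (de["padj"] < thresholds.adj_p_max)
        ]
        markers = []
        for gene, row in sig_gene.iterrows():
            probes = sig_probe[sig_probe["gene"] == gene]
            if probes.empty:
                continue
            opposite = probes["delta_beta"] * row["log2fc"] < 0
            if opposite.any():
                markers.append(str(gene))
        out[cluster] = markers
    return out


# ---------------------------------------------------------------------------
# developmental stage assignment
# ---------------------------------------------------------------------------

def assign_stage(E: EnrichmentMatrix, cluster_labels: pd.Series,
                 hsc_signature: str = "HSC/MPP", alpha: float = 0.05
                 ) -> dict[str, str]:
    """Assign each cluster the most significantly upregulated signature.

    Each signature is tested cluster-vs-rest (Welch t on the enrichment
    scores, BH across signatures). The stem-cell signature is assigned only
    when it is the sole significant signature; clusters with no significant
    signature are labeled "unassigned".
    """
    if hsc_signature not in E.feature_ids:
        raise ValidationError(
            f"enrichment matrix lacks the {hsc_signature!r} signature"
        )
    labels = pd.Series(cluster_labels, index=E.sample_ids) \
        if not isinstance(cluster_labels, pd.Series) else cluster_labels
    arr = E.values
    out: dict[str, str] = {}
    for cluster in pd.unique(labels):
        in_c = labels == cluster
        A = arr.loc[:, in_c.values].to_numpy()
        B = arr.loc[:, ~in_c.values].to_numpy()
        t, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)
        padj = multipletests(p, method="fdr_bh")[1]
        up = (t > 0) & (padj < alpha)
        sig_names = [E.feature_ids[i] for i in np.flatnonzero(up)]
        if not sig_names:
            out[str(cluster)] = "unassigned"
            continue
        ranked = sorted(np.flatnonzero(up), key=lambda i: padj[i])
        if sig_names == [hsc_signature]:
            out[str(cluster)] = hsc_signature
            continue
        non_hsc = [i for i in ranked if E.feature_ids[i] != hsc_signature]
        out[str(cluster)] = E.feature_ids[non_hsc[0]] if non_hsc else hsc_signature
    return out


# ---------------------------------------------------------------------------
# simplified positive regulons
# ---------------------------------------------------------------------------

def infer_regulons(X: OmicsMatrix, tf_list: list[str],
                   params: RegulonParams | None = None) -> GeneSetCollection:
    """Positive regulon of each TF by Spearman correlation.

    A deliberately simplified, correlation-defined regulon: targets are the
    genes (excluding the TF) with rho >= rho_min and BH-adjusted P <
    adj_p_max; regulons smaller than min_targets are dropped with a warning.
    """
    params = params or RegulonParams()
    params.validate()
    n = X.shape[1]
    if n < 10:
        raise ValidationError("regulon inference requires >= 10 samples")
    arr = X.to_numpy()
    ranks = stats.rankdata(arr, axis=1)
    ranks = (ranks - ranks.mean(axis=1, keepdims=True))
    norms = np.linalg.norm(ranks, axis=1)
    genes = X.feature_ids
    gene_index = {g: i for i, g in enumerate(genes)}
    regulons: dict[str, list[str]] = {}
    for tf in tf_list:
        if tf not in gene_index:
            raise ValidationError(f"TF {tf!r} absent from the matrix")
        ti = gene_index[tf]
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = ranks @ ranks[ti] / np.maximum(norms * norms[ti], 1e-12)
        rho = np.clip(np.where(np.isfinite(rho), rho, 0.0), -1, 1)
        # t approximation for the Spearman P value
        with np.errstate(invalid="ignore", divide="ignore"):
            tstat = rho * np.sqrt((n - 2) / np.maximum(1 - rho**2, 1e-12))
        p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
        keep = np.ones(len(genes), dtype=bool)
        keep[ti] = False
        padj = np.full(len(genes), 1.0)
        padj[keep] = multipletests(p[keep], method="fdr_bh")[1]
        targets = [
            genes[i] for i in np.flatnonzero(
                keep & (rho >= params.rho_min) & (padj < params.adj_p_max)
            )
        ]
        if len(targets) < params.min_targets:
            log.warning("infer_regulons: %s regulon has %d targets (< %d); dropped",
                        tf, len(targets), params.min_targets)
            continue
        regulons[tf] = targets
    return GeneSetCollection(regulons)


def kruskal_wallis_screen(E: OmicsMatrix, labels: pd.Series) -> pd.DataFrame:
    """Kruskal-Wallis H (tie-corrected) and chi-square P per signature row."""
    labels = pd.Series(labels, index=E.sample_ids) \
        if not isinstance(labels, pd.Series) else labels
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValidationError("kruskal_wallis_screen requires >= 2 groups")
    arr = E.values
    rows = []
    for name in E.feature_ids:
        samples = [arr.loc[name, (labels == g).values].to_numpy() for g in groups]
        try:
            h, p = stats.kruskal(*samples)
        except ValueError:  # all values identical
            h, p = 0.0, 1.0
        if not np.isfinite(h):  # fully tied data: no evidence either way
            h, p = 0.0, 1.0
        rows.append({"signature": name, "H": float(h), "p": float(p)})
    return pd.DataFrame(rows).set_index("signature")
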