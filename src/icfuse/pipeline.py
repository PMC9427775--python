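"""End-to-end orchestration of the dual-omics subtyping analysis."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .consensus import ConsensusResult, run_consensus
from .knn import TrainedKNN, align_query, grid_search, knn_predict
from .preprocess import prepare_layer_for_clustering
from .simulate import CohortBundle, SimulationConfig, simulate_cohort
from .snf import AffinityMatrix, build_affinity, snf_fuse
from .survival import cox_ph_fit, efs_from_clinical, expand_covariates, logrank_test
from .types import OmicsMatrix
from .variants import burden_group, filter_deepseq, flag_subclonal, pathway_burden

log = logging.getLogger("icfuse")


@dataclass
class ClusteringOutputs:
    fused: AffinityMatrix
    fused_result: ConsensusResult
    per_layer_results: dict[str, ConsensusResult]
    labels: pd.Series               # sample -> "IC<j>" in cluster order


def cluster_cohort(
    expression: OmicsMatrix,
    methylation: OmicsMatrix,
    config: AnalysisConfig,
    batch=None,
    per_layer: bool = True,
) -> ClusteringOutputs:
    """Preprocess both layers, fuse, and consensus-cluster.

    Also consensus-clusters each single-layer affinity when `per_layer` is
    set, so the dual-omics gain in resolution can be inspected.
    """
    expr = prepare_layer_for_clustering(expression, config.preprocess.n_top_genes)
    meth = prepare_layer_for_clustering(
        methylation, config.preprocess.n_top_probes, batch=batch
    )
    w_expr = build_affinity(expr, config.snf)
    w_meth = build_affinity(meth, config.snf)
    fused = snf_fuse([w_expr, w_meth], config.snf)
    fused_result = run_consensus(fused.values, config.consensus)
    per_layer_results = {}
    if per_layer:
        per_layer_results["expression"] = run_consensus(
            w_expr.values, config.consensus
        )
        per_layer_results["methylation"] = run_consensus(
            w_meth.values, config.consensus
        )
    labels = pd.Series(
        [f"IC{l + 1}" for l in fused_result.labels],
        index=fused.sample_ids, name="cluster",
    )
    return ClusteringOutputs(fused, fused_result, per_layer_results, labels)


def stacked_features(expression: OmicsMatrix, methylation: OmicsMatrix,
                     config: AnalysisConfig, batch=None) -> pd.DataFrame:
    """Concatenate the two preprocessed layers for classifier training."""
    expr = prepare_layer_for_clustering(expression, config.preprocess.n_top_genes)
    meth = prepare_layer_for_clustering(
        methylation, config.preprocess.n_top_probes, batch=batch
    )
    return pd.concat([expr.values, meth.values], axis=0)


def prepare_query_features(
    expression: OmicsMatrix,
    methylation: OmicsMatrix,
    train_features: pd.DataFrame,
    batch=None,
) -> pd.DataFrame:
    """Build a query feature matrix aligned to a trained feature panel.

    Methylation betas are converted to M-values (with the query cohort's
    own batch term removed when given), the two layers are stacked, rows
    are restricted to the training panel, and each feature is z-scored
    within the query cohort (the classifier is translation/scale sensitive,
    so each cohort is standardized on its own, as one would for an external
    validation set).
    """
    from .preprocess import beta_m_convert, remove_batch_effect

    meth = beta_m_convert(methylation, "beta_to_m")
    if batch is not None:
        meth = remove_batch_effect(meth, batch)
    stacked = pd.concat([expression.values, meth.values], axis=0)
    q = stacked.loc[train_features.index]
    mean = q.mean(axis=1).to_numpy()[:, None]
    sd = q.std(axis=1, ddof=0).to_numpy()[:, None]
    return (q - mean) / np.where(sd == 0, 1.0, sd)


def transfer_labels(
    train_features: pd.DataFrame,
    train_labels: pd.Series,
    query_features: pd.DataFrame,
    config: AnalysisConfig,
    fixed: tuple[int, int] | None = None,
) -> dict:
    """Grid-search (or use a fixed) KNN model and classify a query cohort."""
    X = train_features.to_numpy(dtype=float)
    feats = [str(f) for f in train_features.index]
    y = train_labels.loc[train_features.columns].to_numpy()
    if fixed is None:
        (K, n_feat), table = grid_search(X, y, config.knn)
    else:
        K, n_feat = fixed
        table = None
    model = TrainedKNN.fit(X, y, feats, K=K, n_features=n_feat)
    Q = align_query(model, query_features)
    preds, votes = knn_predict(model, Q)
    return {
        "K": K, "n_features": n_feat, "grid_table": table,
        "predictions": pd.Series(preds, index=query_features.columns),
        "votes": votes, "model": model,
    }


def burden_analysis(bundle: CohortBundle, config: AnalysisConfig) -> dict:
    """Deep-seq filtering, subclonality, RTK-RAS burden and survival strata."""
    passed, reasons = filter_deepseq(bundle.variants, config.deepseq_filter)
    sub = flag_subclonal(passed, config.deepseq_filter.subclonal_vaf)
    case_ids = [r.case_id for r in bundle.clinical]
    burden = pathway_burden(passed, config.pathway, case_ids)
    groups = {c: burden_group(b) for c, b in burden.items()}
    efs = efs_from_clinical(bundle.clinical)
    efs["burden_group"] = [groups[c] for c in efs.index]
    hn = efs[efs["burden_group"].isin(["high", "none"])]
    logrank_high_none = (
        logrank_test(hn["time"], hn["event"], hn["burden_group"])
        if hn["event"].any() and hn["burden_group"].nunique() == 2 else None
    )
    burden_s = pd.Series(burden)
    cluster_of = pd.Series({r.case_id: r.cluster_label for r in bundle.clinical})
    return {
        "passed": passed,
        "fail_reasons": reasons,
        "subclonal_fraction": float(np.mean(sub)) if sub else float("nan"),
        "burden": burden_s,
        "burden_groups": pd.Series(groups),
        "mean_burden_by_cluster": burden_s.groupby(cluster_of).mean(),
        "altered_fraction": float((burden_s > 0).mean()),
        "efs_by_burden": efs,
        "logrank_high_vs_none": logrank_high_none,
    }


def survival_analysis(bundle: CohortBundle, labels: pd.Series | None = None,
                      ref_group: str | None = None) -> dict:
    """EFS log-rank across clusters and a multivariate Cox model."""
    clinical = bundle.clinical
    efs = efs_from_clinical(clinical)
    if labels is not None:
        efs["group"] = labels.loc[efs.index].to_numpy()
    lr = logrank_test(efs["time"], efs["event"], efs["group"])
    cov = pd.DataFrame({
        "cluster": efs["group"],
        "age_months": [r.age_months for r in clinical],
        "log_wbc": np.log10([r.wbc for r in clinical]),
        "sex_male": [float(r.sex == "M") for r in clinical],
        "cns": [float(r.cns_involved) for r in clinical],
    }, index=efs.index)
    if ref_group is None:
        # reference = worst-prognosis cluster (highest event fraction),
        # matching the study's choice of its most refractory subgroup
        ref_group = str(efs.groupby("group")["event"].mean().idxmax())
    design = expand_covariates(cov, categorical={"cluster": ref_group})
    cox = cox_ph_fit(efs["time"].to_numpy(), efs["event"].to_numpy(), design)
    return {"efs": efs, "logrank": lr, "cox": cox, "cox_reference": ref_group}


def run_all(sim_config: SimulationConfig | None = None,
            config: AnalysisConfig | None = None) -> dict:
    """Simulate a cohort and run the full analysis on it."""
    sim_config = sim_config or SimulationConfig()
    config = config or AnalysisConfig()
    config.consensus.seed = config.seed
    bundle = simulate_cohort(sim_config)
    clustering = cluster_cohort(bundle.expression, bundle.methylation, config,
                                batch=bundle.batch)
    burden = burden_analysis(bundle, config)
    surv = survival_analysis(bundle, labels=bundle.labels)
    return {
        "bundle": bundle,
        "clustering": clustering,
        "burden": burden,
        "survival": surv,
    }
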