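"""Feature selection, scaling, beta/M conversion, batch removal and QC.

The clustering branch of the pipeline follows the order: MAD-rank feature
selection (top 200 genes / top 1000 probes), then per-feature z-scoring,
then Euclidean distances. Methylation statistics are computed on M-values
(logit-2 of beta) while effect sizes are reported on the beta scale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import Layer, OmicsMatrix, ValidationError

log = logging.getLogger("icfuse")

_EPS_BETA = 1e-6


def mad_rank_select(matrix: OmicsMatrix, n: int) -> OmicsMatrix:
    """Keep the n features with largest median absolute deviation.

    The MAD is the raw median of |x - median(x)| (no consistency constant —
    only ranks matter). Ties are broken by input feature order.
    """
    if n > matrix.shape[0]:
        raise ValidationError(
            f"cannot select {n} features from {matrix.shape[0]}"
        )
    X = matrix.to_numpy()
    med = np.median(X, axis=1, keepdims=True)
    mad = np.median(np.abs(X - med), axis=1)
    # stable sort on -mad keeps input order among ties
    order = np.argsort(-mad, kind="stable")[:n]
    order = np.sort(order)  # preserve input feature order in the output
    return OmicsMatrix(matrix.values.iloc[order], matrix.layer)


def zscore_features(matrix: OmicsMatrix) -> OmicsMatrix:
    """Standardize every feature to mean 0, sd 1 (population denominator)."""
    X = matrix.to_numpy()
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)  # ddof=0: scale cancels in distances
    zero = np.flatnonzero(sd.ravel() == 0)
    if zero.size:
        raise ValidationError(
            f"zero-variance feature: {matrix.feature_ids[zero[0]]!r}"
        )
    Z = (X - mean) / sd
    return OmicsMatrix(
        pd.DataFrame(Z, index=matrix.values.index, columns=matrix.values.columns),
        matrix.layer,
    )


def beta_m_convert(matrix: OmicsMatrix, direction: str) -> OmicsMatrix:
    """Convert beta <-> M methylation scales.

    M = log2(beta / (1 - beta)); beta = 2^M / (1 + 2^M). Betas are clipped
    to [1e-6, 1 - 1e-6] before the logit (clipping logged).
    """
    X = matrix.to_numpy()
    if direction == "beta_to_m":
        if matrix.layer is not Layer.METHYLATION_BETA:
            raise ValidationError("beta_to_m expects a methylation_beta matrix")
        n_clip = int(((X < _EPS_BETA) | (X > 1 - _EPS_BETA)).sum())
        if n_clip:
            log.info("beta_m_convert: clipped %d beta values to [%g, %g]",
                     n_clip, _EPS_BETA, 1 - _EPS_BETA)
        B = np.clip(X, _EPS_BETA, 1 - _EPS_BETA)
        out = np.log2(B / (1 - B))
        layer = Layer.METHYLATION_M
    elif direction == "m_to_beta":
        if matrix.layer is Layer.METHYLATION_BETA:
            raise ValidationError("m_to_beta expects an M-value matrix")
        out = np.exp2(X) / (1 + np.exp2(X))
        layer = Layer.METHYLATION_BETA
    else:
        raise ValueError("direction must be 'beta_to_m' or 'm_to_beta'")
    return OmicsMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        layer,
    )


def remove_batch_effect(matrix: OmicsMatrix, batch) -> OmicsMatrix:
    """Subtract the per-feature batch component (sum-to-zero coding).

    For each feature a least-squares fit value ~ intercept + batch is
    computed and the fitted batch deviations (batch mean minus grand
    batch-mean average) are subtracted, preserving the grand mean. With a
    single batch the transform is the identity.
    """
    batch = np.asarray(batch)
    if batch.shape[0] != matrix.shape[1]:
        raise ValidationError("batch vector length must equal sample count")
    levels, inverse = np.unique(batch, return_inverse=True)
    if levels.size == 1:
        return matrix.copy()
    counts = np.bincount(inverse)
    if counts.min() < 2:
        bad = levels[np.argmin(counts)]
        raise ValidationError(
            f"batch {bad!r} has a single sample; effect confounded"
        )
    X = matrix.to_numpy()
    # per-feature batch means, then sum-to-zero deviations
    sums = np.zeros((X.shape[0], levels.size))
    for b in range(levels.size):
        sums[:, b] = X[:, inverse == b].mean(axis=1)
    dev = sums - sums.mean(axis=1, keepdims=True)
    out = X - dev[:, inverse]
    return OmicsMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        matrix.layer,
    )


def filter_low_expression(
    tpm: pd.DataFrame,
    all_threshold: float = 1.0,
    mean_threshold: float = 0.5,
    chromosomes: pd.Series | None = None,
    sex_chromosomes: tuple[str, ...] = ("X", "Y", "chrX", "chrY"),
) -> list[str]:
    """Return genes surviving the low-expression rules.

    A gene is removed iff all samples have TPM < `all_threshold` or its mean
    TPM < `mean_threshold`. When a chromosome annotation is supplied, genes
    on sex chromosomes are removed as well.
    """
    if (tpm.to_numpy() < 0).any():
        raise ValidationError("TPM values must be non-negative")
    arr = tpm.to_numpy()
    low_all = (arr < all_threshold).all(axis=1)
    low_mean = arr.mean(axis=1) < mean_threshold
    keep = ~(low_all | low_mean)
    if chromosomes is not None:
        sex = tpm.index.map(lambda g: str(chromosomes.get(g, "")) in sex_chromosomes)
        keep &= ~np.asarray(sex, dtype=bool)
    return [str(g) for g in tpm.index[keep]]


def filter_cells(
    counts: pd.DataFrame,
    mito_genes: list[str],
    min_counts: int = 1000,
    min_genes: int = 500,
    max_genes: int = 3000,
    max_mito_frac: float = 0.15,
    min_cells_per_gene: int = 10,
) -> tuple[list[str], list[str]]:
    """Single-cell QC: remove failing cells first, then unreliable genes.

    `counts` is genes x cells (integer UMI counts). Cells with < min_counts
    total counts, < min_genes or > max_genes detected genes, or a
    mitochondrial count fraction above max_mito_frac are removed. Genes
    detected in fewer than min_cells_per_gene of the surviving cells, and
    mitochondrial genes, are then removed.
    """
    arr = counts.to_numpy()
    mito_mask = counts.index.isin(mito_genes)
    total = arr.sum(axis=0)
    detected = (arr > 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, arr[mito_mask].sum(axis=0) / np.maximum(total, 1), 1.0)
    cell_keep = (
        (total >= min_counts)
        & (detected >= min_genes)
        & (detected <= max_genes)
        & (mito_frac <= max_mito_frac)
    )
    kept_cells = [str(c) for c in counts.columns[cell_keep]]
    sub = arr[:, cell_keep]
    gene_keep = ((sub > 0).sum(axis=1) >= min_cells_per_gene) & ~mito_mask
    kept_genes = [str(g) for g in counts.index[gene_keep]]
    log.info("cell QC: kept %d/%d cells, %d/%d genes",
             len(kept_cells), counts.shape[1], len(kept_genes), counts.shape[0])
    return kept_cells, kept_genes


def prepare_layer_for_clustering(
    matrix: OmicsMatrix,
    n_top: int,
    batch=None,
) -> OmicsMatrix:
    """Standard pre-integration chain for one omics layer.

    Methylation betas are first converted to M-values; an optional batch
    vector is regressed out (additive, per feature); then MAD-rank selection
    of the top `n_top` features and per-feature z-scoring.
    """
    if matrix.layer is Layer.METHYLATION_BETA:
        matrix = beta_m_convert(matrix, "beta_to_m")
    if batch is not None:
        matrix = remove_batch_effect(matrix, batch)
    matrix = mad_rank_select(matrix, n_top)
    return zscore_features(matrix)
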