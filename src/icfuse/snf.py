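"""Similarity network fusion of per-layer sample affinity networks.

Each omics layer yields a sample-to-sample Euclidean distance matrix that is
converted to a Gaussian-density affinity with a locally adaptive scale, and
the per-layer networks are merged by iterative cross-diffusion: each layer's
full transition matrix is repeatedly propagated through its own sparse
K-nearest-neighbor kernel against the average of the other layers. The
kernel form and update schedule follow the reference SNF construction
(alpha = 0.5, K = 10, t = 20 by default).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import SNFParams
from .types import OmicsMatrix, ValidationError

log = logging.getLogger("icfuse")

_EPS = 1e-12


class AffinityMatrix:
    """Symmetric non-negative n x n sample similarity matrix."""

    def __init__(self, values: pd.DataFrame):
        arr = values.to_numpy(dtype=float)
        if arr.shape[0] != arr.shape[1]:
            raise ValidationError("affinity matrix must be square")
        if not np.isfinite(arr).all():
            raise ValidationError("affinity matrix contains non-finite values")
        if np.abs(arr - arr.T).max() > 1e-10:
            raise ValidationError("affinity matrix not symmetric within 1e-10")
        if arr.min() < 0:
            raise ValidationError("affinity matrix has negative entries")
        self.values = values

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def euclidean_distance_matrix(matrix: OmicsMatrix) -> pd.DataFrame:
    """Pairwise sample Euclidean distances (samples are columns)."""
    X = matrix.to_numpy().T  # samples x features
    sq = np.sum(X**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * X @ X.T
    np.maximum(d2, 0, out=d2)
    D = np.sqrt(d2)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2
    ids = matrix.sample_ids
    return pd.DataFrame(D, index=ids, columns=ids)


def affinity_kernel(D: pd.DataFrame, params: SNFParams) -> AffinityMatrix:
    """Gaussian-density affinity with locally adaptive scale.

    eps(i, j) = (mean distance from i to its K nearest neighbors
                 + same for j + D(i, j)) / 3, and
    W(i, j) = N(D(i, j); 0, (alpha * eps)^2) — i.e. the normal density with
    standard deviation alpha * eps evaluated at the distance. The result is
    symmetrized as (W + W^T) / 2. A floor of 1e-12 guards degenerate
    all-duplicate neighborhoods.
    """
    arr = D.to_numpy(dtype=float)
    n = arr.shape[0]
    params.validate(n_samples=n)
    # mean distance to K nearest neighbors, self excluded
    sorted_rows = np.sort(arr, axis=1)[:, 1:params.K + 1]
    mu = sorted_rows.mean(axis=1)
    eps = (mu[:, None] + mu[None, :] + arr) / 3.0
    if (eps <= 0).any():
        log.warning("affinity_kernel: %d zero scales floored at %g",
                    int((eps <= 0).sum()), _EPS)
    eps = np.maximum(eps, _EPS)
    sigma = params.alpha * eps
    W = np.exp(-(arr**2) / (2 * sigma**2)) / (np.sqrt(2 * np.pi) * sigma)
    W = (W + W.T) / 2
    return AffinityMatrix(pd.DataFrame(W, index=D.index, columns=D.columns))


def full_kernel_normalize(W: np.ndarray) -> np.ndarray:
    """Row-stochastic full kernel: P(i,i) = 1/2, off-diagonal mass = 1/2."""
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    row = off.sum(axis=1)
    if (row <= 0).any():
        bad = int(np.flatnonzero(row <= 0)[0])
        raise ValidationError(f"row {bad} has no off-diagonal affinity mass")
    P = off / (2 * row[:, None])
    np.fill_diagonal(P, 0.5)
    return P


def local_kernel(W: np.ndarray, K: int) -> np.ndarray:
    """Sparse kernel restricted to each sample's K nearest neighbors.

    Neighbors are ranked by affinity descending with self excluded; ties at
    the K-th neighbor are resolved toward the lower sample index. Rows are
    normalized to sum to one over the retained entries.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if K >= n:
        raise ValidationError("local kernel requires K < n")
    S = np.zeros_like(W)
    masked = W.copy()
    np.fill_diagonal(masked, -np.inf)  # exclude self
    for i in range(n):
        order = np.argsort(-masked[i], kind="stable")[:K]
        s = W[i, order].sum()
        S[i, order] = W[i, order] / max(s, _EPS)
    return S


def snf_fuse(layers: list[AffinityMatrix], params: SNFParams) -> AffinityMatrix:
    """Fuse >= 2 per-layer affinity networks by iterative cross-diffusion.

    P_v is initialized with the full kernel, S_v fixed from the initial W_v;
    for t iterations P_v <- S_v (mean of other layers' P) S_v^T followed by
    re-normalization. The final network is the layer average, symmetrized,
    with the diagonal reset by one more full-kernel normalization.
    """
    if len(layers) < 2:
        raise ValidationError("fusion requires at least two layers")
    ids = layers[0].sample_ids
    for layer in layers[1:]:
        if layer.sample_ids != ids:
            raise ValidationError("all layers must share sample ids and order")
    Ws = [l.to_numpy() for l in layers]
    Ps = [full_kernel_normalize(W) for W in Ws]
    Ss = [local_kernel(W, params.K) for W in Ws]
    m = len(Ws)
    for _ in range(params.t):
        new = []
        for v in range(m):
            others = sum(Ps[u] for u in range(m) if u != v) / (m - 1)
            new.append(Ss[v] @ others @ Ss[v].T)
        Ps = [full_kernel_normalize(P) for P in new]
    fused = sum(Ps) / m
    fused = (fused + fused.T) / 2
    fused = full_kernel_normalize(fused)
    fused = (fused + fused.T) / 2
    return AffinityMatrix(pd.DataFrame(fused, index=ids, columns=ids))


def build_affinity(matrix: OmicsMatrix, params: SNFParams) -> AffinityMatrix:
    """Distance + kernel in one step for a preprocessed (z-scored) layer."""
    return affinity_kernel(euclidean_distance_matrix(matrix), params)
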