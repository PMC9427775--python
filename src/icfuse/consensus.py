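"""Subsampled spectral consensus clustering and stability-based model choice.

For each candidate cluster number k, the fused similarity network is
repeatedly subsampled (80% of samples without replacement), each subsample
is spectral-clustered, and the consensus matrix records how often each
sample pair co-clusters among the runs in which both were drawn. Three
stability metrics — the cophenetic correlation of the consensus dendrogram,
the proportion of ambiguous clustering (PAC), and the mean silhouette width
of the final cut — are combined by mean rank to choose k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.linalg import eigh
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr, rankdata
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

from .config import ConsensusParams
from .types import ValidationError

log = logging.getLogger("icfuse")


def canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..k-1 in order of first occurrence."""
    labels = np.asarray(labels)
    mapping: dict = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def spectral_cluster(S: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Normalized-Laplacian spectral clustering of a similarity matrix.

    Embeds samples with the top-k eigenvectors of D^(-1/2) S D^(-1/2),
    row-normalizes the embedding, and runs seeded k-means with 10 restarts.
    Labels are canonicalized to first-occurrence order.
    """
    S = np.asarray(S, dtype=float)
    n = S.shape[0]
    if k > n:
        raise ValidationError(f"k={k} exceeds n={n}")
    if k < 2:
        raise ValidationError("k must be >= 2")
    deg = S.sum(axis=1)
    if (deg <= 0).any():
        log.warning("spectral_cluster: isolated sample(s); degree floored")
        deg = np.maximum(deg, 1e-12)
    d = 1.0 / np.sqrt(deg)
    M = S * d[:, None] * d[None, :]
    M = (M + M.T) / 2
    _, vecs = eigh(M, subset_by_index=(n - k, n - 1))
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    U = vecs / np.maximum(norms, 1e-12)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return canonical_labels(km.fit_predict(U))


def pac(M: np.ndarray, lower: float = 0.1, upper: float = 0.9) -> float:
    """Proportion of strictly off-diagonal entries strictly inside (u1, u2)."""
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    mask = ~np.eye(n, dtype=bool)
    vals = M[mask]
    return float(np.mean((vals > lower) & (vals < upper)))


def cophenetic_coefficient(M: np.ndarray, method: str = "average") -> float:
    """Cophenetic correlation of the dendrogram built on 1 - M.

    Pearson correlation between the dendrogram's cophenetic distances and
    the input distances over upper-triangle pairs. Returns NaN (logged) when
    the distances have zero variance.
    """
    M = np.asarray(M, dtype=float)
    if M.shape[0] < 3:
        raise ValidationError("cophenetic coefficient requires n >= 3")
    D = 1.0 - M
    np.fill_diagonal(D, 0.0)
    condensed = squareform(D, checks=False)
    Z = linkage(condensed, method=method)
    coph = cophenet(Z)
    if np.std(condensed) == 0 or np.std(coph) == 0:
        log.warning("cophenetic_coefficient: zero-variance distances")
        return float("nan")
    return float(pearsonr(condensed, coph)[0])


def silhouette(Mdist: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width on a precomputed distance matrix.

    Singleton clusters contribute s(i) = 0 (scikit-learn convention).
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValidationError("silhouette requires >= 2 clusters")
    D = np.asarray(Mdist, dtype=float).copy()
    np.fill_diagonal(D, 0.0)
    return float(np.mean(silhouette_samples(D, labels, metric="precomputed")))


@dataclass
class KResult:
    k: int
    consensus_matrix: np.ndarray
    labels: np.ndarray
    cophenetic: float
    pac: float
    mean_silhouette: float
    degenerate: bool = False


@dataclass
class ConsensusResult:
    per_k: dict[int, KResult]
    chosen_k: int = 0
    sample_ids: list[str] = field(default_factory=list)

    @property
    def labels(self) -> np.ndarray:
        return self.per_k[self.chosen_k].labels

    def metrics_frame(self) -> pd.DataFrame:
        rows = [
            {"k": r.k, "cophenetic": r.cophenetic, "pac": r.pac,
             "mean_silhouette": r.mean_silhouette, "degenerate": r.degenerate}
            for r in self.per_k.values()
        ]
        return pd.DataFrame(rows).set_index("k")


def _correlation_distance(M: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between consensus-matrix rows, guarded."""
    X = np.asarray(M, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    safe = np.maximum(norms, 1e-12)
    C = (Xc @ Xc.T) / np.outer(safe, safe)
    D = 1.0 - np.clip(C, -1.0, 1.0)
    # constant rows: undefined correlation -> maximal distance, 0 to itself
    const = norms < 1e-12
    if const.any():
        D[const, :] = 1.0
        D[:, const] = 1.0
        D[np.ix_(const, const)] = 0.0
    np.fill_diagonal(D, 0.0)
    return D


def run_consensus(S: pd.DataFrame, params: ConsensusParams) -> ConsensusResult:
    """Consensus-cluster a similarity matrix over the configured k range."""
    params.validate()
    arr = S.to_numpy(dtype=float) if isinstance(S, pd.DataFrame) else np.asarray(S, float)
    ids = [str(c) for c in S.columns] if isinstance(S, pd.DataFrame) else [
        str(i) for i in range(arr.shape[0])
    ]
    n = arr.shape[0]
    size = int(np.ceil(params.p_item * n))
    rng = np.random.default_rng(params.seed)
    result = ConsensusResult(per_k={}, sample_ids=ids)
    for k in params.k_range:
        if k > size:
            log.warning("run_consensus: skipping k=%d > subsample size %d", k, size)
            continue
        co_cluster = np.zeros((n, n))
        co_sample = np.zeros((n, n))
        for rep in range(params.reps):
            idx = np.sort(rng.choice(n, size=size, replace=False))
            sub = arr[np.ix_(idx, idx)]
            labels = spectral_cluster(sub, k, seed=int(rng.integers(2**31 - 1)))
            co_sample[np.ix_(idx, idx)] += 1
            same = labels[:, None] == labels[None, :]
            co_cluster[np.ix_(idx, idx)] += same
        never = co_sample == 0
        if never.sum() > n:  # off-diagonal pairs never co-drawn
            log.info("run_consensus: k=%d: %d pairs never co-sampled",
                     k, int((never.sum() - n) // 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(never, 0.0, co_cluster / np.maximum(co_sample, 1))
        np.fill_diagonal(M, 1.0)
        M = (M + M.T) / 2
        # final cut: agglomerative clustering of consensus rows
        D = _correlation_distance(M) if params.row_distance == "pearson" else 1.0 - M
        np.fill_diagonal(D, 0.0)
        Z = linkage(squareform(D, checks=False), method=params.final_linkage)
        labels = canonical_labels(fcluster(Z, t=k, criterion="maxclust"))
        degenerate = len(np.unique(labels)) < k
        if degenerate:
            log.warning("run_consensus: k=%d produced an empty cluster", k)
            result.per_k[k] = KResult(k, M, labels, cophenetic=-1.0, pac=1.0,
                                      mean_silhouette=-1.0, degenerate=True)
            continue
        result.per_k[k] = KResult(
            k=k,
            consensus_matrix=M,
            labels=labels,
            cophenetic=cophenetic_coefficient(M, method=params.final_linkage),
            pac=pac(M, params.pac_lower, params.pac_upper),
            mean_silhouette=silhouette(1.0 - M, labels),
        )
    result.chosen_k = select_k(result)
    return result


def select_k(result: ConsensusResult, tol_decimals: int = 2) -> int:
    """Pick k by best mean rank across the three stability metrics.

    Cophenetic and silhouette rank high-good, PAC low-good; metrics are
    quantized to `tol_decimals` decimals first, since stability differences
    below that resolution are resampling noise at the configured rep
    counts. When several k tie for the best mean rank the largest tied k —
    the finest equally-stable partition — is chosen: coarse splits of a
    hierarchically structured cohort are trivially stable, so the finest
    solution among the maximally stable ones is the informative one. A tie
    spanning the whole candidate range (fully degenerate input) falls back
    to the smallest k. NaN metrics are assigned the worst rank.
    """
    ks = sorted(result.per_k)
    if len(ks) < 2:
        return ks[0] if ks else 0
    coph = np.array([result.per_k[k].cophenetic for k in ks])
    sil = np.array([result.per_k[k].mean_silhouette for k in ks])
    p = np.array([result.per_k[k].pac for k in ks])
    coph = np.round(np.where(np.isnan(coph), -2.0, coph), tol_decimals)
    sil = np.round(np.where(np.isnan(sil), -2.0, sil), tol_decimals)
    p = np.round(np.where(np.isnan(p), 2.0, p), tol_decimals)
    ranks = (
        rankdata(-coph, method="average")
        + rankdata(-sil, method="average")
        + rankdata(p, method="average")
    ) / 3.0
    best = np.flatnonzero(np.abs(ranks - ranks.min()) < 1e-9)
    if best.size == len(ks):
        return int(ks[0])
    return int(ks[best[-1]])
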