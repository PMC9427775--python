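"""Independent brute-force reference implementations.

Every function here is written as a direct, loop-based transcription of the
mathematical definition it checks, deliberately sharing no code with the
package (scipy/sklearn shortcuts are avoided). They are slow and only meant
for tiny instances.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import norm


# ---------------------------------------------------------------------------
# SNF kernels
# ---------------------------------------------------------------------------

def affinity_oracle(D: np.ndarray, K: int, alpha: float) -> np.ndarray:
    n = D.shape[0]
    mu = np.empty(n)
    for i in range(n):
        others = sorted(D[i, j] for j in range(n) if j != i)
        mu[i] = sum(others[:K]) / K
    W = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            eps = max((mu[i] + mu[j] + D[i, j]) / 3.0, 1e-12)
            sigma = alpha * eps
            W[i, j] = math.exp(-D[i, j] ** 2 / (2 * sigma**2)) / (
                math.sqrt(2 * math.pi) * sigma
            )
    return (W + W.T) / 2


def full_normalize_oracle(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    P = np.empty((n, n))
    for i in range(n):
        row = sum(W[i, k] for k in range(n) if k != i)
        for j in range(n):
            P[i, j] = 0.5 if i == j else W[i, j] / (2 * row)
    return P


def local_oracle(W: np.ndarray, K: int) -> np.ndarray:
    n = W.shape[0]
    S = np.zeros((n, n))
    for i in range(n):
        neighbors = sorted(
            (j for j in range(n) if j != i), key=lambda j: (-W[i, j], j)
        )[:K]
        total = sum(W[i, j] for j in neighbors)
        for j in neighbors:
            S[i, j] = W[i, j] / total
    return S


def euclidean_oracle(X: np.ndarray) -> np.ndarray:
    """X: features x samples."""
    n = X.shape[1]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = math.sqrt(sum((X[f, i] - X[f, j]) ** 2
                                    for f in range(X.shape[0])))
    return D


# ---------------------------------------------------------------------------
# enrichment walks
# ---------------------------------------------------------------------------

def gsva_oracle(X: np.ndarray, gene_names: list[str],
                sets: dict[str, list[str]], tau: float = 1.0,
                bandwidth_factor: float = 4.0, mx_diff: bool = True
                ) -> dict[str, list[float]]:
    """Explicit enumeration of the GSVA random walk, sample by sample."""
    G, n = X.shape
    scores = {name: [0.0] * n for name in sets}
    h = [max(np.std(X[g], ddof=1) / bandwidth_factor, 1e-8) for g in range(G)]
    z = np.empty((G, n))
    for g in range(G):
        for j in range(n):
            z[g, j] = sum(norm.cdf((X[g, j] - X[g, k]) / h[g])
                          for k in range(n)) / n
    for j in range(n):
        order = sorted(range(G), key=lambda g: (-z[g, j], g))
        rank_of = {g: p + 1 for p, g in enumerate(order)}
        r = {g: abs(G / 2.0 - rank_of[g]) for g in range(G)}
        for name, members in sets.items():
            member_idx = {gene_names.index(m) for m in members}
            denom = sum(r[g] ** tau for g in member_idx)
            walk, cum, mx, mn = [], 0.0, 0.0, 0.0
            for g in order:
                if g in member_idx:
                    cum += r[g] ** tau / denom
                else:
                    cum -= 1.0 / (G - len(member_idx))
                mx, mn = max(mx, cum), min(mn, cum)
            if mx_diff:
                scores[name][j] = mx + mn
            else:
                scores[name][j] = mx if mx > -mn else mn
    return scores


def preranked_es_oracle(metric: np.ndarray, in_set: np.ndarray) -> float:
    order = sorted(range(len(metric)), key=lambda g: (-metric[g], g))
    m = int(in_set.sum())
    P = len(metric)
    denom = sum(abs(metric[g]) for g in order if in_set[g])
    cum, best, best_abs = 0.0, 0.0, 0.0
    for g in order:
        if in_set[g]:
            cum += (abs(metric[g]) / denom) if denom > 0 else 1.0 / m
        else:
            cum -= 1.0 / (P - m)
        if abs(cum) > best_abs:
            best, best_abs = cum, abs(cum)
    return best


# ---------------------------------------------------------------------------
# clustering metrics
# ---------------------------------------------------------------------------

def average_linkage_cophenetic_oracle(D: np.ndarray) -> np.ndarray:
    """Naive average-linkage agglomeration; returns cophenetic distances."""
    n = D.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))

    def cluster_dist(a: list[int], b: list[int]) -> float:
        return sum(D[i, j] for i in a for j in b) / (len(a) * len(b))

    while len(clusters) > 1:
        keys = sorted(clusters)
        best, pair = None, None
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                d = cluster_dist(clusters[keys[ai]], clusters[keys[bi]])
                if best is None or d < best:
                    best, pair = d, (keys[ai], keys[bi])
        a, b = pair
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return coph


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum()))


def silhouette_oracle(D: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    vals = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            vals.append(0.0)
            continue
        a = sum(D[i, j] for j in own) / len(own)
        b = math.inf
        for lab in set(labels) - {labels[i]}:
            others = [j for j in range(n) if labels[j] == lab]
            b = min(b, sum(D[i, j] for j in others) / len(others))
        vals.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# exact and survival statistics
# ---------------------------------------------------------------------------

def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided exact P by full enumeration of the hypergeometric tables."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x: int) -> float:
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    p_obs = prob(a)
    return sum(prob(x) for x in range(0, c1 + 1)
               if prob(x) <= p_obs * (1 + 1e-9))


def km_oracle(times: np.ndarray, events: np.ndarray):
    """Product-limit estimate; events precede censorings at tied times."""
    order = np.argsort(times, kind="stable")
    times, events = np.asarray(times)[order], np.asarray(events)[order]
    s, out = 1.0, []
    for t in sorted(set(times)):
        at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & events))
        if at_risk > 0 and d > 0:
            s *= 1 - d / at_risk
        out.append((float(t), at_risk, d, s))
    return out


def logrank_2group_oracle(times, events, groups) -> float:
    """Two-group log-rank chi-square by direct O-E tabulation."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    g0 = np.unique(groups)[0]
    O = E = V = 0.0
    for t in sorted(set(times[events])):
        at_risk = times >= t
        n = at_risk.sum()
        n0 = (at_risk & (groups == g0)).sum()
        d = ((times == t) & events).sum()
        d0 = ((times == t) & events & (groups == g0)).sum()
        O += d0
        E += d * n0 / n
        if n > 1:
            V += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
    return float((O - E) ** 2 / V)


def cox_binary_grid_oracle(times, events, x, grid=None) -> float:
    """Single binary covariate, no ties: maximize the partial likelihood."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    x = np.asarray(x, dtype=float)
    if grid is None:
        grid = np.linspace(-5, 5, 200001)

    def log_pl(beta: float) -> float:
        ll = 0.0
        for i in np.flatnonzero(events):
            risk = times >= times[i]
            ll += beta * x[i] - math.log(np.sum(np.exp(beta * x[risk])))
        return ll

    vals = [log_pl(b) for b in grid]
    return float(grid[int(np.argmax(vals))])
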