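"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity by a different route than the library:
local alignment by explicit Gotoh dynamic programming, AUC by exhaustive
pair counting, AUPR by explicit threshold enumeration, PKR by the dense
Kronecker solve, and complete-linkage clustering by naive agglomeration.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_score_dp(a: str, b: str, gap_open: float = 10.0, gap_extend: float = 0.5) -> float:
    """Smith-Waterman with affine gaps by explicit dynamic programming.

    A gap of length L costs gap_open + (L - 1) * gap_extend.
    """
    n, m = len(a), len(b)
    neg = -1e18
    h = np.zeros((n + 1, m + 1))
    e = np.full((n + 1, m + 1), neg)  # gap in a (horizontal)
    f = np.full((n + 1, m + 1), neg)  # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e[i][j] = max(h[i][j - 1] - gap_open, e[i][j - 1] - gap_extend)
            f[i][j] = max(h[i - 1][j] - gap_open, f[i - 1][j] - gap_extend)
            sub = h[i - 1][j - 1] + _BLOSUM62[a[i - 1]][b[j - 1]]
            h[i][j] = max(0.0, sub, e[i][j], f[i][j])
            best = max(best, h[i][j])
    return best


def auc_pair_counting(scores, labels) -> float:
    """AUC as the fraction of positive-negative pairs ranked correctly, ties = 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def aupr_threshold_enumeration(scores, labels) -> float:
    """Area under the PR step curve by enumerating every distinct threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    area = 0.0
    prev_recall = 0.0
    for t in sorted(set(scores.tolist()), reverse=True):
        sel = scores >= t
        tp = int(labels[sel].sum())
        precision = tp / int(sel.sum())
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def pkr_dense_solve(k_c: np.ndarray, k_p: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Solve (K_c (x) K_p + lam I) vec(B) = vec(Y) by materializing the system."""
    n_x, n_y = y.shape
    gram = np.kron(k_c, k_p) + lam * np.eye(n_x * n_y)
    return np.linalg.solve(gram, y.reshape(-1)).reshape(n_x, n_y)


def pkr_predict_naive(beta, k_cross, k_protein) -> np.ndarray:
    """Score pairs by the explicit double sum over training compounds/proteins."""
    n_test = k_cross.shape[0]
    n_panel = k_protein.shape[1]
    n_x, n_y = beta.shape
    out = np.zeros((n_test, n_panel))
    for t in range(n_test):
        for q in range(n_panel):
            s = 0.0
            for i in range(n_x):
                for j in range(n_y):
                    s += beta[i, j] * k_cross[t, i] * k_protein[j, q]
            out[t, q] = s
    return out


def complete_linkage_clusters(sim: np.ndarray, threshold: float) -> list[set[int]]:
    """Naive agglomerative complete linkage on distance 1 - sim, cut at 1 - threshold."""
    n = sim.shape[0]
    dist = 1.0 - sim
    clusters: list[set[int]] = [{i} for i in range(n)]
    cut = 1.0 - threshold
    while len(clusters) > 1:
        best = None
        best_d = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = max(dist[a, b] for a in clusters[i] for b in clusters[j])
                if best_d is None or d < best_d:
                    best_d, best = d, (i, j)
        if best_d is None or best_d > cut:
            break
        i, j = best
        clusters[i] |= clusters[j]
        del clusters[j]
    return clusters
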