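"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive (explicit loops, closed forms) and
shares no code with the implementation under test.
"""

from __future__ import annotations

import math


def pearson_oracle(x, y) -> float:
    """Direct covariance/variance evaluation of the correlation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def nw_affine_score(a: str, b: str, match=2.0, mismatch=-1.0,
                    gap_open=-0.5, gap_extend=-0.1) -> float:
    """Global alignment score, affine gaps (first gap position costs
    gap_open, each further position gap_extend), end gaps penalized."""
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]  # a[i-1] aligned to b[j-1]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a[i-1] vs -)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (- vs b[j-1])
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


def diffusion_oracle(A, LS, MS, eps=1e-11):
    """Explicit two-hop resource-path enumeration of the two-way diffusion.

    Returns the nl x nm score matrix as nested lists, averaging the
    lncRNA-side and miRNA-side passes over both weighted networks.
    """
    nl, nm = len(A), len(A[0])
    A_l = [[sum(LS[i][k] * A[k][j] for k in range(nl)) for j in range(nm)]
           for i in range(nl)]
    A_m = [[sum(A[i][k] * MS[k][j] for k in range(nm)) for j in range(nm)]
           for i in range(nl)]
    for W in (A_l, A_m):
        for i in range(nl):
            for j in range(nm):
                if W[i][j] == 0:
                    W[i][j] = eps

    SS = [[0.0] * nm for _ in range(nl)]
    for W in (A_l, A_m):
        colsum = [sum(W[i][m] for i in range(nl)) for m in range(nm)]
        rowsum = [sum(W[l][j] for j in range(nm)) for l in range(nl)]
        for a in range(nl):
            for b in range(nm):
                # lncRNA-side: a -> m (column share) -> l (row share) -> A[l][b]
                lnc_term = sum(
                    (W[a][m] / colsum[m]) * (W[l][m] / rowsum[l]) * A[l][b]
                    for l in range(nl) for m in range(nm)
                )
                # miRNA-side: b <- l (row share) <- m (column share) <- A[a][m]
                mir_term = sum(
                    A[a][m] * (W[l][m] / colsum[m]) * (W[l][b] / rowsum[l])
                    for l in range(nl) for m in range(nm)
                )
                SS[a][b] += 0.25 * (lnc_term + mir_term)
    return SS


def auc_oracle(pos, neg) -> float:
    """All-pairs comparison count with half-credit ties."""
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def truncated_svd_oracle(A, rank):
    """Rank-truncated reconstruction via the eigendecomposition of A^T A."""
    import numpy as np

    A = np.asarray(A, dtype=float)
    evals, V = np.linalg.eigh(A.T @ A)
    order = np.argsort(evals)[::-1][:rank]
    recon = np.zeros_like(A)
    for k in order:
        if evals[k] <= 1e-12:
            continue
        v = V[:, k]
        u = A @ v / np.sqrt(evals[k])
        recon += np.sqrt(evals[k]) * np.outer(u, v)
    return recon
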