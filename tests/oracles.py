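"""Independent brute-force reference implementations used only by the tests.

Everything here is written as a direct, loop-level transcription of the
defining formulas — deliberately naive and independent of the vectorised
library code it checks.
"""

import numpy as np


def naive_euclidean(X):
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = np.sqrt(sum((X[i, k] - X[j, k]) ** 2 for k in range(X.shape[1])))
    return D


def naive_u_center(D):
    """Line-by-line evaluation of the U-centering formula."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    row = [sum(D[i, j] for j in range(n)) for i in range(n)]
    col = [sum(D[i, j] for i in range(n)) for j in range(n)]
    grand = sum(row)
    U = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                U[i, j] = D[i, j] - (row[i] + col[j]) / (n - 2) + grand / ((n - 1) * (n - 2))
    return U


def naive_inner_product(A, B):
    """Double loop over all i != j."""
    n = A.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                total += A[i, j] * B[i, j]
    return total / (n * (n - 3))


def naive_dcor(X, Y):
    """Full pipeline from raw data matrices, all steps naive."""
    A = naive_u_center(naive_euclidean(X))
    B = naive_u_center(naive_euclidean(Y))
    return naive_inner_product(A, B) / np.sqrt(
        naive_inner_product(A, A) * naive_inner_product(B, B)
    )


def naive_survival_distance(time, status):
    """Exhaustive enumeration over pairs and unique event times."""
    o = np.asarray(time, dtype=float)
    s = np.asarray(status, dtype=int)
    n = o.size
    grid = sorted(set(o[s == 1]))
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            total = 0
            for u in grid:
                total += int(o[j] > u >= o[i]) * int(s[i] == 1)
                total += int(o[i] > u >= o[j]) * int(s[j] == 1)
            D[i, j] = total
    return D


def naive_commensurate(X):
    """Center each column, divide by its sum of |x_i - x_j| over unordered pairs."""
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    out = np.empty_like(X)
    for g in range(m):
        centered = X[:, g] - X[:, g].mean()
        pair_sum = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                pair_sum += abs(centered[i] - centered[j])
        out[:, g] = centered / pair_sum
    return out
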