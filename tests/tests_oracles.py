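"""Independent brute-force oracles shared across the test suite.

Each function recomputes a quantity by a method deliberately different from
the package's implementation (enumeration, naive loops, Kronecker
vectorization) so the two routes can be compared.
"""

import itertools

import numpy as np


def qp_simplex_oracle(v):
    """Exact simplex projection by enumerating KKT active sets."""
    n = len(v)
    for size in range(n, 0, -1):
        for support in itertools.combinations(range(n), size):
            lam = (sum(v[i] for i in support) - 1.0) / size
            if any(v[i] - lam < -1e-12 for i in support):
                continue
            if any(v[j] - lam > 1e-12 for j in range(n) if j not in support):
                continue
            x = np.zeros(n)
            for i in support:
                x[i] = max(v[i] - lam, 0.0)
            return x
    raise AssertionError("no KKT point found")


def kron_solve_oracle(SD, SM, Y, a, b):
    """Sylvester solution via the Kronecker-vectorized linear system."""
    from amvml.solver import laplacian

    q, p = Y.shape
    A = a * laplacian(SD) + np.eye(q)
    B = b * laplacian(SM)
    K = np.kron(np.eye(p), A) + np.kron(B.T, np.eye(q))
    return np.linalg.solve(K, Y.flatten(order="F")).reshape((q, p), order="F")


def gip_oracle(Y, space, prior):
    """Interaction-profile kernel by an explicit double loop."""
    profiles = Y if space == "disease" else Y.T
    n = profiles.shape[0]
    beta = prior / np.mean([(profiles[i] ** 2).sum() for i in range(n)])
    K = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            K[i, j] = np.exp(-beta * ((profiles[i] - profiles[j]) ** 2).sum())
    return K


def functional_oracle(Y, S):
    """Best-match-average miRNA functional similarity by naive loops."""
    q, p = Y.shape
    M = np.eye(p)
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            di = np.flatnonzero(Y[:, i])
            dj = np.flatnonzero(Y[:, j])
            if di.size == 0 or dj.size == 0:
                M[i, j] = 0.0
                continue
            tot = sum(S[a, dj].max() for a in di) + sum(S[b, di].max() for b in dj)
            M[i, j] = tot / (di.size + dj.size)
    return M


def pair_counting_auc(scores, labels):
    """Rank AUC as the fraction of concordant positive-negative pairs."""
    scores, labels = np.asarray(scores), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for s in pos:
        total += (s > neg).sum() + 0.5 * (s == neg).sum()
    return total / (len(pos) * len(neg))
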