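"""Independent reference implementations used to validate the solvers.

These deliberately use different algorithms from the package (proximal
gradient instead of coordinate descent; exhaustive enumeration instead of
vectorized masks) so agreement is meaningful.
"""

from __future__ import annotations

import itertools

import numpy as np


def enet_proximal_gradient(X, y, alpha, lam, tol=1e-12, max_iter=200_000):
    """Elastic net by ISTA (proximal gradient) on the objective
    (1/2n)||y - Xb||^2 + lam*(alpha*||b||_1 + (1-alpha)/2*||b||^2)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    G = Xc.T @ Xc / n
    c = Xc.T @ yc / n
    l2 = lam * (1.0 - alpha)
    l1 = lam * alpha
    L = np.linalg.eigvalsh(G)[-1] + l2  # Lipschitz constant of smooth part
    if L <= 0:
        return np.zeros(p)
    step = 1.0 / L
    b = np.zeros(p)
    for _ in range(max_iter):
        grad = G @ b - c + l2 * b
        z = b - step * grad
        b_new = np.sign(z) * np.maximum(np.abs(z) - step * l1, 0.0)
        if np.max(np.abs(b_new - b)) < tol:
            return b_new
        b = b_new
    return b


def lasso_neighborhood_bruteforce(X, j, lam, tol=1e-12):
    """Node j's lasso neighborhood via the proximal-gradient oracle on
    internally correlation-scaled columns (matching the package's penalty
    convention)."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    sd = np.sqrt((Xc**2).mean(axis=0))
    sd[sd == 0] = 1.0
    Xs = Xc / sd
    others = [k for k in range(X.shape[1]) if k != j]
    beta = enet_proximal_gradient(Xs[:, others], Xs[:, j], 1.0, lam, tol=tol)
    out = np.zeros(X.shape[1])
    out[others] = beta
    return out


def link_count_bruteforce(adj, kingdom, present, pairing):
    """Unordered link count by explicit pair enumeration."""
    p = adj.shape[0]
    total = 0
    for i in range(p):
        for k in range(i + 1, p):
            if not (present[i] and present[k] and adj[i, k]):
                continue
            pair = {kingdom[i], kingdom[k]}
            if pairing == "all":
                total += 1
            elif pairing == "bb" and pair == {"bacteria"}:
                total += 1
            elif pairing == "ff" and pair == {"fungi"}:
                total += 1
            elif pairing == "bf" and pair == {"bacteria", "fungi"}:
                total += 1
    return total


def rao_q_bruteforce(p, d):
    """Rao's quadratic entropy by explicit double sum."""
    q = 0.0
    for i in range(len(p)):
        for j in range(len(p)):
            q += p[i] * p[j] * d[i][j]
    return q


def coverage_bruteforce(supporter_sets, total_taxa, k):
    """Mean union-size proportion over all exhaustive k-subsets."""
    funcs = sorted(supporter_sets)
    vals = []
    for combo in itertools.combinations(funcs, k):
        union = set()
        for f in combo:
            union |= set(supporter_sets[f])
        vals.append(len(union) / total_taxa)
    return float(np.mean(vals)), vals


def sequential_ss_bruteforce(y, design_blocks):
    """Sequential sums of squares via nested least-squares fits (numpy
    only).  ``design_blocks`` is an ordered list of 2-D arrays; returns the
    per-block SS list and the residual SS."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = np.ones((n, 1))
    rss_prev = float(((y - y.mean()) ** 2).sum())
    ss = []
    for block in design_blocks:
        X = np.hstack([X, block])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ beta) ** 2).sum())
        ss.append(rss_prev - rss)
        rss_prev = rss
    return ss, rss_prev
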