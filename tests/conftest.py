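"""Shared fixtures and independent oracles used across the test suite.

The oracles here deliberately avoid the package's own code paths: the
convex-programming oracle minimizes a smoothed surrogate of the nonsmooth
objective with L-BFGS, the affinity oracle scores windows one by one in
pure Python, and the agglomeration oracle is the naive O(k^3) algorithm.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from scipy.optimize import minimize

from sctfa.trees import TaskTree


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# convex-programming oracle (smoothed objective + L-BFGS)


def solve_group_objective_oracle(X, Y, groups, lam, ridge=0.0, mu=1e-12):
    """Minimize RSS + ridge*||B||_F^2 + lam * sum_g w_g ||B[:, G]||_2 per row.

    Uses the smooth surrogate sqrt(||v||^2 + mu) for each group norm (error
    bounded by lam * sum w * p * sqrt(mu)) and L-BFGS; independent of the
    package's proximal-gradient solver.
    """
    n, p = X.shape
    k = Y.shape[1]

    def fun(b):
        B = b.reshape(p, k)
        resid = Y - X @ B
        val = float((resid**2).sum()) + ridge * float((B**2).sum())
        grad = -2.0 * X.T @ resid + 2.0 * ridge * B
        for idx, w in groups:
            sub = B[:, idx]
            norms = np.sqrt((sub**2).sum(axis=1) + mu)
            val += lam * w * float(norms.sum())
            grad[:, idx] += lam * w * sub / norms[:, None]
        return val, grad.ravel()

    res = minimize(
        fun,
        np.zeros(p * k),
        jac=True,
        method="L-BFGS-B",
        options=dict(maxiter=50000, maxfun=200000, ftol=1e-18, gtol=1e-14),
    )
    return res.x.reshape(p, k)


def prox_oracle(v, groups, tau, mu=1e-14):
    """argmin_z 0.5 ||z - v||^2 + tau * sum w ||z[G]||  for one row, smoothed."""
    v = np.asarray(v, dtype=float)

    def fun(z):
        val = 0.5 * float(((z - v) ** 2).sum())
        grad = z - v
        for idx, w in groups:
            norm = math.sqrt(float((z[idx] ** 2).sum()) + mu)
            val += tau * w * norm
            grad[idx] += tau * w * z[idx] / norm
        return val, grad

    res = minimize(fun, np.zeros_like(v), jac=True, method="L-BFGS-B",
                   options=dict(maxiter=20000, ftol=1e-18, gtol=1e-14))
    return res.x


# ---------------------------------------------------------------------------
# statistics oracles


def bh_adjust_oracle(pvals):
    """Textbook Benjamini-Hochberg step-up: adj_(i) = min_{j>=i} m*p_(j)/j, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adjusted[i] = running
    return adjusted


def mannwhitney_exact_oracle(a, b):
    """Exact two-sided Mann-Whitney p by full enumeration of group assignments."""
    a, b = list(a), list(b)
    pooled = a + b
    n1, n2 = len(a), len(b)
    ranks = _average_ranks(pooled)
    u_obs = sum(ranks[: n1]) - n1 * (n1 + 1) / 2.0
    # enumerate every way to assign n1 of the pooled values to group A
    total = 0
    at_least = 0
    mean_u = n1 * n2 / 2.0
    for combo in itertools.combinations(range(n1 + n2), n1):
        u = sum(ranks[i] for i in combo) - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            at_least += 1
    return at_least / total


def _average_ranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    """Spearman rho as the Pearson correlation of average ranks."""
    rx = np.asarray(_average_ranks(list(x)))
    ry = np.asarray(_average_ranks(list(y)))
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))


# ---------------------------------------------------------------------------
# clustering oracle


def complete_linkage_oracle(dissim):
    """Naive O(k^3) complete-linkage agglomeration; returns the merge list.

    Each merge is (cluster_a, cluster_b, height) with scipy's cluster
    numbering (new cluster k + step) and lowest-distance-first selection.
    """
    D = np.asarray(dissim, dtype=float)
    k = D.shape[0]
    clusters = {i: [i] for i in range(k)}
    merges = []
    next_id = k
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = max(D[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merges.append((a, b, d))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return merges


# ---------------------------------------------------------------------------
# affinity oracle


def trap_oracle(sequence, pwm, lambda_trap=0.7, ln_r0=None):
    """Window-by-window, both-strand affinity sum in plain Python."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = len(pwm)
    if ln_r0 is None:
        ln_r0 = pwm.ln_r0()
    probs = pwm.probs
    pmax = probs.max(axis=0)
    seq = sequence.upper()
    total = 0.0
    for start in range(len(seq) - L + 1):
        window = seq[start : start + L]
        if any(b not in base_idx for b in window):
            continue
        for strand_window in (window, "".join(comp[b] for b in reversed(window))):
            energy = sum(
                math.log(pmax[i] / probs[base_idx[strand_window[i]], i]) for i in range(L)
            )
            total += 1.0 / (1.0 + math.exp(energy / lambda_trap - ln_r0))
    return total


# ---------------------------------------------------------------------------
# small tree helpers


def random_binary_tree(k, rng):
    """Random rooted binary tree over k labelled leaves."""
    nodes = list(range(k))
    parents = [None] * k
    next_id = k
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parents.append(None)
        parents[a] = next_id
        parents[b] = next_id
        nodes = [x for x in nodes if x not in (a, b)] + [next_id]
        next_id += 1
    return TaskTree(parents, [f"c{i}" for i in range(k)])
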