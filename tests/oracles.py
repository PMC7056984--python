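"""Independent brute-force oracles used by multiple test modules.

These deliberately reimplement, in the most transparent way possible,
logic the package implements more efficiently: exhaustive reciprocity
checking for ortholog pairs, full-enumeration Mann-Whitney p-values, an
affine-gap alignment DP, and a literal-loop percentile bootstrap.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_force_rbh(fwd_hits, rev_hits, evalue_max=1e-6):
    """Exhaustive double loop over all hit pairs: (a, b) is reported iff no
    forward hit of a beats b and no reverse hit of b beats a, with the
    (evalue asc, bitscore desc, subject asc) ordering, both below the
    ceiling. Multiple HSPs per pair are reduced the same way."""

    def reduce_hsps(hits):
        best = {}
        for h in hits:
            k = (h.query, h.subject)
            if k not in best or (h.evalue, -h.bitscore) < (
                best[k].evalue, -best[k].bitscore
            ):
                best[k] = h
        return list(best.values())

    fwd = reduce_hsps(fwd_hits)
    rev = reduce_hsps(rev_hits)

    def key(h):
        return (h.evalue, -h.bitscore, h.subject)

    pairs = []
    for fh in fwd:
        beaten = any(
            other.query == fh.query and key(other) < key(fh) for other in fwd
        )
        if beaten:
            continue
        for rh in rev:
            if rh.query != fh.subject or rh.subject != fh.query:
                continue
            if any(o.query == rh.query and key(o) < key(rh) for o in rev):
                continue
            if fh.evalue < evalue_max and rh.evalue < evalue_max:
                pairs.append((fh.query, fh.subject))
    return sorted(set(pairs))


def mwu_exact_enumeration(x, y):
    """Two-sided Mann-Whitney p by enumerating all label assignments."""
    x = list(x)
    y = list(y)
    pooled = x + y
    n = len(pooled)
    nx = len(x)

    def u_stat(xs, ys):
        return sum(1 for xi in xs for yj in ys if xi > yj) + 0.5 * sum(
            1 for xi in xs for yj in ys if xi == yj
        )

    u_obs = u_stat(x, y)
    mean_u = nx * len(y) / 2.0
    dev_obs = abs(u_obs - mean_u)
    count = total = 0
    for idx in combinations(range(n), nx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n) if i not in idx]
        if abs(u_stat(xs, ys) - mean_u) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def affine_nw_score(a: str, b: str, matrix, gap_open=-10.0, gap_extend=-0.5):
    """Gotoh affine-gap global alignment score (independent DP)."""
    n, m = len(a), len(b)
    neg = float("-inf")
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (consume a)
    Y = np.full((n + 1, m + 1), neg)  # gap in a (consume b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
    return max(M[n, m], X[n, m], Y[n, m])


def bootstrap_median_ci_oracle(values, n_boot=1000, level=0.95, seed=0):
    """Literal-loop percentile bootstrap using the shared RNG protocol:
    default_rng(seed), one integers(0, n, size=n) draw per replicate."""
    v = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    meds = []
    for _ in range(n_boot):
        idx = rng.integers(0, v.size, size=v.size)
        meds.append(np.median(v[idx]))
    alpha = (1 - level) / 2
    return (
        float(np.median(v)),
        float(np.quantile(meds, alpha)),
        float(np.quantile(meds, 1 - alpha)),
    )
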