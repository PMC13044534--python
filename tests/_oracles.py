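"""Brute-force reference implementations used only to check the package.

Each oracle recomputes a quantity by direct enumeration, independent of the
code paths it validates.
"""

from __future__ import annotations

from itertools import product

import numpy as np


def best_split_partition(values: np.ndarray) -> np.ndarray:
    """Exhaustive 1-D two-class partition minimizing total within-class sum
    of squares: every contiguous cut of the sorted values is scored by
    recomputing both cluster variances from scratch.  Returns a boolean
    high-cluster membership aligned with ``values``."""
    v = np.asarray(values, float)
    s = np.sort(v)
    best_sse, best_cut = np.inf, None
    for k in range(1, len(s)):
        if s[k - 1] == s[k]:
            continue
        left, right = s[:k], s[k:]
        sse = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
        if sse < best_sse:
            best_sse, best_cut = sse, (s[k - 1] + s[k]) / 2.0
    return v > best_cut


def brute_nearest_distances(ref_xy: np.ndarray, tgt_xy: np.ndarray,
                            same_class: bool) -> np.ndarray:
    """O(n*m) per-reference-cell nearest-target distance; self excluded on
    the diagonal."""
    d = np.sqrt(
        ((ref_xy[:, None, :] - tgt_xy[None, :, :]) ** 2).sum(axis=2)
    )
    if same_class:
        np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def weighted_modularity(w: np.ndarray, membership) -> float:
    """Newman weighted modularity computed straight from the definition."""
    membership = np.asarray(membership)
    m2 = w.sum()  # 2m for a symmetric matrix with zero diagonal
    deg = w.sum(axis=1)
    q = 0.0
    n = len(w)
    for i in range(n):
        for j in range(n):
            if membership[i] == membership[j]:
                q += w[i, j] - deg[i] * deg[j] / m2
    return q / m2


def _set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [[first] + block] + smaller[i + 1:]
        yield [[first]] + smaller


def max_modularity_partition(w: np.ndarray) -> tuple[float, list]:
    """Exhaustive weighted-modularity maximization over all set partitions
    (feasible for <= 8 nodes)."""
    n = len(w)
    best_q, best = -np.inf, None
    for part in _set_partitions(list(range(n))):
        membership = np.empty(n, int)
        for c, block in enumerate(part):
            membership[block] = c
        q = weighted_modularity(w, membership)
        if q > best_q:
            best_q, best = q, membership
    return best_q, best


def enumerate_combo_frequencies(pos: np.ndarray, markers) -> dict[tuple, float]:
    """Per-cell enumeration of Boolean marker combinations: walk every cell,
    build its state tuple, count."""
    counts: dict[tuple, int] = {
        combo: 0 for combo in product([True, False], repeat=len(markers))
    }
    for row in np.asarray(pos, bool):
        counts[tuple(row)] += 1
    n = len(pos)
    return {combo: c / n for combo, c in counts.items()}


def mann_whitney_exact_p(a, b) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all C(n_a+n_b, n_a)
    group assignments of the pooled ranks."""
    from itertools import combinations

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    ranks = pooled.argsort().argsort() + 1.0
    na = len(a)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2.0
    u_obs = min(u_obs, len(a) * len(b) - u_obs)
    count = total = 0
    for idx in combinations(range(len(pooled)), na):
        u = ranks[list(idx)].sum() - na * (na + 1) / 2.0
        u = min(u, na * len(b) - u)
        total += 1
        if u <= u_obs:
            count += 1
    return count / total
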