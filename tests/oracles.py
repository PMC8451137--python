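"""Independent brute-force oracles used to check the fast implementations.

Everything here is written as plain loops over the definitions, sharing no
code with the package internals.
"""

from __future__ import annotations

import numpy as np


def oracle_best_split(X, g, h, idx, lam, min_samples_leaf):
    """Exhaustive (feature, threshold) search on the sample subset ``idx``.

    Mirrors the engine's contract: thresholds are the distinct observed
    values (all but the largest); values <= threshold go left; missing
    (NaN) goes to the child with more non-missing samples (tie -> left);
    both children must have >= min_samples_leaf samples. Returns
    (gain, feature, threshold, missing_left) with ties broken by lowest
    feature then lowest threshold; gain is -inf if no valid split exists.
    """
    best = (-np.inf, None, None, True)
    for f in range(X.shape[1]):
        col = X[idx, f]
        miss = np.isnan(col)
        vals = sorted(set(col[~miss].tolist()))
        for thr in vals[:-1]:
            left_nm = [i for i, v in zip(idx, col) if not np.isnan(v) and v <= thr]
            right_nm = [i for i, v in zip(idx, col) if not np.isnan(v) and v > thr]
            missing = [i for i, v in zip(idx, col) if np.isnan(v)]
            missing_left = len(left_nm) >= len(right_nm)
            left = left_nm + (missing if missing_left else [])
            right = right_nm + ([] if missing_left else missing)
            if len(left) < max(min_samples_leaf, 1) \
                    or len(right) < max(min_samples_leaf, 1):
                continue
            GL, HL = g[left].sum(), h[left].sum()
            GR, HR = g[right].sum(), h[right].sum()
            gain = GL**2 / (HL + lam) + GR**2 / (HR + lam) \
                - (GL + GR)**2 / (HL + HR + lam)
            if gain > best[0]:
                best = (gain, f, thr, missing_left)
    return best


def oracle_split_gain(X, g, h, idx, f, thr, lam, min_samples_leaf):
    """Gain of one specific (feature, threshold) split, same rules."""
    col = X[idx, f]
    left_nm = [i for i, v in zip(idx, col) if not np.isnan(v) and v <= thr]
    right_nm = [i for i, v in zip(idx, col) if not np.isnan(v) and v > thr]
    missing = [i for i, v in zip(idx, col) if np.isnan(v)]
    missing_left = len(left_nm) >= len(right_nm)
    left = left_nm + (missing if missing_left else [])
    right = right_nm + ([] if missing_left else missing)
    if len(left) < max(min_samples_leaf, 1) \
            or len(right) < max(min_samples_leaf, 1) \
            or not left_nm or not right_nm:
        return -np.inf
    GL, HL = g[left].sum(), h[left].sum()
    GR, HR = g[right].sum(), h[right].sum()
    return GL**2 / (HL + lam) + GR**2 / (HR + lam) \
        - (GL + GR)**2 / (HL + HR + lam)


def brute_dbscan(X, eps, min_samples):
    """Textbook DBSCAN by direct definition (no indexing tricks).

    A core point has >= min_samples neighbours within eps (itself
    included); clusters are connected components of core points under
    eps-reachability plus their border points. Noise is -1. Label numbering
    follows discovery order over sample index.
    """
    n = len(X)
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    neighbors = [set(np.flatnonzero(d[i] <= eps).tolist()) for i in range(n)]
    core = [len(neighbors[i]) >= min_samples for i in range(n)]
    labels = np.full(n, -1)
    cid = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        stack = [i]
        labels[i] = cid
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for k in neighbors[j]:
                if labels[k] == -1:
                    labels[k] = cid
                    stack.append(k)
        cid += 1
    return labels


def best_two_partition_sse(X):
    """Exhaustive optimal 2-cluster partition by within-cluster SSE (n<=12)."""
    n = len(X)
    best_sse, best_assign = np.inf, None
    for bits in range(1, 2 ** (n - 1)):  # fix sample 0 in cluster 0
        assign = [(bits >> i) & 1 for i in range(n)]
        sse = 0.0
        for c in (0, 1):
            pts = X[[i for i in range(n) if assign[i] == c]]
            if len(pts) == 0:
                sse = np.inf
                break
            sse += ((pts - pts.mean(axis=0)) ** 2).sum()
        if sse < best_sse:
            best_sse, best_assign = sse, assign
    return np.array(best_assign), best_sse


def same_partition(a, b):
    """Two label vectors describe the same partition (up to renaming)."""
    a, b = np.asarray(a), np.asarray(b)
    mapping = {}
    for x, y in zip(a.tolist(), b.tolist()):
        if x in mapping and mapping[x] != y:
            return False
        mapping[x] = y
    return len(set(mapping.values())) == len(mapping)
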