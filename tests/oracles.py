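"""Independent brute-force oracles used by the test suite.

Everything here is computed with explicit loops straight from the defining
formulas, deliberately ignoring the package's vectorized implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def dist(a, b) -> float:
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))


def brute_validity(X, labels) -> dict:
    """All validity indices by direct enumeration (small n only)."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = len(X)
    ids = sorted(set(labels.tolist()))
    k = len(ids)
    members = {c: [i for i in range(n) if labels[i] == c] for c in ids}

    pairs = list(itertools.combinations(range(n), 2))
    d = {(i, j): dist(X[i], X[j]) for i, j in pairs}
    wd = [d[p] for p in pairs if labels[p[0]] == labels[p[1]]]
    bd = [d[p] for p in pairs if labels[p[0]] != labels[p[1]]]

    out = {}
    centroids = {c: X[members[c]].mean(axis=0) for c in ids}
    grand = X.mean(axis=0)

    W = sum(dist(X[i], centroids[c]) ** 2 for c in ids for i in members[c])
    B = sum(len(members[c]) * dist(centroids[c], grand) ** 2 for c in ids)
    if 1 < k < n:
        out["calinski_harabasz"] = (B / (k - 1)) / (W / (n - k)) if W else math.inf

    if k > 1:
        s = {c: np.mean([dist(X[i], centroids[c]) for i in members[c]]) for c in ids}
        out["davies_bouldin"] = np.mean([
            max((s[a] + s[b]) / dist(centroids[a], centroids[b])
                for b in ids if b != a)
            for a in ids])

    if wd and bd:
        s_plus = sum(1 for w in wd for b in bd if w < b)
        s_minus = sum(1 for w in wd for b in bd if w > b)
        if s_plus + s_minus:
            out["bh_gamma"] = (s_plus - s_minus) / (s_plus + s_minus)
        alld = sorted(d.values())
        l = len(wd)
        S, Smin, Smax = sum(wd), sum(alld[:l]), sum(alld[-l:])
        if Smax > Smin:
            out["c_index"] = (S - Smin) / (Smax - Smin)

    if 1 < k < n:
        sil = []
        for i in range(n):
            own = [j for j in members[labels[i]] if j != i]
            if not own:
                sil.append(0.0)
                continue
            a = np.mean([dist(X[i], X[j]) for j in own])
            b = min(np.mean([dist(X[i], X[j]) for j in members[c]])
                    for c in ids if c != labels[i])
            sil.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
        out["silhouette"] = float(np.mean(sil))

    if k > 1 and bd:
        diam = max(wd) if wd else 0.0
        out["dunn"] = math.inf if diam == 0 else min(bd) / diam

    out["membership_entropy"] = -sum(
        (len(members[c]) / n) * math.log(len(members[c]) / n) for c in ids)
    if wd:
        out["avg_within"], out["max_within"] = float(np.mean(wd)), float(max(wd))
    if bd:
        out["avg_between"], out["max_between"] = float(np.mean(bd)), float(max(bd))
    return out


def brute_apn(X, k, clusterer) -> float:
    """APN by the definition: per deleted column, recluster and average the
    per-subject proportion of lost co-cluster members."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    base = clusterer(X, k)
    vals = []
    for col in range(p):
        Xd = np.delete(X, col, axis=1)
        new = clusterer(Xd, k)
        for i in range(n):
            orig = [j for j in range(n) if base[j] == base[i]]
            inter = [j for j in orig if new[j] == new[i]]
            vals.append(1.0 - len(inter) / len(orig))
    return float(np.mean(vals))


def brute_pearson(x, y) -> float:
    """Pearson r from the covariance formula, explicit sums."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def permutation_t_pvalues(X, mask, n_perm, seed) -> np.ndarray:
    """Two-sided permutation p-values for the mean-difference statistic."""
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    obs = np.abs(X[mask].mean(axis=0) - X[~mask].mean(axis=0))
    count = np.zeros(X.shape[1])
    for _ in range(n_perm):
        pm = rng.permutation(mask)
        stat = np.abs(X[pm].mean(axis=0) - X[~pm].mean(axis=0))
        count += stat >= obs - 1e-12
    return (count + 1) / (n_perm + 1)
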