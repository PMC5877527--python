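"""Hierarchical clustering and cluster-validity indices.

Clustering is agglomerative with Euclidean distances and complete linkage
(scipy's implementation behind this module's surface). The validity battery
is computed from first principles: Calinski–Harabasz pseudo-F,
Davies–Bouldin, the Baker–Hubert adaptation of Goodman–Kruskal's gamma, the
Hubert–Levine C-index, mean silhouette width, the Dunn index (single-linkage
separation over maximum diameter), membership entropy, the average/maximal
within- and between-cluster distances, and — as a stability measure — the
average proportion of non-overlap (APN) under leave-one-feature-out
reclustering.

Index orientations: higher is better for CH, gamma, silhouette and Dunn;
lower is better for Davies–Bouldin, C-index and APN. Membership entropy and
the distance summaries are descriptive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist, squareform

#: orientation of every comparable index: +1 higher-better, -1 lower-better
INDEX_ORIENTATION = {
    "calinski_harabasz": +1,
    "davies_bouldin": -1,
    "bh_gamma": +1,
    "c_index": -1,
    "silhouette": +1,
    "dunn": +1,
    "apn": -1,
}
DESCRIPTIVE_INDICES = (
    "membership_entropy", "avg_within", "max_within", "avg_between", "max_between",
)
ALL_INDICES = tuple(INDEX_ORIENTATION) + DESCRIPTIVE_INDICES


@dataclass
class Dendrogram:
    """Complete-linkage merge tree over labelled subjects."""

    Z: np.ndarray
    labels: list

    def cut(self, k: int) -> np.ndarray:
        return cut_k(self, k)

    def to_newick(self) -> str:
        """Export the merge tree as a Newick string (heights as lengths)."""
        tree = to_tree(self.Z)

        def rec(node, parent_h):
            length = parent_h - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_h:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{max(length, 0.0):.6g}"

        return f"({rec(tree.left, tree.dist)},{rec(tree.right, tree.dist)});" \
            if not tree.is_leaf() else f"({self.labels[tree.id]});"


def hclust_complete(X) -> Dendrogram:
    """Agglomerate subjects with Euclidean distance and complete linkage."""
    if isinstance(X, pd.DataFrame):
        labels = list(X.index)
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        labels = list(range(arr.shape[0]))
    if arr.shape[0] < 2:
        raise ValueError("clustering requires at least 2 subjects")
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate subject ids")
    Z = linkage(pdist(arr), method="complete")
    return Dendrogram(Z, labels)


def cut_k(dendrogram: Dendrogram, k: int) -> np.ndarray:
    """Cut the tree into k clusters; ids contiguous 1..k in order of first
    appearance."""
    n = len(dendrogram.labels)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    if k == n:
        return np.arange(1, n + 1)
    raw = fcluster(dendrogram.Z, t=k, criterion="maxclust")
    _, first = np.unique(raw, return_index=True)
    remap = {raw[i]: rank + 1 for rank, i in enumerate(sorted(first))}
    out = np.array([remap[c] for c in raw])
    if out.max() != k:
        raise ValueError(f"could not cut into exactly {k} clusters (tied heights)")
    return out


@dataclass
class ValidityReport:
    """The nine-index quality evaluation of one partition."""

    k: int
    n: int
    indices: dict[str, float]
    undefined: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.indices[name]

    def to_series(self) -> pd.Series:
        return pd.Series(self.indices)


def _check_partition(labels: np.ndarray) -> int:
    ids = np.unique(labels)
    if not np.array_equal(ids, np.arange(1, len(ids) + 1)):
        raise ValueError("cluster ids must be contiguous 1..k")
    return len(ids)


def validity_report(X, labels) -> ValidityReport:
    """Compute every validity index for one partition of X.

    Indices needing both within- and between-cluster structure are reported
    as NaN with a reason when k = 1 or k = n; a zero maximum diameter sends
    the Dunn index to +inf.
    """
    arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = arr.shape[0]
    if labels.shape[0] != n:
        raise ValueError("labels length must match number of subjects")
    k = _check_partition(labels)
    D = squareform(pdist(arr))
    iu = np.triu_indices(n, k=1)
    pair_d = D[iu]
    same = labels[iu[0]] == labels[iu[1]]
    wd, bd = pair_d[same], pair_d[~same]

    idx: dict[str, float] = {}
    undef: dict[str, str] = {}

    def undefined(name, reason):
        idx[name] = math.nan
        undef[name] = reason

    sizes = np.array([(labels == c).sum() for c in range(1, k + 1)])
    centroids = np.stack([arr[labels == c].mean(axis=0) for c in range(1, k + 1)])
    grand = arr.mean(axis=0)

    # Calinski-Harabasz pseudo F
    W = sum(((arr[labels == c] - centroids[c - 1]) ** 2).sum() for c in range(1, k + 1))
    B = float((sizes[:, None] * (centroids - grand) ** 2).sum())
    if k == 1 or k == n:
        undefined("calinski_harabasz", "requires 1 < k < n")
    elif W == 0:
        idx["calinski_harabasz"] = math.inf
    else:
        idx["calinski_harabasz"] = (B / (k - 1)) / (W / (n - k))

    # Davies-Bouldin
    if k == 1:
        undefined("davies_bouldin", "requires k >= 2")
    else:
        s = np.array([
            np.linalg.norm(arr[labels == c] - centroids[c - 1], axis=1).mean()
            for c in range(1, k + 1)])
        ratios = np.zeros(k)
        for i in range(k):
            vals = []
            for j in range(k):
                if i == j:
                    continue
                dij = np.linalg.norm(centroids[i] - centroids[j])
                vals.append(math.inf if dij == 0 else (s[i] + s[j]) / dij)
            ratios[i] = max(vals)
        idx["davies_bouldin"] = float(ratios.mean())

    # Baker-Hubert gamma and Hubert-Levine C-index
    if wd.size == 0 or bd.size == 0:
        undefined("bh_gamma", "requires within and between pairs")
        undefined("c_index", "requires within and between pairs")
    else:
        # s_plus: (within, between) pairs with within < between;
        # s_minus: within > between; ties count for neither.
        bsort = np.sort(bd)
        less = np.searchsorted(bsort, wd, side="left")   # between strictly < within
        upto = np.searchsorted(bsort, wd, side="right")  # between <= within
        s_minus = int(less.sum())
        s_plus = int((bd.size - upto).sum())
        denom = s_plus + s_minus
        if denom == 0:
            undefined("bh_gamma", "all pairwise distances tied")
        else:
            idx["bh_gamma"] = (s_plus - s_minus) / denom
        l = wd.size
        dsort = np.sort(pair_d)
        S = float(wd.sum())
        S_min = float(dsort[:l].sum())
        S_max = float(dsort[-l:].sum())
        if S_max == S_min:
            undefined("c_index", "all pairwise distances tied")
        else:
            idx["c_index"] = (S - S_min) / (S_max - S_min)

    # Silhouette (singletons contribute 0, the usual convention)
    if k == 1 or k == n:
        undefined("silhouette", "requires 1 < k < n")
    else:
        sil = np.zeros(n)
        for i in range(n):
            own = labels == labels[i]
            if own.sum() == 1:
                sil[i] = 0.0
                continue
            a = D[i, own].sum() / (own.sum() - 1)
            b = min(D[i, labels == c].mean() for c in range(1, k + 1) if c != labels[i])
            sil[i] = 0.0 if max(a, b) == 0 else (b - a) / max(a, b)
        idx["silhouette"] = float(sil.mean())

    # Dunn
    if k == 1:
        undefined("dunn", "requires k >= 2")
    else:
        diam = 0.0 if wd.size == 0 else float(wd.max())
        sep = float(bd.min()) if bd.size else math.nan
        if not math.isfinite(sep):
            undefined("dunn", "no between-cluster pairs")
        elif diam == 0:
            idx["dunn"] = math.inf
        else:
            idx["dunn"] = sep / diam

    # membership entropy
    frac = sizes / n
    idx["membership_entropy"] = float(-(frac * np.log(frac)).sum())

    # distance summaries
    if wd.size:
        idx["avg_within"], idx["max_within"] = float(wd.mean()), float(wd.max())
    else:
        undefined("avg_within", "no within pairs")
        undefined("max_within", "no within pairs")
    if bd.size:
        idx["avg_between"], idx["max_between"] = float(bd.mean()), float(bd.max())
    else:
        undefined("avg_between", "no between pairs")
        undefined("max_between", "no between pairs")

    return ValidityReport(k=k, n=n, indices=idx, undefined=undef)


def stability_apn(
    X,
    k: int,
    columns=None,
    seed: int | None = None,
) -> float:
    """Average proportion of non-overlap under leave-one-column-out.

    For each deleted feature column the subjects are reclustered (complete
    linkage, cut at the same k) and, for every subject, the proportion of
    its original co-cluster members no longer sharing its cluster is
    averaged. 0 means perfectly stable clustering; the chance level
    approaches 1 - 1/k.

    ``columns`` limits the deletions to a subsample (an int draws that many
    columns with ``seed``); default is every column.
    """
    arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    n, p = arr.shape
    if p < 2:
        raise ValueError("stability_apn requires at least 2 feature columns")
    base = cut_k(hclust_complete(arr), k)
    if columns is None:
        cols = np.arange(p)
    elif np.isscalar(columns):
        m = min(int(columns), p)
        cols = np.sort(np.random.default_rng(seed).choice(p, size=m, replace=False))
    else:
        cols = np.asarray(columns, dtype=int)

    # squared distances updated per deleted column (cheaper than recomputing)
    D2 = squareform(pdist(arr, metric="sqeuclidean"))
    members = {c: np.flatnonzero(base == c) for c in np.unique(base)}
    total = 0.0
    for col in cols:
        diff = arr[:, col][:, None] - arr[:, col][None, :]
        D2_del = np.maximum(D2 - diff ** 2, 0.0)
        np.fill_diagonal(D2_del, 0.0)
        Z = linkage(squareform(np.sqrt(D2_del), checks=False), method="complete")
        raw = fcluster(Z, t=k, criterion="maxclust")
        overlap = 0.0
        for i in range(n):
            orig = members[base[i]]
            overlap += (raw[orig] == raw[i]).mean()
        total += 1.0 - overlap / n
    return total / len(cols)
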