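"""Exploratory hypothesis formation over nest centroids.

Species hypotheses are generated without labels: Euclidean distances between
nest centroids feed agglomerative dendrograms (UPGMA for display and as the
``hclust`` base, Ward optionally), k-means partitions, and PART — a recursive
cluster-number estimation that keeps splitting a cluster while a gap-type
statistic detects substructure and every resulting subcluster satisfies a
minimum size.  Nonmetric multidimensional scaling (Kruskal stress-1) provides
the NMDS embedding used by the NMDS/k-means display variant.

Every stochastic operation takes an explicit seed and is bit-reproducible;
composite procedures derive child seeds from the master seed via
``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage, to_tree
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.manifold import MDS

from .data_model import CentroidMatrix, MorphometryError
from .rav import CorrectedMatrix

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "Partition",
    "GapCurve",
    "Embedding",
    "MisassignmentReport",
    "euclidean_distances",
    "agglomerate",
    "kmeans_partition",
    "gap_statistic",
    "part",
    "nmds",
    "compare_partitions",
]


def as_frame(matrix) -> pd.DataFrame:
    """Coerce the accepted matrix types to a numeric DataFrame."""
    if isinstance(matrix, (CentroidMatrix, CorrectedMatrix)):
        return matrix.frame
    if isinstance(matrix, pd.DataFrame):
        return matrix
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2:
        raise MorphometryError("expected a 2-D matrix")
    return pd.DataFrame(arr, index=[str(i) for i in range(arr.shape[0])])


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise MorphometryError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise MorphometryError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise MorphometryError("distance matrix diagonal is not zero")
        if (v < 0).any():
            raise MorphometryError("negative distances")
        self.values = v

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class Dendrogram:
    """Binary merge tree over items (scipy linkage encoding)."""

    ids: list[str]
    merge_matrix: np.ndarray  # scipy (n-1, 4) linkage matrix
    linkage: str  # "UPGMA" | "Ward"

    @property
    def heights(self) -> np.ndarray:
        return self.merge_matrix[:, 2]

    def cut(self, k: int) -> "Partition":
        """Partition by cutting the tree into k clusters."""
        if not 1 <= k <= len(self.ids):
            raise MorphometryError(f"cannot cut {len(self.ids)} leaves into {k} clusters")
        flat = fcluster(self.merge_matrix, t=k, criterion="maxclust")
        return Partition(
            labels={i: int(c) for i, c in zip(self.ids, flat)},
            k=int(len(set(flat))),
            metadata={"method": f"{self.linkage}-cut"},
        )

    def to_newick(self) -> str:
        """Newick string; branch lengths are merge-height differences."""
        root = to_tree(self.merge_matrix)

        def walk(node, parent_height: float) -> str:
            length = max(parent_height - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.ids[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(root, root.dist) + ";"


@dataclass
class Partition:
    labels: dict[str, int]
    k: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.labels.values())) != self.k:
            raise MorphometryError("k does not match the number of distinct clusters")

    @property
    def ids(self) -> list[str]:
        return list(self.labels)

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for item, c in self.labels.items():
            out.setdefault(c, []).append(item)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"item": list(self.labels), "cluster": list(self.labels.values())}
        )


@dataclass
class GapCurve:
    ks: list[int]
    log_wk: np.ndarray
    ref_log_wk_mean: np.ndarray
    sk: np.ndarray
    chosen_k: int

    @property
    def gap(self) -> np.ndarray:
        return self.ref_log_wk_mean - self.log_wk

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.ks, "log_Wk": self.log_wk,
             "ref_log_Wk": self.ref_log_wk_mean, "gap": self.gap, "se": self.sk}
        )


@dataclass
class Embedding:
    coords: pd.DataFrame
    stress: float
    converged: bool
    metadata: dict = field(default_factory=dict)


@dataclass
class MisassignmentReport:
    n_items: int
    n_misassigned: int
    misassigned: list[str]
    mapping: dict[int, str]  # cluster id -> matched truth label

    @property
    def agreement(self) -> float:
        return 1.0 - self.n_misassigned / self.n_items


# ---------------------------------------------------------------------------


def euclidean_distances(matrix, standardize: bool = False) -> DistanceMatrix:
    """Pairwise Euclidean distances, optionally after per-column z-scoring."""
    frame = as_frame(matrix)
    if frame.shape[0] < 2:
        raise MorphometryError("need at least 2 items for a distance matrix")
    if frame.isna().any().any():
        raise MorphometryError("missing values in the selected columns")
    X = frame.to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise MorphometryError(
                f"cannot standardize constant column(s) {list(frame.columns[zero])}"
            )
        X = (X - X.mean(axis=0)) / sd
    return DistanceMatrix(
        ids=[str(i) for i in frame.index], values=squareform(pdist(X))
    )


def agglomerate(dist: DistanceMatrix, linkage: str = "UPGMA") -> Dendrogram:
    """Full agglomerative merge tree: UPGMA (average) or Ward."""
    methods = {"UPGMA": "average", "Ward": "ward"}
    if linkage not in methods:
        raise MorphometryError(f"unknown linkage {linkage!r}; use UPGMA or Ward")
    Z = scipy_linkage(dist.condensed, method=methods[linkage])
    return Dendrogram(ids=list(dist.ids), merge_matrix=Z, linkage=linkage)


def _wss(X: np.ndarray, assign: np.ndarray) -> float:
    """Total within-cluster sum of squared distances to cluster centroids."""
    total = 0.0
    for c in np.unique(assign):
        sub = X[assign == c]
        total += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return total


def kmeans_partition(
    matrix, k: int, seed: int = 0, n_init: int = 10
) -> Partition:
    """Lloyd's k-means, best of ``n_init`` seeded starts by within-cluster SS."""
    frame = as_frame(matrix)
    n = frame.shape[0]
    if k < 1:
        raise MorphometryError("k must be >= 1")
    if k > n:
        raise MorphometryError(f"k={k} exceeds the number of items {n}")
    X = frame.to_numpy(dtype=float)
    if k == 1:
        assign = np.zeros(n, dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd")
        assign = km.fit_predict(X)
    return Partition(
        labels={str(i): int(c) + 1 for i, c in zip(frame.index, assign)},
        k=int(len(np.unique(assign))),
        metadata={"method": "kmeans", "seed": seed, "n_init": n_init,
                  "wss": _wss(X, assign)},
    )


def _assignments(X: np.ndarray, k: int, base: str, rng_seed: int) -> np.ndarray:
    if k == 1:
        return np.zeros(X.shape[0], dtype=int)
    if base == "hclust":
        Z = scipy_linkage(pdist(X), method="average")
        return fcluster(Z, t=k, criterion="maxclust") - 1
    if base == "kmeans":
        km = KMeans(n_clusters=k, n_init=5, random_state=rng_seed, algorithm="lloyd")
        return km.fit_predict(X)
    raise MorphometryError(f"unknown base method {base!r}")


def gap_statistic(
    matrix,
    k_max: int = 5,
    b: int = 100,
    base: str = "hclust",
    seed: int = 0,
) -> GapCurve:
    """Gap statistic for the number of clusters.

    gap(k) = mean_ref log W_k − log W_k, with W_k the within-cluster
    dispersion of the base clustering and the reference drawn uniformly in
    the principal-component-aligned bounding box of the data.  The chosen k
    is the smallest k with gap(k) >= gap(k+1) − s_{k+1} (the one-standard-
    error rule); on a degenerate, dispersion-free input k = 1 is returned
    with a warning.
    """
    if k_max < 1 or b < 1:
        raise MorphometryError("k_max and b must be >= 1")
    frame = as_frame(matrix)
    X = frame.to_numpy(dtype=float)
    n = X.shape[0]
    k_max = min(k_max, n)
    ks = list(range(1, k_max + 1))

    if np.allclose(X, X[0]):
        warnings.warn("degenerate (all-identical) data: choosing k = 1")
        zero = np.zeros(len(ks))
        return GapCurve(ks=ks, log_wk=zero, ref_log_wk_mean=zero.copy(),
                        sk=zero.copy(), chosen_k=1)

    ss = np.random.SeedSequence(seed)
    base_seed, ref_seed = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))

    eps = np.finfo(float).tiny
    log_wk = np.array(
        [np.log(max(_wss(X, _assignments(X, k, base, base_seed)), eps)) for k in ks]
    )

    # reference: uniform in the PCA-aligned bounding box
    mean = X.mean(axis=0)
    Xc = X - mean
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    Xp = Xc @ Vt.T
    lo, hi = Xp.min(axis=0), Xp.max(axis=0)

    rng = np.random.default_rng(ref_seed)
    ref_logs = np.empty((b, len(ks)))
    for j in range(b):
        Zp = rng.uniform(lo, hi, size=Xp.shape)
        Z = Zp @ Vt + mean
        for ki, k in enumerate(ks):
            ref_logs[j, ki] = np.log(max(_wss(Z, _assignments(Z, k, base, base_seed)), eps))
    ref_mean = ref_logs.mean(axis=0)
    sk = ref_logs.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / b)

    gap = ref_mean - log_wk
    chosen = ks[-1]
    for ki in range(len(ks) - 1):
        if gap[ki] >= gap[ki + 1] - sk[ki + 1]:
            chosen = ks[ki]
            break
    return GapCurve(ks=ks, log_wk=log_wk, ref_log_wk_mean=ref_mean, sk=sk,
                    chosen_k=int(chosen))


def part(
    matrix,
    base: str = "hclust",
    b: int = 1000,
    min_size: int = 5,
    seed: int = 0,
    k_max: int = 5,
) -> Partition:
    """Recursive cluster-number estimation under a minimum-cluster-size rule.

    Each current item set is tested for substructure with the gap statistic;
    if the chosen k exceeds 1 and every subcluster produced by the base
    method has at least ``min_size`` members, the set is split and each part
    recursed into; otherwise the set becomes an output cluster.  A proposed
    split violating ``min_size`` is rejected entirely.
    """
    frame = as_frame(matrix)
    if min_size < 1:
        raise MorphometryError("min_size must be >= 1")
    ids = np.array([str(i) for i in frame.index])
    X = frame.to_numpy(dtype=float)

    clusters: list[np.ndarray] = []

    def recurse(idx: np.ndarray, node_seed: np.random.SeedSequence) -> None:
        if idx.size < 2 * min_size:
            clusters.append(idx)
            return
        gap_seed, split_seed, *child_seeds = node_seed.spawn(2 + k_max)
        sub = X[idx]
        km = min(k_max, idx.size // min_size)
        curve = gap_statistic(
            pd.DataFrame(sub, index=ids[idx]), k_max=km, b=b, base=base,
            seed=int(gap_seed.generate_state(1)[0] % (2**31)),
        )
        if curve.chosen_k <= 1:
            clusters.append(idx)
            return
        assign = _assignments(
            sub, curve.chosen_k, base,
            int(split_seed.generate_state(1)[0] % (2**31)),
        )
        parts = [idx[assign == c] for c in np.unique(assign)]
        if any(p.size < min_size for p in parts):
            clusters.append(idx)
            return
        for p, cseed in zip(parts, child_seeds):
            recurse(p, cseed)

    recurse(np.arange(len(ids)), np.random.SeedSequence(seed))

    labels: dict[str, int] = {}
    for cid, idx in enumerate(sorted(clusters, key=lambda a: a[0]), start=1):
        for i in idx:
            labels[ids[i]] = cid
    labels = {i: labels[i] for i in ids}  # restore input order
    return Partition(
        labels=labels, k=len(clusters),
        metadata={"method": f"PART-{base}", "b": b, "min_size": min_size,
                  "seed": seed, "k_max": k_max},
    )


def nmds(
    dist: DistanceMatrix,
    dims: int = 2,
    seed: int = 0,
    restarts: int = 4,
    max_iter: int = 300,
) -> Embedding:
    """Nonmetric MDS minimizing Kruskal stress-1; best of seeded restarts."""
    n = len(dist.ids)
    if n < dims + 1:
        raise MorphometryError(f"need at least dims+1={dims + 1} items, got {n}")
    best: Optional[tuple[float, np.ndarray, int]] = None
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(max(restarts, 1)):
        rs = int(child.generate_state(1)[0] % (2**31))
        mds = MDS(
            n_components=dims, metric_mds=False, metric="precomputed",
            n_init=1, init="random", max_iter=max_iter, random_state=rs,
            normalized_stress=True,
        )
        coords = mds.fit_transform(dist.values)
        if best is None or mds.stress_ < best[0]:
            best = (float(mds.stress_), coords, int(mds.n_iter_))
    stress, coords, n_iter = best
    return Embedding(
        coords=pd.DataFrame(
            coords, index=dist.ids, columns=[f"dim{i + 1}" for i in range(dims)]
        ),
        stress=stress,
        converged=n_iter < max_iter,
        metadata={"restarts": restarts, "seed": seed, "n_iter": n_iter},
    )


def compare_partitions(p: Partition, truth: Mapping[str, str]) -> MisassignmentReport:
    """Count disagreements under the best cluster-to-label matching."""
    if set(p.labels) != set(truth):
        raise MorphometryError("partition and truth cover different item sets")
    clusters = sorted(set(p.labels.values()))
    classes = sorted(set(truth.values()))
    table = np.zeros((len(clusters), len(classes)), dtype=int)
    ci = {c: i for i, c in enumerate(clusters)}
    li = {l: i for i, l in enumerate(classes)}
    for item, c in p.labels.items():
        table[ci[c], li[truth[item]]] += 1
    # pad to square so every cluster/label can be left unmatched
    m = max(table.shape)
    padded = np.zeros((m, m), dtype=int)
    padded[: table.shape[0], : table.shape[1]] = table
    rows, cols = linear_sum_assignment(-padded)
    mapping = {
        clusters[r]: classes[c]
        for r, c in zip(rows, cols)
        if r < len(clusters) and c < len(classes)
    }
    mis = [
        item for item, c in p.labels.items()
        if mapping.get(c) != truth[item]
    ]
    return MisassignmentReport(
        n_items=len(p.labels), n_misassigned=len(mis),
        misassigned=mis, mapping=mapping,
    )
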