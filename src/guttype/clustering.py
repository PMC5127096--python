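"""Enterotype-style clustering on Jensen-Shannon distances.

The workflow follows the distance-based enterotyping lineage: sample profiles
are compared with the square root of the Jensen-Shannon divergence (natural
log; a proper metric bounded by sqrt(ln 2)), partitioned with PAM (k-medoids,
BUILD + SWAP), the number of clusters chosen by the Calinski-Harabasz index in
a principal-coordinates embedding, and the chosen partition validated by
prediction strength (split-half cluster stability) and the mean silhouette
width.  Classification bands: PS >= 0.9 means strong clustering; SI bands are
<=0.25 (no substantial structure), (0.25, 0.5] weak, (0.5, 0.75] reasonable,
>0.75 strong.  A partition counts as statistically reliable when PS >= 0.9
and SI > 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .abundance import AbundanceTable

__all__ = [
    "DistanceMatrix",
    "PartitionResult",
    "ClusterValidationReport",
    "Dendrogram",
    "jsd_distance",
    "pam",
    "upgma",
    "ch_index",
    "prediction_strength",
    "silhouette",
    "select_and_validate",
    "classify_ps",
    "classify_si",
    "CH_CAP",
]

#: Sentinel reported for the CH index when within-cluster dispersion is zero.
CH_CAP = 1e12

MAX_SQRT_JSD = float(np.sqrt(np.log(2.0)))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise sample dissimilarities with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0):
            raise ValueError("distance matrix must be symmetric within 1e-12")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if (self.values < 0).any():
            raise ValueError("distances must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def subset(self, sample_ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.values[np.ix_(idx, idx)])

    def to_tsv(self, path: str | Path, header_lines: Iterable[str] = ()) -> None:
        frame = pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)
        frame.index.name = "sample_id"
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            frame.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        return cls([str(s) for s in frame.index], frame.to_numpy(dtype=float))


def jsd_distance(table: AbundanceTable, sqrt: bool = True) -> DistanceMatrix:
    """Pairwise (square-root) Jensen-Shannon divergence between sample profiles.

    d(a, b) = sqrt( H(m) - (H(a) + H(b)) / 2 ) with m = (a + b)/2 and H the
    natural-log entropy; 0 log 0 := 0.  Without ``sqrt`` the raw divergence is
    returned (bounded by ln 2, not a metric).
    """
    if table.kind != "relative":
        raise ValueError("jsd_distance expects a relative-abundance table")
    profiles = table.values
    sums = profiles.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6, rtol=0):
        raise ValueError("profile rows must each sum to 1")
    n = profiles.shape[0]

    def entropy(rows: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(rows > 0, rows * np.log(rows), 0.0)
        return -term.sum(axis=-1)

    h = entropy(profiles)
    out = np.zeros((n, n))
    for i in range(n):
        mix = 0.5 * (profiles[i][None, :] + profiles[i + 1 :])
        div = entropy(mix) - 0.5 * (h[i] + h[i + 1 :])
        out[i, i + 1 :] = np.maximum(div, 0.0)
    out = out + out.T
    if sqrt:
        out = np.sqrt(out)
    return DistanceMatrix(table.sample_ids, out)


@dataclass
class PartitionResult:
    """A PAM partition: labels, medoids and the total within-cluster distance."""

    k: int
    labels: np.ndarray
    medoid_indices: np.ndarray
    medoid_ids: list[str]
    objective: float


def _as_matrix(dist: DistanceMatrix | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(dist, DistanceMatrix):
        return dist.values, dist.sample_ids
    arr = np.asarray(dist, dtype=float)
    return arr, [str(i) for i in range(arr.shape[0])]


#: Instances with at most this many candidate medoid sets are solved exactly.
PAM_EXACT_LIMIT = 300


def pam(
    dist: DistanceMatrix | np.ndarray, k: int, max_iter: int = 300, method: str = "auto"
) -> PartitionResult:
    """Partitioning around medoids.

    Tiny instances (at most :data:`PAM_EXACT_LIMIT` candidate medoid sets,
    ``method="auto"``) are solved exactly by enumeration; larger ones by the
    classic BUILD + best-improvement SWAP heuristic (``method="build_swap"``
    forces it).  Either way the result is swap-optimal: no single medoid <->
    non-medoid exchange decreases the objective, which is the sum of the
    distances of every sample to its nearest medoid.  Deterministic: ties in
    BUILD, SWAP, enumeration and label assignment break toward the lowest
    sample index.
    """
    d, ids = _as_matrix(dist)
    n = d.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    from math import comb

    if method not in ("auto", "build_swap", "exact"):
        raise ValueError(f"unknown method {method!r}")
    if method == "exact" or (method == "auto" and comb(n, k) <= PAM_EXACT_LIMIT):
        return _pam_exact(d, ids, k)
    return _pam_build_swap(d, ids, k, max_iter)


def _finish(d: np.ndarray, ids: list[str], medoid_arr: np.ndarray, k: int) -> PartitionResult:
    n = d.shape[0]
    labels = np.argmin(d[:, medoid_arr], axis=1)
    labels[medoid_arr] = np.arange(k)  # each medoid anchors its own cluster
    objective = float(d[np.arange(n), medoid_arr[labels]].sum())
    return PartitionResult(
        k=k,
        labels=labels,
        medoid_indices=medoid_arr,
        medoid_ids=[ids[m] for m in medoid_arr],
        objective=objective,
    )


def _pam_exact(d: np.ndarray, ids: list[str], k: int) -> PartitionResult:
    from itertools import combinations

    n = d.shape[0]
    best_obj = np.inf
    best_set: tuple[int, ...] | None = None
    for combo in combinations(range(n), k):  # lexicographic => deterministic ties
        obj = d[:, combo].min(axis=1).sum()
        if obj < best_obj - 1e-15:
            best_obj = obj
            best_set = combo
    return _finish(d, ids, np.array(best_set), k)


def _pam_build_swap(d: np.ndarray, ids: list[str], k: int, max_iter: int) -> PartitionResult:
    n = d.shape[0]
    # BUILD: greedy seeding; first medoid minimizes total distance.
    medoids = [int(np.argmin(d.sum(axis=1)))]
    nearest = d[:, medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[:, None] - d, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        h = int(np.argmax(gains))
        medoids.append(h)
        nearest = np.minimum(nearest, d[:, h])

    medoid_arr = np.array(sorted(medoids))
    objective = float(d[:, medoid_arr].min(axis=1).sum())

    # SWAP: steepest-descent exchange of one medoid for one non-medoid.
    for _ in range(max_iter):
        best_delta = -1e-12
        best_swap: tuple[int, int] | None = None
        in_set = np.zeros(n, dtype=bool)
        in_set[medoid_arr] = True
        for pos, m_out in enumerate(medoid_arr):
            others = np.delete(medoid_arr, pos)
            partial = d[:, others].min(axis=1) if others.size else np.full(n, np.inf)
            cand_obj = np.minimum(partial[:, None], d).sum(axis=0)
            cand_obj[in_set] = np.inf
            h = int(np.argmin(cand_obj))
            delta = float(cand_obj[h]) - objective
            if delta < best_delta:
                best_delta = delta
                best_swap = (pos, h)
        if best_swap is None:
            break
        pos, h = best_swap
        medoid_arr[pos] = h
        medoid_arr = np.sort(medoid_arr)
        objective = float(d[:, medoid_arr].min(axis=1).sum())

    return _finish(d, ids, medoid_arr, k)


@dataclass
class Dendrogram:
    """UPGMA tree over samples; node heights are half the merged distance."""

    leaf_ids: list[str]
    linkage_matrix: np.ndarray

    @property
    def merge_heights(self) -> np.ndarray:
        """Ultrametric node heights, nondecreasing toward the root."""
        return self.linkage_matrix[:, 2] / 2.0

    def to_newick(self) -> str:
        tree = to_tree(self.linkage_matrix)

        def recurse(node, parent_height: float) -> str:
            height = node.dist / 2.0
            length = parent_height - height
            if node.is_leaf():
                return f"{self.leaf_ids[node.id]}:{parent_height:.10g}"
            left = recurse(node.left, height)
            right = recurse(node.right, height)
            return f"({left},{right}):{length:.10g}"

        root_height = tree.dist / 2.0
        left = recurse(tree.left, root_height)
        right = recurse(tree.right, root_height)
        return f"({left},{right});"

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def upgma(dist: DistanceMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) dendrogram; ultrametric by construction."""
    if dist.n < 2:
        raise ValueError("UPGMA needs at least two samples")
    z = linkage(dist.condensed(), method="average")
    return Dendrogram(leaf_ids=list(dist.sample_ids), linkage_matrix=z)


def _pcoa_coords(d: np.ndarray) -> np.ndarray:
    """Classical-MDS embedding keeping positive-eigenvalue axes."""
    n = d.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-10, 1e-8 * abs(eigval[0])) if eigval.size else 0.0
    keep = eigval > tol
    return eigvec[:, keep] * np.sqrt(eigval[keep])


def ch_index(
    dist: DistanceMatrix | np.ndarray,
    labels: Sequence[int],
    coords: np.ndarray | None = None,
) -> float:
    """Calinski-Harabasz index computed in the PCoA embedding of the distances.

    CH = [B/(k-1)] / [W/(n-k)] with B and W the between/within sums of squared
    deviations from centroids.  For Euclidean input distances this equals the
    classic coordinate-based CH.  W = 0 is reported as the capped sentinel
    :data:`CH_CAP` so argmax over k stays well defined.
    """
    d, _ = _as_matrix(dist)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k = uniq.size
    n = d.shape[0]
    if k < 2:
        raise ValueError("CH index undefined for k < 2")
    if coords is None:
        coords = _pcoa_coords(d)
    grand = coords.mean(axis=0)
    within = 0.0
    between = 0.0
    for lab in uniq:
        members = coords[labels == lab]
        centroid = members.mean(axis=0)
        within += ((members - centroid) ** 2).sum()
        between += members.shape[0] * ((centroid - grand) ** 2).sum()
    if within <= 1e-12 * max(between, 1.0):
        return CH_CAP
    return float((between / (k - 1)) / (within / (n - k)))


def silhouette(dist: DistanceMatrix | np.ndarray, labels: Sequence[int]) -> float:
    """Mean silhouette width s(i) = (b - a)/max(a, b); singleton clusters get 0."""
    d, _ = _as_matrix(dist)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette undefined for a single cluster")
    n = d.shape[0]
    # mean distance from every sample to every cluster
    sums = np.stack([d[:, labels == lab].sum(axis=1) for lab in uniq], axis=1)
    sizes = np.array([(labels == lab).sum() for lab in uniq])
    own = np.searchsorted(uniq, labels)
    s = np.zeros(n)
    for i in range(n):
        c = own[i]
        if sizes[c] == 1:
            continue
        a = sums[i, c] / (sizes[c] - 1)
        other = [sums[i, j] / sizes[j] for j in range(uniq.size) if j != c]
        b = min(other)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def prediction_strength(
    dist: DistanceMatrix | np.ndarray,
    k: int,
    repeats: int = 100,
    seed: int | None = None,
) -> float:
    """Split-half cluster stability of the k-cluster PAM partition.

    For each repeat the samples are split 50/50 at random and PAM is run on
    each half.  Test samples are then assigned to their nearest training
    medoid; for every test-side cluster with at least two members the fraction
    of its pairs co-assigned by the training rule is computed, and the repeat
    scores the minimum over those clusters.  Both fold directions are
    evaluated; the mean over 2 x repeats is returned (in [0, 1]).
    """
    d, _ = _as_matrix(dist)
    n = d.shape[0]
    if k < 2:
        raise ValueError("prediction strength requires k >= 2")
    if n < 4 or k > n // 2:
        raise ValueError(f"need k <= n/2 and n >= 4 (n={n}, k={k})")
    rng = np.random.default_rng(seed)
    scores = []
    for _ in range(repeats):
        perm = rng.permutation(n)
        half_a, half_b = perm[: n // 2], perm[n // 2 :]
        for train, test in ((half_a, half_b), (half_b, half_a)):
            scores.append(_ps_one_fold(d, train, test, k))
    return float(np.mean(scores))


def _ps_one_fold(d: np.ndarray, train: np.ndarray, test: np.ndarray, k: int) -> float:
    train_part = pam(d[np.ix_(train, train)], k)
    test_part = pam(d[np.ix_(test, test)], k)
    train_medoids = train[train_part.medoid_indices]
    transfer = np.argmin(d[np.ix_(test, train_medoids)], axis=1)
    cluster_scores = []
    for lab in range(k):
        members = np.where(test_part.labels == lab)[0]
        m = members.size
        if m < 2:
            continue
        assign = transfer[members]
        same = (assign[:, None] == assign[None, :]).sum() - m
        cluster_scores.append(same / (m * (m - 1)))
    return min(cluster_scores) if cluster_scores else 1.0


def classify_ps(ps: float) -> str:
    return "strong clustering" if ps >= 0.9 else "no strong clustering"


def classify_si(si: float) -> str:
    if si <= 0.25:
        return "no substantial structure"
    if si <= 0.5:
        return "weak structure"
    if si <= 0.75:
        return "reasonable structure"
    return "strong structure"


@dataclass
class ClusterValidationReport:
    """CH per k, chosen k, PS/SI at the chosen k, and threshold classifications."""

    ch_by_k: dict[int, float]
    best_k: int
    prediction_strength: float
    silhouette: float
    ps_class: str = field(init=False)
    si_class: str = field(init=False)
    reliable: bool = field(init=False)

    def __post_init__(self) -> None:
        self.ps_class = classify_ps(self.prediction_strength)
        self.si_class = classify_si(self.silhouette)
        self.reliable = self.prediction_strength >= 0.9 and self.silhouette > 0.25

    def to_frame(self) -> pd.DataFrame:
        rows = {f"ch_k{k}": v for k, v in sorted(self.ch_by_k.items())}
        rows.update(
            best_k=self.best_k,
            prediction_strength=self.prediction_strength,
            silhouette=self.silhouette,
            ps_class=self.ps_class,
            si_class=self.si_class,
            reliable=self.reliable,
        )
        return pd.DataFrame({"value": rows})


def select_and_validate(
    dist: DistanceMatrix | np.ndarray,
    k_range: Sequence[int] = range(2, 11),
    repeats: int = 100,
    seed: int | None = None,
    force_k: int | None = None,
) -> ClusterValidationReport:
    """Choose k by the CH index, then validate the partition with PS and SI.

    ``best_k`` is the CH argmax over *k_range* (ties toward smaller k); PS and
    SI are computed at ``best_k`` unless *force_k* pins them to a fixed k.
    """
    d, _ = _as_matrix(dist)
    n = d.shape[0]
    k_range = [k for k in k_range if 2 <= k <= n - 1]
    if not k_range:
        raise ValueError("k_range must contain at least one k in [2, n-1]")
    coords = _pcoa_coords(d)
    ch_by_k: dict[int, float] = {}
    partitions: dict[int, PartitionResult] = {}
    for k in k_range:
        part = pam(d, k)
        partitions[k] = part
        ch_by_k[k] = ch_index(d, part.labels, coords=coords)
    best_k = max(sorted(ch_by_k), key=lambda k: (ch_by_k[k], -k))
    eval_k = force_k if force_k is not None else best_k
    part = partitions.get(eval_k) or pam(d, eval_k)
    ps = prediction_strength(d, eval_k, repeats=repeats, seed=seed)
    si = silhouette(d, part.labels)
    return ClusterValidationReport(
        ch_by_k=ch_by_k, best_k=best_k, prediction_strength=ps, silhouette=si
    )
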