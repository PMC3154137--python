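"""Association-pattern clustering.

Raw p-values from differently powered studies are not directly comparable,
so association strength is first reduced to four ordinal evidence classes
(cut-points 0.05, 1e-3, 1e-6).  SNP profiles over these classes are compared
with Gower's distance for categorical data (mismatch averaged over the
phenotypes observed in both SNPs), clustered by Ward's agglomerative method,
and the tree is cut into k groups.  Each group's per-disease evidence is then
summarized with Fisher's omnibus statistic over the member SNPs' p-values.

The agglomeration is hand-rolled rather than delegated to
``scipy.cluster.hierarchy`` because reproducibility across platforms requires
an explicit tie-break: on equal merge cost, the candidate pair whose
(lexicographically smallest member labels) sort first is merged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import AssociationMatrix, FisherResult, fisher_omnibus

__all__ = [
    "EVIDENCE_CUTPOINTS",
    "EvidenceMatrix",
    "DistanceMatrix",
    "MergeTree",
    "ClusterModel",
    "bin_evidence",
    "evidence_matrix",
    "gower_distance",
    "ward_linkage",
    "cut_clusters",
    "cluster_disease_summary",
    "to_newick",
]

# Class boundaries on p: [0.05, 1] -> 0, [1e-3, 0.05) -> 1,
# [1e-6, 1e-3) -> 2, (0, 1e-6) -> 3.  Boundary points fall in the
# weaker-evidence bin (left-closed), an arbitrary but fixed convention.
EVIDENCE_CUTPOINTS = (0.05, 1e-3, 1e-6)

N_CLASSES = 4


def bin_evidence(p: Optional[float]) -> Optional[int]:
    """Ordinal evidence class of a p-value (0 weakest .. 3 strongest).

    Missing input (None or NaN) propagates as None.
    """
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return None
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p must be in (0, 1], got {p}")
    if p >= EVIDENCE_CUTPOINTS[0]:
        return 0
    if p >= EVIDENCE_CUTPOINTS[1]:
        return 1
    if p >= EVIDENCE_CUTPOINTS[2]:
        return 2
    return 3


@dataclass
class EvidenceMatrix:
    """SNP x phenotype grid of ordinal evidence classes (NaN = missing)."""

    frame: pd.DataFrame  # float codes 0..3 with NaN for missing

    @property
    def snp_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def phenotypes(self) -> list[str]:
        return list(self.frame.columns)


def evidence_matrix(matrix: AssociationMatrix) -> EvidenceMatrix:
    """Bin every association of a matrix into evidence classes."""
    pf = matrix.p_frame()
    codes = pf.map(lambda p: np.nan if pd.isna(p) else float(bin_evidence(p)))
    return EvidenceMatrix(frame=codes)


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray  # symmetric, zero diagonal, values in [0, 1]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")


def gower_distance(em: EvidenceMatrix, mode: str = "categorical") -> DistanceMatrix:
    """Gower dissimilarity between SNP evidence profiles.

    ``categorical``: per-phenotype contribution is 0 on equal class, 1
    otherwise.  ``ordinal``: contribution is |class difference| / 3, using
    the natural order of the evidence bins.  Either way the pairwise distance
    averages contributions over the phenotypes observed in *both* SNPs
    (Gower's pairwise-deletion rule); a pair with no shared phenotype is an
    error, as is an all-missing profile.
    """
    if mode not in ("categorical", "ordinal"):
        raise ValueError(f"unknown gower mode: {mode!r}")
    x = em.frame.to_numpy(dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("gower_distance requires at least 2 SNPs")
    obs = ~np.isnan(x)
    empty = ~obs.any(axis=1)
    if empty.any():
        bad = [em.snp_ids[i] for i in np.flatnonzero(empty)]
        raise ValueError(f"all-missing evidence profile(s): {bad}")
    d = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            shared = obs[i] & obs[j]
            m = int(shared.sum())
            if m == 0:
                raise ValueError(
                    f"no shared phenotypes between {em.snp_ids[i]} and "
                    f"{em.snp_ids[j]}; distance undefined"
                )
            if mode == "categorical":
                contrib = (x[i, shared] != x[j, shared]).astype(float)
            else:
                contrib = np.abs(x[i, shared] - x[j, shared]) / (N_CLASSES - 1)
            d[i, j] = d[j, i] = contrib.mean()
    return DistanceMatrix(labels=list(em.snp_ids), d=d)


@dataclass
class MergeTree:
    """Agglomeration history in scipy linkage layout.

    ``merges`` has one row per merge: (id_a, id_b, height, size), where ids
    0..n-1 are the input leaves in ``labels`` order and id n+t is the cluster
    created by merge t.
    """

    labels: list[str]
    merges: np.ndarray  # (n-1, 4)
    dialect: str

    @property
    def n_leaves(self) -> int:
        return len(self.labels)


def ward_linkage(dm: DistanceMatrix, dialect: str = "ward_d") -> MergeTree:
    """Ward agglomerative clustering of a precomputed dissimilarity matrix.

    Ward's criterion merges, at each step, the pair of clusters whose fusion
    least increases the within-cluster error sum of squares; with only a
    dissimilarity matrix available this is realized through the
    Lance-Williams update
    ``d(k, ij) = ((n_i + n_k) d(k,i) + (n_j + n_k) d(k,j) - n_k d(i,j)) / (n_i + n_j + n_k)``.
    ``ward_d`` applies the update to the dissimilarities as given (the
    classical behaviour of R's ``hclust(method="ward.D")``); ``ward_d2``
    applies it to squared dissimilarities and reports square-rooted heights.

    Ties in merge cost are broken deterministically: the candidate pair whose
    sorted pair of lexicographically-smallest member labels compares lowest
    is merged first.
    """
    if dialect not in ("ward_d", "ward_d2"):
        raise ValueError(f"unknown ward dialect: {dialect!r}")
    labels = list(dm.labels)
    n = len(labels)
    if n < 2:
        raise ValueError("ward_linkage requires at least 2 items")
    work = dm.d.copy()
    if dialect == "ward_d2":
        work = work ** 2

    # active cluster state keyed by scipy-style id
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(work[i, j])
    size = {i: 1 for i in range(n)}
    rep = {i: labels[i] for i in range(n)}  # lexicographically smallest member
    active = set(range(n))
    merges = np.zeros((n - 1, 4), dtype=float)

    def key(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a < b else (b, a)

    for t in range(n - 1):
        best = None
        for a in sorted(active):
            for b in sorted(active):
                if b <= a:
                    continue
                cost = dist[key(a, b)]
                lo, hi = sorted((rep[a], rep[b]))
                cand = (cost, lo, hi, a, b)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        cost, _, _, a, b = best
        new = n + t
        height = math.sqrt(max(cost, 0.0)) if dialect == "ward_d2" else cost
        merges[t] = (a, b, height, size[a] + size[b])
        # Lance-Williams update for Ward's criterion
        for c in active:
            if c in (a, b):
                continue
            na, nb, nc = size[a], size[b], size[c]
            dca, dcb = dist[key(c, a)], dist[key(c, b)]
            dab = dist[key(a, b)]
            dist[(c, new)] = (  # c < new always: new ids grow monotonically
                (na + nc) * dca + (nb + nc) * dcb - nc * dab
            ) / (na + nb + nc)
        size[new] = size[a] + size[b]
        rep[new] = min(rep[a], rep[b])
        active.discard(a)
        active.discard(b)
        active.add(new)

    # guard against monotonicity wobble from floating-point roundoff
    for t in range(1, n - 1):
        if merges[t, 2] < merges[t - 1, 2]:
            if merges[t - 1, 2] - merges[t, 2] > 1e-9 * max(1.0, merges[t - 1, 2]):
                raise AssertionError("non-monotone Ward merge heights")
            merges[t, 2] = merges[t - 1, 2]
    return MergeTree(labels=labels, merges=merges, dialect=dialect)


@dataclass
class ClusterModel:
    """A k-cut of a dendrogram: SNP id -> cluster label (1..k)."""

    tree: MergeTree
    k: int
    assignment: dict[str, int]

    def members(self, label: int) -> list[str]:
        return [s for s, c in self.assignment.items() if c == label]

    def partition(self) -> set[frozenset]:
        """Label-free view of the clustering, for partition comparisons."""
        out: dict[int, set] = {}
        for s, c in self.assignment.items():
            out.setdefault(c, set()).add(s)
        return {frozenset(v) for v in out.values()}


def cut_clusters(tree: MergeTree, k: int = 4) -> ClusterModel:
    """Cut a dendrogram into exactly k clusters (drop the k-1 highest merges).

    Cluster labels 1..k are assigned in order of each cluster's
    lexicographically smallest member, so the labelling is deterministic;
    only partition-level comparisons are meaningful across runs.
    """
    n = tree.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for t in range(n - k):  # replay all but the k-1 last merges
        a, b = int(tree.merges[t, 0]), int(tree.merges[t, 1])
        new = n + t
        parent[find(a)] = new
        parent[find(b)] = new

    groups: dict[int, list[str]] = {}
    for i, lab in enumerate(tree.labels):
        groups.setdefault(find(i), []).append(lab)
    ordered = sorted(groups.values(), key=lambda ms: min(ms))
    assignment = {s: c + 1 for c, ms in enumerate(ordered) for s in ms}
    return ClusterModel(tree=tree, k=k, assignment=assignment)


def cluster_disease_summary(
    model: ClusterModel, matrix: AssociationMatrix
) -> pd.DataFrame:
    """Fisher omnibus summary of each (cluster, phenotype) cell.

    For every cluster and phenotype, combines the member SNPs' non-missing
    p-values with Fisher's method (chi-square, 2N df).  Cells with no
    observed p-value are reported with NaN statistic and combined p
    (undefined), not dropped.
    """
    missing_ids = set(model.assignment) - set(matrix.snp_ids)
    if missing_ids:
        raise ValueError(f"assignment covers SNPs absent from matrix: {missing_ids}")
    pf = matrix.p_frame()
    rows = []
    for label in sorted(set(model.assignment.values())):
        members = model.members(label)
        sub = pf.loc[members]
        for ph in matrix.phenotypes:
            vals = sub[ph].dropna().to_numpy()
            if vals.size == 0:
                rows.append(
                    {"cluster": label, "phenotype": ph, "n": 0,
                     "s_cum": np.nan, "df": 0, "combined_p": np.nan,
                     "log10_p": np.nan}
                )
                continue
            res: FisherResult = fisher_omnibus(vals)
            rows.append(
                {"cluster": label, "phenotype": ph, "n": int(vals.size),
                 "s_cum": res.statistic, "df": res.df,
                 "combined_p": res.combined_p, "log10_p": res.log10_p}
            )
    return pd.DataFrame(rows)


def to_newick(tree: MergeTree) -> str:
    """Dendrogram as a Newick string with merge heights as branch lengths."""
    n = tree.n_leaves
    height = {i: 0.0 for i in range(n)}
    node = {i: tree.labels[i] for i in range(n)}
    for t in range(n - 1):
        a, b, h = int(tree.merges[t, 0]), int(tree.merges[t, 1]), tree.merges[t, 2]
        la = max(h - height[a], 0.0)
        lb = max(h - height[b], 0.0)
        node[n + t] = f"({node[a]}:{la:.10g},{node[b]}:{lb:.10g})"
        height[n + t] = h
    return node[2 * n - 2] + ";"
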