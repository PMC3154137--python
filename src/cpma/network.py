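"""Protein-interaction connectivity of clustered loci.

Loci (the genes overlapping each associated SNP's genomic span) grouped by
cluster are tested for being more inter-connected in a protein-protein
interaction network than chance would allow.  Two scores are computed:
direct connectivity (network edges joining genes of distinct loci, ignoring
edges within a locus) and common-intermediary connectivity (distinct-locus
gene pairs sharing at least one network neighbour).  Significance comes from
a degree-aware permutation null: each observed gene is relabelled with a
network gene drawn from the same degree bin, preserving the locus structure
and the degree profile of the observed set, and the observed counts are
compared against the permuted distribution with the add-one empirical
p-value (1 + #{null >= obs}) / (B + 1).

This is a deliberately simplified, self-contained variant of DAPPLE-style
within-degree node relabelling; see docs/methods.md.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_DEGREE_BINS",
    "Locus",
    "ConnectivityResult",
    "build_loci",
    "connectivity",
    "permutation_test",
]

# degree bins for the permutation null: [lo, hi] inclusive
DEFAULT_DEGREE_BINS: tuple[tuple[int, int], ...] = (
    (1, 4), (5, 9), (10, 49), (50, 99), (100, 10**9),
)


@dataclass(frozen=True)
class Locus:
    """An associated SNP's genomic span, reduced to its overlapping genes."""

    snp_id: str
    genes: frozenset

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"locus {self.snp_id} has an empty gene set")


@dataclass
class ConnectivityResult:
    direct_count: int
    indirect_count: int
    null_direct: np.ndarray
    null_indirect: np.ndarray
    p_direct: float
    p_indirect: float
    n_perm: int
    seed: int


def build_loci(
    snp_ids: Sequence[str],
    gene_intervals: pd.DataFrame,
    locus_spans: pd.DataFrame,
) -> list[Locus]:
    """Assign genes to SNP loci by genomic overlap.

    ``gene_intervals`` needs columns (gene, chrom, start, end) and
    ``locus_spans`` columns (snp, chrom, start, end); coordinates are 1-based
    fully-closed, so a gene belongs to a locus iff the intervals share at
    least one base on the same chromosome (adjacency is not overlap).  SNPs
    whose span covers no gene are dropped with a warning.
    """
    for df, cols, what in (
        (gene_intervals, ("gene", "chrom", "start", "end"), "gene_intervals"),
        (locus_spans, ("snp", "chrom", "start", "end"), "locus_spans"),
    ):
        missing = set(cols) - set(df.columns)
        if missing:
            raise ValueError(f"{what} missing columns: {sorted(missing)}")
        bad = df[df["start"] > df["end"]]
        if len(bad):
            raise ValueError(f"{what} has start > end rows: {bad.index.tolist()}")

    spans = locus_spans.set_index("snp")
    loci: list[Locus] = []
    for snp_id in snp_ids:
        if snp_id not in spans.index:
            raise ValueError(f"no locus span for SNP {snp_id}")
        row = spans.loc[snp_id]
        same = gene_intervals[gene_intervals["chrom"].astype(str) == str(row["chrom"])]
        hit = same[(same["start"] <= row["end"]) & (same["end"] >= row["start"])]
        genes = frozenset(hit["gene"].astype(str))
        if not genes:
            logger.warning("locus %s overlaps no gene; dropped", snp_id)
            continue
        loci.append(Locus(snp_id=snp_id, genes=genes))
    return loci


def _locus_membership(loci: Sequence[Locus]) -> dict:
    """gene -> set of locus indices (genes may sit in several loci)."""
    member: dict = {}
    for i, locus in enumerate(loci):
        for g in locus.genes:
            member.setdefault(g, set()).add(i)
    return member


def connectivity(loci: Sequence[Locus], net: nx.Graph) -> tuple[int, int]:
    """(direct, common-intermediary) connectivity of one cluster's loci.

    Direct: network edges between genes that share no locus (within-locus
    edges are excluded — genes under the same association peak interacting
    with each other is not evidence of a shared pathway between loci).
    Indirect: unordered pairs of genes sharing no locus that have at least
    one common network neighbour (the intermediary may be any node).  Genes
    absent from the network contribute nothing.
    """
    if not loci:
        raise ValueError("connectivity requires at least one locus")
    member = _locus_membership(loci)
    genes = [g for g in member if net.has_node(g)]

    direct = 0
    for u, v in net.edges():
        if u in member and v in member and not (member[u] & member[v]):
            direct += 1

    indirect = 0
    neigh = {g: set(net.neighbors(g)) for g in genes}
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            u, v = genes[i], genes[j]
            if member[u] & member[v]:
                continue
            if neigh[u] & neigh[v]:
                indirect += 1
    return direct, indirect


def _degree_bin(deg: int, bins: Sequence[tuple[int, int]]) -> int:
    for b, (lo, hi) in enumerate(bins):
        if lo <= deg <= hi:
            return b
    # degree 0 or outside all bins: treat as the lowest bin
    return 0


def permutation_test(
    loci: Sequence[Locus],
    net: nx.Graph,
    n_perm: int = 4000,
    seed: Optional[int] = None,
    degree_bins: Sequence[tuple[int, int]] = DEFAULT_DEGREE_BINS,
) -> ConnectivityResult:
    """Degree-aware permutation test of cluster connectivity.

    Each permutation relabels every observed network gene with a gene drawn
    uniformly (without replacement within the permutation) from the same
    degree bin of the network, keeping the locus structure — including genes
    shared between loci — intact.  A bin with too few candidates is widened
    to its neighbours with a logged warning.  Empirical p-values use the
    add-one rule, so they are bounded below by 1/(n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if seed is None:
        raise ValueError("seed is mandatory for reproducibility")
    rng = np.random.default_rng(seed)

    obs_direct, obs_indirect = connectivity(loci, net)
    sampler = _NullSampler(loci, net, degree_bins)

    null_direct = np.zeros(n_perm, dtype=int)
    null_indirect = np.zeros(n_perm, dtype=int)
    for it in range(n_perm):
        null_direct[it], null_indirect[it] = connectivity(
            sampler.draw(rng), net
        )

    p_direct = (1 + int((null_direct >= obs_direct).sum())) / (n_perm + 1)
    p_indirect = (1 + int((null_indirect >= obs_indirect).sum())) / (n_perm + 1)
    return ConnectivityResult(
        direct_count=obs_direct,
        indirect_count=obs_indirect,
        null_direct=null_direct,
        null_indirect=null_indirect,
        p_direct=p_direct,
        p_indirect=p_indirect,
        n_perm=n_perm,
        seed=seed,
    )


class _NullSampler:
    """Draws degree-matched relabellings of a cluster's observed genes."""

    def __init__(
        self,
        loci: Sequence[Locus],
        net: nx.Graph,
        degree_bins: Sequence[tuple[int, int]] = DEFAULT_DEGREE_BINS,
    ) -> None:
        self.loci = list(loci)
        node_bin = {v: _degree_bin(d, degree_bins) for v, d in net.degree()}
        self.node_bin = node_bin
        bin_pool: dict[int, list] = {b: [] for b in range(len(degree_bins))}
        for v, b in node_bin.items():
            bin_pool[b].append(v)
        for b in bin_pool:
            bin_pool[b].sort()  # determinism across dict orderings

        self.observed_genes = sorted(
            {g for locus in loci for g in locus.genes if net.has_node(g)}
        )
        self.need: dict[int, int] = {}
        for g in self.observed_genes:
            self.need[node_bin[g]] = self.need.get(node_bin[g], 0) + 1

        # candidate pool per bin, widened where a bin cannot cover demand
        self.pool_for: dict[int, list] = {}
        for b, cnt in self.need.items():
            pool = list(bin_pool[b])
            lo, hi = b, b
            while len(pool) < cnt and (lo > 0 or hi < len(degree_bins) - 1):
                lo, hi = max(lo - 1, 0), min(hi + 1, len(degree_bins) - 1)
                pool = sorted(
                    set().union(*(bin_pool[x] for x in range(lo, hi + 1)))
                )
                logger.warning(
                    "degree bin %d has %d candidates for %d genes; "
                    "widened to bins %d-%d",
                    b, len(bin_pool[b]), cnt, lo, hi,
                )
            if len(pool) < cnt:
                raise ValueError(
                    f"network too small: {cnt} genes needed in degree bin "
                    f"{b}, {len(pool)} candidates even after widening"
                )
            self.pool_for[b] = pool

    def draw(self, rng: np.random.Generator) -> list[Locus]:
        """One degree-matched relabelling of the observed loci."""
        mapping: dict = {}
        used: set = set()
        for b in sorted(self.need):
            pool = [g for g in self.pool_for[b] if g not in used]
            pick = rng.choice(len(pool), size=self.need[b], replace=False)
            chosen = [pool[i] for i in pick]
            used.update(chosen)
            targets = [x for x in self.observed_genes if self.node_bin[x] == b]
            mapping.update(zip(targets, chosen))
        return [
            Locus(
                snp_id=locus.snp_id,
                genes=frozenset(mapping.get(g, g) for g in locus.genes),
            )
            for locus in self.loci
        ]
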