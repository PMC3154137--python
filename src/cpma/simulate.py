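"""Synthetic association matrices and networks for calibration and power.

The generators emulate the sampling model behind cross-phenotype summary
statistics: under the null every SNP-phenotype cell has a standard-normal
signed Z with two-sided p = 2*Phi(-|z|), making p marginally uniform on
(0, 1); under the partial-sharing alternative a chosen number of phenotypes
per SNP receives a mean-shifted Z (the shift direction fixed per phenotype,
mimicking a consistent allelic effect).  Network fixtures are Erdos-Renyi
graphs, optionally with a planted set of loci whose genes form a complete
inter-locus subgraph.

All generators are pure functions of their parameters and a single integer
seed; independent named streams are derived from the seed so the modules can
be tested in isolation without seed collisions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import ndtr

from .core import (
    AssociationCell,
    AssociationMatrix,
    SnpRecord,
    cpma_arrays,
)
from .network import Locus

__all__ = [
    "SimulationSpec",
    "stream_rng",
    "simulate_null",
    "simulate_alt",
    "estimate_type1",
    "simulate_network",
]

# named sub-streams of the user seed (values are arbitrary fixed offsets)
_STREAMS = {"null": 0, "alt": 1, "type1": 2, "network": 3}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for one named stream of a global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


@dataclass(frozen=True)
class SimulationSpec:
    """Partial-sharing alternative: k_assoc of n_phenotypes carry signal.

    ``mu`` is the mean of the associated cells' |Z| shift (dimensionless,
    on the standard-normal scale); ``mu = 0`` collapses to the null.
    """

    n_snps: int
    n_phenotypes: int
    k_assoc: int
    mu: float
    seed: int

    def __post_init__(self) -> None:
        if not (0 <= self.k_assoc <= self.n_phenotypes):
            raise ValueError(
                f"k_assoc must be in [0, {self.n_phenotypes}], got {self.k_assoc}"
            )
        if self.mu < 0:
            raise ValueError("mu must be >= 0")


def _matrix_from_z(z: np.ndarray, prefix: str = "snp") -> AssociationMatrix:
    p = 2.0 * ndtr(-np.abs(z))
    p = np.minimum(p, 1.0)
    n_snps, n_phen = z.shape
    phenotypes = [f"pheno{j + 1}" for j in range(n_phen)]
    width = max(4, len(str(n_snps)))
    records = [
        SnpRecord(
            snp_id=f"{prefix}{i + 1:0{width}d}",
            cells={
                ph: AssociationCell(z=float(z[i, j]), p=float(max(p[i, j], 1e-320)))
                for j, ph in enumerate(phenotypes)
            },
        )
        for i in range(n_snps)
    ]
    return AssociationMatrix(phenotypes=phenotypes, records=records)


def simulate_null(n_snps: int, n_phenotypes: int, seed: int) -> AssociationMatrix:
    """Null association matrix: Z standard normal, p two-sided uniform."""
    if n_snps < 1 or n_phenotypes < 1:
        raise ValueError("dimensions must be positive")
    rng = stream_rng(seed, "null")
    z = rng.standard_normal((n_snps, n_phenotypes))
    return _matrix_from_z(z)


def simulate_alt(spec: SimulationSpec) -> tuple[AssociationMatrix, pd.DataFrame]:
    """Partial-sharing alternative matrix plus per-cell truth labels.

    For each SNP a uniformly random subset of ``k_assoc`` phenotypes gets
    Z ~ Normal(s_j * mu, 1), where the sign s_j is drawn once per phenotype;
    all other cells are null.  Returns the matrix and a boolean SNP x
    phenotype DataFrame marking the truly associated cells.
    """
    rng = stream_rng(spec.seed, "alt")
    z = rng.standard_normal((spec.n_snps, spec.n_phenotypes))
    truth = np.zeros((spec.n_snps, spec.n_phenotypes), dtype=bool)
    signs = rng.choice([-1.0, 1.0], size=spec.n_phenotypes)
    for i in range(spec.n_snps):
        which = rng.choice(spec.n_phenotypes, size=spec.k_assoc, replace=False)
        z[i, which] += signs[which] * spec.mu
        truth[i, which] = True
    am = _matrix_from_z(z)
    truth_df = pd.DataFrame(
        truth, index=am.snp_ids, columns=am.phenotypes
    )
    return am, truth_df


def estimate_type1(
    n_sims: int, n_phenotypes: int, alpha: float, seed: int
) -> tuple[float, float]:
    """Empirical CPMA type-I error rate over null simulations.

    Returns ``(rate, se)`` where ``rate`` is the fraction of ``n_sims``
    null SNPs (each with ``n_phenotypes`` uniform p-values) rejected at
    ``alpha`` and ``se = sqrt(alpha (1 - alpha) / n_sims)`` is the binomial
    Monte-Carlo standard error of the nominal level.
    """
    if n_sims < 1000:
        raise ValueError("n_sims must be >= 1000 for a stable estimate")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    rng = stream_rng(seed, "type1")
    z = rng.standard_normal((n_sims, n_phenotypes))
    p = 2.0 * ndtr(-np.abs(z))
    _, _, log10_p = cpma_arrays(p, axis=1)
    if alpha == 0.0:
        rate = 0.0
    else:
        rate = float((log10_p < np.log10(alpha)).mean())
    se = float(np.sqrt(alpha * (1.0 - alpha) / n_sims))
    return rate, se


def simulate_network(
    n_nodes: int,
    edge_prob: float,
    planted: Optional[tuple[int, int]] = None,
    seed: int = 0,
) -> tuple[nx.Graph, list[Locus]]:
    """Erdos-Renyi network, optionally with a planted connected module.

    ``planted = (n_loci, genes_per_locus)`` selects that many distinct genes
    at random, groups them into loci, and adds every inter-locus edge among
    them (a complete multipartite subgraph), so the loci are maximally
    directly connected against the random background.
    """
    if not (0.0 <= edge_prob <= 1.0):
        raise ValueError("edge_prob must be in [0, 1]")
    rng = stream_rng(seed, "network")
    names = [f"g{i:04d}" for i in range(n_nodes)]
    g = nx.Graph()
    g.add_nodes_from(names)
    if edge_prob > 0:
        upper = np.triu_indices(n_nodes, k=1)
        mask = rng.random(len(upper[0])) < edge_prob
        g.add_edges_from(
            (names[i], names[j])
            for i, j in zip(upper[0][mask], upper[1][mask])
        )
    loci: list[Locus] = []
    if planted is not None:
        n_loci, per_locus = planted
        total = n_loci * per_locus
        if total > n_nodes:
            raise ValueError("planted module larger than the network")
        chosen = rng.choice(n_nodes, size=total, replace=False)
        groups = [
            [names[chosen[i * per_locus + j]] for j in range(per_locus)]
            for i in range(n_loci)
        ]
        for i, genes in enumerate(groups):
            loci.append(Locus(snp_id=f"locus{i + 1}", genes=frozenset(genes)))
        for a in range(n_loci):
            for b in range(a + 1, n_loci):
                for u in groups[a]:
                    for v in groups[b]:
                        g.add_edge(u, v)
    return g, loci
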