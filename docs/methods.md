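# Methods

## The CPMA likelihood-ratio test

For a SNP with `n ≥ 2` non-missing association p-values across phenotypes,
the test models `x_i = −ln p_i` as i.i.d. exponential with rate λ. Under the
null of no additional associations the p-values are uniform and λ = 1; the
alternative is any other rate, fitted by the MLE `λ̂ = n / Σ x_i`. The
statistic

    LRT = 2 [ n ln λ̂ − n + Σ x_i ]  =  2n ( ln λ̂ + 1/λ̂ − 1 )

is referred to χ² with one degree of freedom. The test is two-sided in λ:
an excess of small p-values gives λ̂ < 1, a deficit gives λ̂ > 1, and both
are flagged. LRT = 0 exactly when Σ x_i = n (λ̂ = 1).

Assumptions worth keeping in mind: the per-phenotype p-values of one SNP
are treated as independent, which overlapping control cohorts in real
cross-disease panels violate mildly; and the χ²₁ reference is asymptotic in
nothing — it is exact only in the large-`n` limit, so with `n = 7`
phenotypes the calibration is checked empirically (see the simulation
suite: the type-I error at α ∈ {0.01, 0.05} over 20,000 null SNPs of 7
phenotypes sits within 3 Monte-Carlo standard errors of nominal).

Numerical choices:

- The natural logarithm is used throughout; the null rate of 1 is only
  meaningful on that scale, and it is the scale that reproduces the
  published per-SNP values.
- p-values are clamped to `[1e-300, 1 − 1e-16]` before the transform.
  p = 1.0 occurs in real tables and is legal cell-wise, but an all-ones
  vector would make λ̂ infinite; the clamp bounds it. p ≤ 0 is rejected as
  a domain error upstream.
- The scalar entry point sorts its inputs before summation, so the result
  is bit-identical under any reordering of the p-values.
- Missing cells reduce `n`; nothing is imputed.

## Extreme tails

Published CPMA p-values reach 10⁻¹⁶⁰, far below where a naive
survival-function call underflows, so all tails are computed in log10
space. For 1 df, `sf(x) = 2 Φ(−√x)` via `scipy.special.log_ndtr`; for even
df the closed-form Poisson survival sum is accumulated with `logsumexp`;
odd df ≥ 3 uses the two-step recurrence from df = 1. The implementation
agrees with a 60-digit arbitrary-precision incomplete-gamma oracle to
better than 10⁻⁶ relative error on the log10 value for x up to 1500 (this
is a test, not a claim taken on trust).

The binomial enrichment tail (e.g. 47 significant SNPs out of 107 at a
per-SNP rate of 0.01) is an exact log-space sum of binomial log-pmfs, valid
to n = 10⁴ without underflow of any intermediate.

## Screening policy

`multi_phenotype_screen` exposes two exclusion policies. `none` (default)
uses every non-missing p-value of each SNP. `discovery` removes the
phenotype in which the SNP's association was originally reported, so the
statistic measures evidence *beyond* the known association. Published
per-SNP values are internally mixed on this point — some rows reproduce
under all-phenotype computation, others only after dropping the discovery
disease — so both policies are first-class and the bundled table annotates
the discovery disease where the table's own study reference identifies it
(one annotation, rs12708716 → MS, is reconstructed rather than directly
stated, and is flagged as inferred in the fixture).

Classification rules are strict-inequality throughout: "directional" means
at least one p < 10⁻⁴ effect of each sign; "associated to all" means
p < 0.05 in every phenotype with no missing cell. Both thresholds reproduce
the published counts (9 and 1) on the bundled table, and the boundary
behaviour (a p of exactly 1.1×10⁻⁴ does not qualify) is pinned by a test.

## Evidence binning, Gower distance, Ward clustering

Raw p-values from studies of different sizes are not comparable, so
association strength is reduced to four ordinal classes before any
distance is computed: class 0 for p ≥ 0.05, 1 for [10⁻³, 0.05), 2 for
[10⁻⁶, 10⁻³), 3 for p < 10⁻⁶. Boundary points fall in the weaker-evidence
bin; the convention is arbitrary but fixed and tested. Binning is a
monotone step function of p.

Distances are Gower's coefficient for categorical data: the mean of
per-phenotype mismatch indicators over the phenotypes observed in *both*
SNPs (pairwise deletion; a pair with no shared phenotype is an error rather
than a silent zero). Because the four classes are ordered, an `ordinal`
mode is also provided in which the contribution is |Δclass| / 3. The
categorical mode is the default: it is the treatment of the cited
formulation for categorical variables, and the choice between the two is a
genuinely open design point — both are deterministic and exposed.

Ward agglomeration runs on the Gower matrix through the Lance–Williams
update. Two dialects are provided, mirroring the long-standing split among
implementations: `ward_d` (default) applies the update to the
dissimilarities as given; `ward_d2` applies it to their squares and reports
square-rooted heights. The agglomeration is written in-package because
reproducibility requires an explicit tie-break — on equal merge cost, the
candidate pair whose lexicographically smallest member labels sort first is
merged — which off-the-shelf linkage routines do not expose. On tie-free
Euclidean data the `ward_d2` partition matches `scipy.cluster.hierarchy`
exactly (a cross-check in the test suite). Cutting the tree at k keeps the
first n−k merges; the k-partition always refines the (k−1)-partition.

On the bundled table at k = 4, the two chromosome-4q27 SNPs — rs4505848
(IL2, a T1D-driven signal) and rs6822844 (IL2/IL21, a coeliac/RA-driven
signal) — fall in different clusters under both Ward dialects, the one
cluster-membership fact the published analysis states explicitly.

Cluster-by-disease summaries combine member SNPs' p-values per disease with
Fisher's omnibus statistic `S = −2 Σ ln p ~ χ²(2N)`. A cluster with no
observed value for a disease yields an undefined (NaN) summary, not a
dropped row. For N = 1 the combination is the identity, exact to 10⁻¹².

## Network connectivity test

Each associated SNP contributes a locus: the set of genes whose intervals
overlap the SNP's genomic span by at least one base (1-based, fully closed
coordinates; adjacency is not overlap). Spans are supplied by the user —
defining them from linkage disequilibrium is out of scope. For the loci of
one cluster and an undirected protein-interaction network, two counts are
taken: *direct* — edges joining genes that share no locus (within-locus
edges say nothing about between-locus biology and are excluded); and
*common-intermediary* — unordered gene pairs sharing no locus that have at
least one common network neighbour, the intermediary being any node.

Significance is by permutation: each observed network gene is relabelled
with a gene drawn uniformly, without replacement within a permutation, from
the same degree bin (bins 1–4, 5–9, 10–49, 50–99, ≥100), keeping the locus
structure intact; 4000 permutations by default; empirical p =
(1 + #{null ≥ observed}) / (B + 1), so p is bounded below by 1/(B+1) and
never zero. A bin too small for its demand is widened to adjacent bins with
a logged warning. This is a deliberately simplified node-relabelling
variant of the DAPPLE family of within-degree permutation methods: binned
rather than exact-degree matching, and gene-level rather than locus-level
permutation. It preserves the degree profile of the observed set (asserted
by a test) but not each gene's exact degree; results should be read as a
self-contained permutation test, not as a reimplementation of any specific
published pipeline.

## Synthetic data

`simulate_null` draws Z from the standard normal and sets p = 2Φ(−|z|), so
the (z, p) coupling matches real summary tables and p is marginally
uniform (Kolmogorov distance < 0.01 on 10⁵ draws, tested).
`simulate_alt(n_snps, n_phenotypes, k_assoc, mu)` gives each SNP a random
subset of `k_assoc` phenotypes with Z ~ Normal(±μ, 1), the sign fixed per
phenotype to mimic a consistent allelic effect; truth labels are returned
alongside. The calibration default mirrors the motivating study design —
7 phenotypes — and the power-demonstration settings (μ = 4, 3 of 7
phenotypes shared, 2000 SNPs) correspond to a clearly detectable but not
saturated effect size on the Z scale.

What the generators do *not* emulate: linkage disequilibrium between SNPs,
shared controls across studies (which correlate p-values of one SNP across
phenotypes), and genomic inflation. Passing calibration tests therefore
demonstrates correctness of the statistic under its stated independence
assumptions, not robustness to cohort-overlap correlation.

All generators are pure functions of (parameters, seed); a single integer
seed feeds independent named streams (null / alt / type1 / network) so no
two generators ever consume the same random draws.

## Problem sizes in the test and acceptance runs

Type-I calibration uses 20,000 null SNPs of 7 phenotypes (vectorized, about
a second); rate recovery uses n = 1000 exponential draws; the planted-module
network test uses a 200-node background at edge probability 0.02 with four
2-gene loci and 4000 permutations; the screening surrogate uses a 107-SNP
panel (47 with signal). These sizes give Monte-Carlo standard errors
comfortably inside the asserted bounds while keeping the full suite under
half a minute.

## Known limitations

- The χ²₁ reference for the LRT is asymptotic; at very small `n` (2–3
  phenotypes) the finite-sample null is visibly discrete in λ̂ and the
  nominal level is approximate.
- The published per-SNP value for rs2476601 (printed 6.3×10⁻¹⁶⁰) is not
  recoverable from the printed two-significant-figure inputs (whose own
  rounding shifts the result by orders of magnitude at that depth); the
  bundled table records the printed value, and the recomputation tolerance
  on the other rows absorbs input rounding of a few percent.
- Fisher's omnibus assumes independent p-values; clusters of SNPs in LD or
  diseases with shared controls violate this and inflate `S_cum`.
- The network test's degree bins are a coarse degree match; hub-adjacent
  biases are reduced, not removed.
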