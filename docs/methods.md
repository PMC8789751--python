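# Methods

## Scope and data model

`gcrep` analyzes paired single-cell gene-expression and B-cell-receptor
(BCR) data from germinal center (GC) B cells. Inputs are 10x-style contig
annotation CSVs (one row per assembled V(D)J contig, extended with a
per-chain V-region germline-identity column), MatrixMarket UMI count
matrices with barcode/feature sidecars, a per-cell annotation table
carrying donor and cluster labels, and GMT gene-set collections. Upstream
steps — alignment, contig assembly, germline alignment itself, clustering
and embedding — are out of scope: cluster labels and per-chain identity
percentages are consumed as inputs (or simulated). The 14 expected
clusters (DZ-1..3, INT-1..4, LZ-1..3, FCRL2/3, PreM, PBL-1, PBL-2) are
grouped as DZ = {DZ-1..3, INT-1}, LZ = {INT-2, INT-4, LZ-1..3},
MP = {INT-3, PreM, FCRL2/3}, PBL = {PBL-1, PBL-2}; the mapping is
overridable.

## QC and pairing

A cell passes QC iff (a) its barcode appears in the expression matrix, (b)
after removing contigs that are not (productive ∧ full-length ∧
high-confidence ∧ UMIs > 3), exactly one heavy (IGH) and one light
(IGK/IGL) contig remain, and (c) the heavy constant gene is neither empty
nor IGHD. The UMI threshold is strict (`umi_min = 4`) and applies to both
chains; it is a parameter because per-chain vs heavy-only scoping is a
judgment call. Failing cells are dropped silently but tallied per rule in
an audit counter whose reasons are checked in a fixed order
(expression → heavy count → light count → constant gene), so each dropped
cell has exactly one reason and `kept + Σ dropped = distinct barcodes`.

Per-cell germline identity is the unweighted arithmetic mean of the heavy
and light V-region identities. No V-region length is available in the
input dialect, so the alternative combiner exposed is a convex weight on
the heavy chain (`heavy_weight = 1` gives heavy-only), not a
length-weighted mean. Identity bins are left-closed — B100 is the exact
point mass at 100%, then [98,100), [96,98), [94,96) and <94 — which makes
the five bins a partition of [0,100] and keeps the textual strata
"≥98%" = B100∪B98 and "<94%" = B_LT94 consistent.

## Clonotypes

Cells belong to the same clonotype iff they share, within one donor, the
same heavy V/D/J and light V/J gene-level calls and an identical
concatenated heavy+light CDR3 nucleotide string (exact match; no distance
threshold, no allele handling — the empty D call matches itself). Clone
ids are deterministic (descending size, then lexicographic key), so the
partition is invariant to input order. Intraclonal isotype heterogeneity
is the fraction of clones with at least `min_size = 5` members whose
members span ≥ 2 isotype *classes*; IGHG1 vs IGHG2 is homogeneous, since
the statistic is meant to witness class switching, not subclass usage (a
`level="subclass"` mode exists). With no eligible clone the fraction is
NaN, not an error.

## Enrichment statistics

Composition tests treat each cluster × category pair as an urn problem:
k of the cluster's n cells fall in a category that covers K of the N
pooled background cells. Enrichment is the exact upper tail P(X ≥ k) and
depletion the lower tail P(X ≤ k) of Hypergeometric(N, K, n); both tails
include the point mass at k, so p_enrich + p_deplete ≥ 1. Tails are
computed by log-space evaluation of the pmf (gammaln) with terms rescaled
by the modal term and accumulated from the far end of the tail inward;
against exact big-integer enumeration the worst relative error over all
parameter combinations with N ≤ 60 is ~1e-13, and accuracy degrades only
slowly with N (≥ 10 significant digits through N ~ 1e5). Benjamini–
Hochberg correction (statsmodels' step-up implementation behind
`bh_adjust`) is applied separately to the enrichment and the depletion
family; by default one family spans all cluster × category tests of a run
— the most conservative natural scope — with a per-category option. Flags
are assigned at q ≤ 0.05. Pathway enrichment uses the same upper tail on
signature/set overlaps after intersecting everything with the supplied
universe.

The background for composition tests pools donors, matching how the
repertoire summaries are usually drawn; a per-donor stratification can be
had by running donors separately.

## Expression summaries

Counts are normalized per cell to a common library size (10⁴); log2(1+x)
is applied on demand, never stored. All-zero cells are removed with an
audit count. Differential expression is a per-gene two-sided Wilcoxon
rank-sum test on log2(1+normalized) with BH correction — a deliberate
substitution of a robust rank test for a hurdle-model engine, which is why
the DE guarantees here are property-based (spike recovery, null
calibration) rather than coefficient reproduction. Fold change is the
linear-scale ratio of group means with a pseudocount of scale/1000 (= 10
at the default scale) stabilizing low-expression ratios; the reporting
filter keeps genes with fold change ≥ 1.2 in either direction, detection
(fraction of cells with a nonzero count) ≥ 25% in at least one group, and
q ≤ 0.05. Dot-plot summaries report percent detected and the per-gene
z-score of mean log2 expression across the clusters included in the call;
zero-variance genes get z = 0 by convention.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
the study's scale: 40,000 cells across 3 donors with equal allocation.

**Cluster proportions** (DZ-1 .12, DZ-2 .10, DZ-3 .08, INT-1 .10, INT-2
.09, INT-3 .02, INT-4 .08, LZ-1 .13, LZ-2 .10, LZ-3 .07, FCRL2/3 .02,
PreM .04, PBL-1 .03, PBL-2 .02) mimic the relative cluster sizes of a
tonsillar GC cohort; exact per-cluster counts are a free choice
constrained only by the pooled marginals.

**Identity model.** Each cell draws an identity bin from its cluster's
mixture, then a value: 100 exactly for B100, uniform within [98,100),
[96,98), [94,96), or [71,94) otherwise (identities are confined to
[71,100]). The PreM mixture is fixed to the bimodal published pattern
(36% unmutated, 13% in [98,100), 51% mutated of which 18% < 94); INT-3 is
almost exclusively ≥ 98%; FCRL2/3 is high-identity-shifted; PBL is mutated
but depleted below 94% (17%). The nine bulk DZ/LZ clusters share one
weight vector solved in closed form so the pooled mixture equals
(B100, B98, B96, B94, B_LT94) = (.02, .13, .29, .24, .32) — the anchors
2% unmutated, 15% ≥ 98%, 32% < 94%, and a B94 weight of .24 that places
the pooled median at 94 + 2·(0.50−0.32)/0.24 = 95.5%. The solved bulk
vector (~.002, .103, .299, .249, .347) independently reproduces the
published ~34% < 94% in the bulk compartments. The per-cell identity is
then decomposed into heavy/light values as target ± uniform(−0.5, 0.5)
jitter (clipped near the range ends) so the unweighted mean recovers the
target exactly, making the combiner testable independently of the
generator; identities are written at full float precision so bin
boundaries are not perturbed by round-off.

**Isotype model.** Fixed per-cluster class probabilities for PreM
(.54/.30/.16 for M/G/A), INT-3 and FCRL2/3 (.78/.13/.09) and PBL
(.08/.71/.21); the bulk vector is again solved in closed form from the
pooled anchors (M .24, G .43, A .33). IGHE has probability 0 everywhere
but remains a first-class category (classified, tabulated as a zero row).
Subclasses are uniform within class.

**Clonal model.** Within each (donor, cluster) stratum, cells are
partitioned into clones with sizes from a geometric law truncated at 30;
the geometric success probability is √0.74, which makes the expected
fraction of cells in singleton clones 0.74 (mid-range of the published
62–86% per-donor band). Clone members inherit the founder's V/D/J calls
and CDR3s; each non-founder independently experiences one irreversible
switch event with p_switch = 0.09 (IGHM → IGHG with probability 0.6 else
IGHA; IGHG → IGHA; IGHA terminal), sized so that roughly a fifth of
size-5 clones end up class-heterogeneous once unswitchable IGHA founders
are accounted for. Founder classes are drawn from a switch-kernel-inverted
distribution so the realized post-switch per-cluster class marginals equal
the profile's probabilities in expectation. Clones are confined to one
cluster; this keeps per-cluster repertoire marginals exactly as
parameterized at the cost of not modeling cross-state clone spread.

**Expression model.** 400 genes (10 hallmark genes — CXCR4/AICDA up in the
DZ clusters, CD83/BCL2A1 in the LZ clusters, CCR6/CELF2 in PreM,
PRDM1/FKBP11 in PBL, FCRL2/FCRL3 in FCRL2/3 — at a 6× mean fold-up in
their designated clusters, plus filler genes) with gamma-Poisson
(negative-binomial) counts at baseline mean 0.3 and dispersion 0.5. The
gene count and baseline are sized so a full cohort generates in seconds
while leaving detection rates and rank tests well-behaved.

**Contaminants.** 2% of cells are injected with QC violations cycling
through five classes — a second eligible heavy contig, a heavy chain at
≤ 3 UMIs, an IGHD constant gene, a non-productive heavy chain, and a
barcode absent from the expression matrix — with the expected audit reason
logged per cell, so the filter audit can be checked for exact agreement.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: transcriptome covariance and batch/cell-cycle
structure (normalization here is library-size only by design), sequence-
level SHM (identities are drawn, not mutated into sequences), cross-
cluster clonal spread, doublets beyond the listed contaminant classes,
donor-specific repertoire biases, and any coupling between mutational load
and isotype within a cluster (the published PreM identity–isotype
correlation is represented only at the cluster-marginal level).

## Numerical and degenerate-input conventions

Ambiguous square expression matrices are read in the genes × cells (10x)
convention. Empty clusters yield n = 0 records with p = 1 and no flag.
Zero-variance genes get z = 0. Constant genes get p = 1 in DE. BH on an
empty vector returns empty. A heterogeneity denominator of zero returns
NaN. Hypergeometric tails return exactly 1.0 and 0.0 outside the support.
Seeds drive a single `numpy` Generator per cohort, so equal profiles give
byte-identical output files.

## Known statistical limitations

At the default scale, PreM holds ~1,570 QC-passing cells, so PreM-restricted
fractions carry a binomial standard error of ~1.2 percentage points — and
the shared clone-founder isotype draw inflates the sd of the PreM IGHM
fraction to ~1.9 points. Single-cohort point estimates of those statistics
therefore scatter by ±2–4 points across seeds even though the generator is
unbiased (verified over 20 seeds). Similarly, the truncated-geometric
clone-size law combined with a 0.74 singleton-cell fraction yields only
~a dozen clones of ≥ 5 cells per 40,000-cell cohort, so the intraclonal
heterogeneity fraction is a noisy statistic at this scale; its calibration
is analytic (via p_switch), not empirical.
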