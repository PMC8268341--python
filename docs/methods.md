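# Methods

## Scope and data model

`kea` infers differential kinase activity from site-level label-free
phosphoproteomics. The unit of quantification is a localized phosphosite:
a (gene, residue ∈ {S, T, Y}, position) triple, kept separate per
phospho-multiplicity (the MaxQuant `___1/___2/___3` intensity columns)
under keys of the form `GENE_Y207_m1`. Multiplicity forms of one residue
are distinct analytes by default because they can respond differently to a
perturbation; `preprocess.merge_multiplicity` collapses them when a user
prefers one row per residue. Rows collapsing to the same key (for example
fraction files of one sample, parsed separately and concatenated) have
their intensities summed on the linear scale, which preserves total ion
signal; the best localization probability and the OR of the quality flags
are kept for the collapsed row. MaxQuant encodes "not quantified" as 0, so
zeros are read as missing. For multi-protein site groups the leading entry
is used, following the MaxQuant convention.

## Preprocessing

The chain is: filter → log2 → quantile normalization → drop
under-quantified rows → missingness classification → imputation.
Filtering removes contaminant and reverse (decoy) rows and sites with
localization probability below 0.75 (the boundary value is kept).
Rows with at most one observed value carry no testable information and are
dropped before imputation.

Quantile normalization runs before imputation, so it must tolerate missing
cells: ranks are computed among each column's observed values, and the
reference distribution is the mean of the columns' empirical quantile
functions interpolated to a common grid of `n_rows` probabilities. With
complete data this is exactly the textbook sort/row-mean/restore procedure
(and therefore idempotent); tied values receive the mean of their tied
reference values, which makes the result deterministic.

Missingness is classified per (site, condition): with one of n replicates
missing the cell is treated as missing at random (MAR, sporadic dropout);
with two or more missing as missing not at random (MNAR, systematic
left-censoring of low-abundance sites). For triplicates this is the
1-of-3 / ≥2-of-3 rule.

Imputation never alters observed cells.

* **MAR** cells are filled with their conditional expectation under a
  multivariate normal over the condition's replicates, fitted by
  expectation-maximization on the condition's complete and MAR rows
  (moment initialisation from observed margins; at most 100 iterations;
  convergence when the observed-data log-likelihood improves by less than
  1e-6; a 1e-8 ridge keeps covariances invertible).
* **MNAR** cells are drawn independently from Normal(q, σ) with q the
  0.01-quantile (probability 0.01, i.e. the first percentile) of the
  sample's observed values and σ = 0.3 × the sample's observed standard
  deviation — the MinProb left-censoring model. The width factor 0.3 keeps
  draws in the censored tail without collapsing them to a constant; it is
  configurable (`minprob_sigma_scale`).
* In the alternative `zero` mode MNAR cells are set to 0 instead, giving
  extra weight to sites present in only one condition; MAR cells are still
  filled by EM.

All draws come from one seeded generator, so a fixed seed reproduces the
imputed matrix bit for bit.

## Differential testing and ranking

Each site is tested with Welch's unequal-variance t-test (two-sided,
Welch–Satterthwaite degrees of freedom); sites with fewer than two usable
values in either group are dropped with a logged count. For one-vs-rest
designs (one cell line against the average of the others) the default
pools all non-target replicates into a single reference group, preserving
the within-group variance the test needs; a `mean_of_means` alternative
uses per-condition means as reference observations instead.

A known small-sample property: at three replicates per group the
Welch–Satterthwaite approximation makes the null p-value distribution
deviate slightly from uniform (Kolmogorov–Smirnov distance ≈ 0.025 at
10,000 sites; at five replicates it is within 0.02). This is inherent to
the plain Welch test, not a numerical issue, and it affects absolute
site-level calibration far more than the enrichment, which depends only on
the ranking.

The full site universe is then ordered by the signed score
sign(log2fc)·(−log10 p), descending for the over-activity ranking and
ascending for the under-activity ranking — no cutoff, so both directions
rank the same universe. Ties break by |log2fc| descending and then site
key, making the order independent of input row order. This signed-score
choice places strongly over-expressed sites at the top of the over-ranking
and is exactly antisymmetric: negating all fold changes swaps the two
rankings (and, with a shared seed, the two result tables).

## Kinase–substrate meta-database

Experimental associations are parsed from snapshots of five public
resources (PhosphoSitePlus, HPRD, RegPhos, Signor, phospho.ELM), with
column dialects and species/mechanism filters described in a shipped
configuration (`resources/source_columns.yaml`) so snapshot format drift
is absorbed without code changes. Kinase name redundancy across resources
is resolved through a curated, user-replaceable synonym table; unmapped
names pass through with a warning. Duplicate (kinase, substrate) pairs
merge with a source-set union, and kinases left with a single association
are removed — one substrate cannot support an enrichment. NetworKIN
predictions are layered on per experiment, restricted to the measured site
universe and a configurable score threshold (default 2.0, a permissive
common choice — results depend on it, so it is surfaced prominently);
experimental evidence takes precedence on conflicts, and the single-entry
rule is re-applied after the merge. Database substrates carry no
multiplicity, so matching against the matrix is on the base
(gene, residue, position) key. No third-party database content is bundled;
tests and examples use synthetic fixtures written in each source dialect.

## Enrichment

Each kinase's substrate set is intersected with the measured universe;
sets below `min_set_size = 2` are dropped (consistent with the
single-entry rule). The primary statistic is the exact minimum
hypergeometric (mHG) test: over every prefix length t of the ranked list,
the hypergeometric upper-tail probability of the observed substrate count
in the top t is computed, and the statistic is the minimum tail. Its exact
null probability is obtained by a dynamic program over monotone lattice
paths from (0,0) to (N,K) — each path is one of the C(N,K) equally likely
substrate placements; mass entering the rejection region
{(n,k) : tail(n,k) ≤ s} is absorbed, and the p-value is one minus the
surviving mass. No Bonferroni-over-cutoffs approximation is used; the DP
is validated against exhaustive enumeration for all N ≤ 12, K ≤ 4. A
cutoff-free ranked test matches the pipeline's no-cutoff rankings; the
statistic is pluggable should a fixed-cutoff Fisher variant be wanted for
comparison.

Overlap elimination operates on the sets with primary p ≤ 0.01
(`set_p_cutoff`). For every ordered pair (A, B) with intersecting members,
B's p-value is recomputed on B∖A with A's members deleted from both the
set and the universe; losing significance adds the edge A→B ("B is
explained by A"). Mutually explaining pairs need a tie-break — if B is A
plus one noise site, removal in either direction kills the other, and
applying the rule symmetrically would discard both. In that case only the
stronger set (smaller primary p, ties by name) keeps its explaining edge.
A node is discarded only when removing the union of all its in-neighbors'
members destroys its significance, so a set explained in part by several
neighbours but with independent signal survives. The procedure is
deterministic and independent of set input order.

Retained significant sets are scored by PageRank (damping 0.85, power
iteration to 1e-10) on the reversed dependence graph, so sets that explain
others accumulate score; an edgeless graph gives uniform scores and scores
sum to one.

Family-wise correction is Bonferroni over the number of sets tested. The
per-kinase FDR is Monte-Carlo: `b_null = 100` seeded random permutations
of the ranked list (one shared permutation per replicate, preserving the
sets' overlap structure), and FDR(p) = mean null count of sets with
p-value ≤ p divided by the observed count, clipped to [0, 1]. Kinases are
reported at primary p ≤ 0.01 and FDR ≤ 0.05. Fewer than 10 permutations
triggers an instability warning. Both directions run with the same seed,
which is what makes the over/under outputs exactly antisymmetric under
fold-change negation.

## Synthetic data generator

The generator emulates the data model above: site log2 intensities are
Gaussian per site (baseline mean 23, SD 2 — typical MaxQuant log2 ranges)
with replicate noise SD 0.5; kinases own disjoint substrate blocks;
"active" kinases shift their substrates by ±1.5 log2 units in the test
condition. Defaults describe a triplicate two-condition experiment with
2,000 sites and 50 kinases × 15 substrates, 3 of them active. Quality
artefacts are injected at realistic rates (2% contaminant, 2% reverse, 10%
poorly localized). MAR dropout is uniform per cell (5%); MNAR dropout is
logistic in the cell's log2 intensity — the left-censoring picture that
justifies MinProb — with midpoint at the 0.005 baseline quantile and slope
6 per log2 unit. The slope was set by the design requirement that
single-replicate MNAR dropout (which the count-based classifier must call
MAR) affect under 1% of (site, condition) pairs; measured ambiguity at
these defaults is ≈ 0.5%, and the ≥ 99% label agreement is asserted in the
tests. Written files round-trip bit-exactly through the parsers (floats
are serialized with full `repr` precision).

What the generator does not emulate: correlated substrate responses beyond
the planted mean shift, shared substrates between kinases (sets are
disjoint unless constructed otherwise), peptide-level identification
error, batch effects, and abundance-dependent variance. Passing the
recovery tests therefore demonstrates correctness of the inference
machinery under the stated model, not performance on real spectra.

## Problem sizes and numerical choices

Simulation-based tests and the acceptance script use 2,000-site, 43-kinase
experiments (3 active + 40 decoys, 20 substrates each) with 25 seeds for
recovery and 20 for null calibration — large enough that the planted
effect dominates sampling noise while a full run stays in seconds. The
exact-p validation enumerates all placements up to N = 12, K = 4 (≈ 10⁴
cases). Degenerate inputs are handled explicitly: zero-variance identical
groups give t = 0, p = 1; empty reduced sets in overlap elimination give
p = 1; single-sample matrices skip normalization with a warning; samples
with fewer than two observed values are a hard error (their MinProb
quantile is undefined).

## Known limitations

Kinase-level inference is bounded by database coverage and biased toward
well-studied kinases; predictions raise coverage but can add false
associations. Phosphatases are not modelled. There is no protein-level
normalization of phosphosite changes and no batch correction. The FDR
estimate is a permutation approximation whose resolution is limited by
`b_null`. At triplicate scale, site-level Welch p-values are slightly
miscalibrated (see above).
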