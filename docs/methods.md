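# Methods

This note documents the models, parameter choices and numerical
conventions behind `chemovar`, and what the synthetic-data validation
does and does not establish about real lab data.

## Data model

A *sample* is one lab-tested flower submission: per-compound cannabinoid
(acid + neutral) and terpene measurements plus lab, producer, strain
name and a commercial category label (Indica/Hybrid/Sativa/Unknown). A
*product* is the mean profile over all samples sharing a (producer,
strain name) pair; product chemotype is assigned from the *mean* total
THC and CBD, not from per-sample majorities.

## Harmonization

Units are converted to % weight (ppm ÷ 10,000; mg/g ÷ 10). Labs that
report ocimene (α, β, cis, trans) or nerolidol (cis, trans) isomers
separately have them summed into single columns; a group whose members
are all null yields null, because an unmeasured compound is not a
measured zero. Cross-lab analysis uses the intersection of lab panels:
6 total cannabinoids (THC, CBD, CBG, CBC, CBN, THCV) and 14 terpenes
(α-/β-pinene kept separate here; they are summed as "pinene" only in
the eight-terpene polar-plot summary, never in the analysis panel).

## QC filters

Row-removal rules, applied sequentially so per-rule counts are disjoint
and additive: exact duplicates (identical on every measurement column
plus producer and strain name; first occurrence kept, so row order
cannot change which rows survive) → any single cannabinoid > 40 %wt
(strict; applied to raw acid or neutral columns after unit conversion)
→ summed total cannabinoids > 50 %wt → both total THC and total CBD
null-or-zero. Terpene rules invalidate terpene data without dropping
the row: row variance (population variance, ddof = 0; the convention is
immaterial for the all-equal degenerate rows the rule targets) below
0.001 → any single terpene > 5 %wt → more than 10 zeros among the 14
panel values, with nulls counted as zeros (consistent with zero-filling
nulls before multivariate analysis). Already-invalid rows are skipped,
making the pass idempotent. The 40 % cap is applied to every reported
cannabinoid column rather than to computed totals; this is the stricter
reading and is exposed as a parameter for sensitivity analysis.

## Total cannabinoids and chemotypes

total = factor × acid + neutral, with factor 0.877 (molecular-weight
ratio of neutral to acid form) for THC, CBD, CBG, CBC and CBN and
0.8668 for the propyl (varin) cannabinoids THCV/CBDV. A null acid or
neutral is treated as 0 unless both are null. Chemotype is a pure
function of the THC:CBD ratio — THC-dominant at ratio ≥ 5, CBD-dominant
at ratio ≤ 1/5, Balanced between — with both boundaries inclusive of
the dominant class and a zero CBD giving an infinite ratio
(THC-dominant). The classifier is scale-invariant by construction.

## Chemometrics

Profiles are normalized to shares of the measured common panel (nulls
zero-filled; all-zero rows flagged and excluded from ratio analyses).
PCA is centered but unscaled — the shares are already commensurate —
with a fixed sign convention (largest-magnitude loading positive) so
runs are comparable. Spearman correlation uses midranks for ties and
pairwise-complete observations; p-values are exact permutation
enumerations for n ≤ 8 and the t-approximation above (10! enumeration
buys nothing at the panel sizes involved). Multiple-comparison control
is Bonferroni throughout; for the 14-terpene matrix m = 91. Display
ordering of the correlation matrix is average-linkage clustering on
Euclidean distances between correlation-matrix rows (standard
clustermap behavior); no clusters are cut from the dendrogram. The
co-occurrence network keeps edges with signed coefficient ≥ 0.10
(inclusive), retaining isolated nodes. MAD outlier masking uses the
modified z-score 0.6745(x − median)/MAD at threshold 3.5, flagging
nothing when MAD = 0.

Group comparisons use Welch's unequal-variance t-test (two zero-variance
groups with equal means return t = 0, p = 1 by convention) and the
equal-weight-variance effect size d′ = (x̄₁ − x̄₂)/√((s₁² + s₂²)/2) with
sample variances. Category enrichment uses Pearson's chi-squared
goodness of fit against the overall labeled-population proportions,
restricted to categories actually present (an absent category would
force a zero expected count).

## Clustering and silhouette analysis

K-means runs on normalized terpene shares with k-means++ seeding, 10
restarts and a 1e-6 relative tolerance; cluster indices are relabeled
by descending size (I, II, III) and characterized by their top-2 mean
polar-profile terpenes. The elbow scan reports the WCSS curve plus an
advisory maximum-curvature k; the pipeline default k = 3 is a config
value, not hard-coded. Silhouette coefficients use Euclidean distance
with singleton labels (and coincident points under different labels)
scoring 0; system means always come from the full filtered data.
Samples labeled "Unknown" are dropped from the commercial-label system
only — the other systems keep the full row set, and the per-system
Welch/d′ comparisons therefore run on slightly different row sets,
matching the intent that each system is scored on the rows it labels.
UMAP (2 components, 15 neighbors, fixed seed) is provided for
qualitative display only.

## Consistency nulls

Strain eligibility requires ≥ 5 producers each contributing ≥ 5 samples
to the name. Per-product consistency is the mean cosine similarity to
the *other* products of the same strain (self-similarity excluded, so
the average is not inflated). The shuffled-name null permutes the
strain-name column over product rows without replacement — preserving
name multiplicities — and per replicate recomputes each randomized
name's mean similarity, then averages across names weighted by product
count; 200 replicates by default. Each observed strain's product
similarities are compared to the replicate vector with Welch's t and
d′, Bonferroni over the number of eligible strains. Similarity is
computed on the same normalized 14-terpene representation used for
clustering (exposed as a parameter). The top-cluster-share null
averages the randomized strains' modal-cluster percentages unweighted
per replicate; modal ties break to the lowest cluster label.

## Synthetic generator

The generator defines the study conditions for all recovery tests.
Defaults: 3 labs cycling the three unit dialects and alternating isomer
dialects; 30 producers × 24 strains with 2–6 samples per product;
chemotype proportions (0.965, 0.022, 0.014) — the observed commercial
shares at printed precision, renormalized internally since they sum to
1.001 — drawn i.i.d. per sample; terpene-cluster proportions
(0.45, 0.43, 0.12), placing ~88 % of THC-dominant mass in clusters
I + II as observed commercially; label fidelity 0.7; strain consistency
0.9; 10 % Unknown labels.

Cannabinoid totals are class-consistent by construction: each sample's
THC:CBD ratio is drawn log-uniformly inside its class's ratio region
(with point masses at ratio 0 and ∞), levels are log-normal and clipped
inside the QC caps, and totals are split into acid/neutral pairs at an
85–95 % acid fraction via the exact decarboxylation factors, so latent
chemotypes are recovered exactly by the classifier. Terpene profiles
are log-normal perturbations around cluster mean vectors (nonnegative
and right-skewed, like real panels): sample-level log-sd 0.25 plus a
product-level random effect of log-sd 0.15 that makes same-product
samples cohere; the α/β-pinene and caryophyllene/humulene pairs share a
latent factor (correlation 0.8), reproducing the positive correlations
their shared biosynthesis produces in real data; CBG is positively
coupled to terpinolene within the terpinolene cluster. Balanced and
CBD-dominant samples draw a single myrcene-dominant profile, mirroring
the lower terpene diversity of high-CBD material. Within-cluster
covariance is a free parameter of the model and is exposed in config.

Contaminant spiking clones distinct existing rows, modifies them in the
batch's own unit and dialect so each trips exactly one QC rule, and
records the spiked IDs; audit tests then require per-rule filter counts
to equal spike counts *exactly*.

What passing these tests shows: the pipeline's bookkeeping,
formulas and statistics are correct, and the analysis recovers known
structure under realistic noise. What it does not show: that real
commercial data has this structure — real panels have lab-specific
quantitation limits, batch effects, missing terpene blocks (terpene
testing is often optional), and concentration distributions the
generator does not attempt to match beyond class structure and
correlation signs.

## Problem sizes

The recovery tests run at ~20,000 samples (50 producers × 40 strains ×
8–12 samples), where three binomial standard errors on the rare-class
shares are still informative and full-dataset silhouette comparison is
comfortable on a single core; null-calibration tests use 100 simulated
strains of 6 products with 200-replicate nulls, with an exhaustive
8-product permutation oracle validating the bootstrap's expectation.

## Known limitations

Lab metadata (quantitation limits, method detection differences) is not
modeled; the pipeline treats all labs as exchangeable after unit
conversion. The elbow heuristic is advisory and discrete; for k-curves
without a clear knee the suggested k is not meaningful. The
shuffled-cluster null conditions on the observed cluster-size
composition, not on a model of cluster assignment. Popularity metrics
and any genotype linkage are out of scope.
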