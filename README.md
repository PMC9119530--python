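# chemovar

Chemotaxonomic analysis of commercial *Cannabis* lab-testing data.

Commercial cannabis is marketed with labels — "Indica" / "Hybrid" /
"Sativa" categories and colloquial strain names — that purport to
predict a product's character. Testing labs, meanwhile, quantify the
actual chemistry: cannabinoids (THC, CBD, CBG, CBC, CBN, THCV, each as
an acid + neutral pair) and a panel of terpenes. `chemovar` is a
pipeline for asking, quantitatively, how well those labels align with
the measured chemistry across many labs, producers and states. It is
aimed at researchers working with aggregated compliance-testing data
and at anyone who wants a tested reference implementation of this style
of chemometric label-validity analysis.

## What it computes

**Harmonization and QC.** Per-lab tables (in % weight, ppm, or mg/g,
with lab-specific isomer-reporting dialects) are converted to % weight,
ocimene/nerolidol isomers are summed, and compound panels are
intersected to the 6 common cannabinoids and 14 common terpenes.
Conservative plausibility filters then remove duplicate rows, any row
with a single cannabinoid over 40 %wt, summed total cannabinoids over
50 %wt, or both total THC and total CBD null/zero — and invalidate
terpene data with row variance below 0.001, a single terpene over
5 %wt, or more than 10 zeros among the 14 terpenes — with exact
per-rule audit counts.

**Chemotyping.** Total cannabinoid levels assume complete
decarboxylation:

    total = 0.877 × acid + neutral        (THC, CBD, CBG, CBC, CBN)
    total = 0.8668 × acid + neutral       (THCV, CBDV)

Samples are classed by THC:CBD ratio: THC-dominant at 5:1 or higher,
CBD-dominant at 1:5 or lower, Balanced in between.

**Clustering and label validity.** Terpene profiles are normalized to
shares of the measured panel, ordinated with PCA, correlated pairwise
(Spearman, Bonferroni over 14·13/2 = 91 comparisons, average-linkage
ordering, co-occurrence network at the ≥ 0.10 threshold), and segmented
with k-means (elbow-selected k, default 3). Labeling systems are scored
with the silhouette coefficient s = (b − a)/max(a, b) and compared with
Welch's t and the effect size d′ = (x̄₁ − x̄₂)/√((σ₁² + σ₂²)/2).

**Strain consistency.** Samples are averaged into products per
(producer, strain name). For strains linked to ≥ 5 producers with ≥ 5
samples each, between-product cosine similarity is tested against a
200-replicate shuffled-name bootstrap null, and each strain's
top-cluster share against the analogous shuffled-cluster null, with
chi-squared tests for category enrichment within clusters.

**Synthetic data.** A first-class generator produces multi-lab datasets
with the structure the analysis assumes — the three-chemotype mixture,
three latent terpene clusters (high caryophyllene-limonene, high
myrcene-pinene, high terpinolene-myrcene), producer/strain nesting,
unit and isomer dialects, and contaminant rows that exercise every QC
rule — together with the latent ground truth, so the whole pipeline
runs and is validated with no external download.

## Worked example

```sh
chemovar run-all --seed 3 --out report.json
```

runs the full pipeline on a default synthetic dataset and prints, for
example:

```
chemovar pipeline report (seed 3, config 00a3be9e06e65c78)
samples after QC: 1428 (1428 with valid terpene data)
chemotype shares:
  THC-dominant: 96.6%
  Balanced: 1.8%
  CBD-dominant: 1.7%
terpene clusters:
  Cluster I: n=788, high caryophyllene-limonene
  Cluster II: n=528, high myrcene-pinene
  Cluster III: n=63, high terpinolene-myrcene
label-system mean silhouette:
  kmeans: 0.681
  dominant_terpene: 0.355
  commercial: 0.195
strain consistency: 12 eligible strains, shuffled-name null mean 0.780
```

Reading it: the chemotype shares recover the generator's configured
mixture (dominated by THC-dominant samples); the three terpene clusters
are characterized by their top two mean terpenes; the silhouette means
show algorithmic clusters fitting the chemistry best, simple
dominant-terpene labels second, and commercial category labels worst —
and per-strain mean cosine similarities are compared against the 0.780
shuffled-name baseline to flag which strain names are chemically more
consistent than arbitrary labeling.

The same stages are available piecewise (`chemovar simulate`,
`harmonize`, `qc`, `chemotype`, `cluster`, `consistency`, `report`) and
as library functions in `chemovar.ingest`, `chemovar.chemotype`,
`chemovar.chemometrics`, `chemovar.clustering`,
`chemovar.consistency` and `chemovar.synthetic`.

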