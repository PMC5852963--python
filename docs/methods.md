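# Methods

## Gene sets

The comparison universe is partitioned into four disjoint sets. Candidate
dual-role genes are the intersection of an oncogene list and a
tumor-suppressor list (symbols compared after whitespace-stripping and
uppercasing; no alias resolution is attempted, so the curated table's
literal "WT" entry is preserved as printed). Only candidates present in a
curated POTSF list become POTSF; candidates never curated are labelled
UNRESOLVED and excluded from all four comparison sets. This exclusion is a
deliberate choice — the provenance of un-curated overlap genes is
ambiguous, and putting them in either parent set would dilute both
contrasts. A `share` policy is available that returns them in both ONC and
TSG memberships for sensitivity analysis.

POTSF genes carry a functional class (TF / KINASE / OTHER); genes missing
from a user class map default to OTHER with a warning so class counts
always total the set size. The packaged curated table contains 83 genes
(41 TF, 13 kinases, 29 others).

## Mutation profiling

Input is a MAF-like table; standard `Variant_Classification` tokens are
mapped onto a closed ten-value vocabulary and unmapped tokens (e.g.
`Translation_Start_Site`) are skipped and tallied rather than guessed.
The **non-silent filter** retains the eight protein-altering classes and
removes SILENT and RNA records; it is order-preserving and conservative
(kept + removed = input).

The **mutation rate** for gene *g* in cohort *c* is

    rate(g, c) = (n_total(g, c) / n_cases(c)) / length_bp(g)

with `n_total` counting silent *plus* non-silent mutations (RNA records
enter neither count: they are neither protein-altering nor exonic point
mutations in the sense of this statistic). Gene length is whatever the
universe file supplies (exonic/coding bp); the statistic is a crude
per-bp-per-case density, not a covariate-adjusted background model, and no
significance is attached to individual genes. Cohort case numbers default
to the distinct sample ids observed per cohort but should be overridden
with the true cohort sizes when the table does not contain every case.

Potential functional impact maps truncating classes (nonsense,
frameshifts, splice-site, nonstop) to LOF_POTENTIAL and
length-preserving coding changes (missense, in-frame indels) to
GOF_POTENTIAL; the mapping is a plain dict argument because conventions
differ between studies.

Exact duplicate rows are kept by default (a position-less dialect cannot
distinguish duplicates from recurrent mutations); `dedup` removes them.

## Expression

Tumor route: per-sample **median normalization** divides each sample by
the median over its *positive* values (zeros excluded — with RSEM's many
exact zeros a global median can be 0 for low-coverage samples), then
per-gene means are taken within cohorts. Organ route: **RPKM** =
reads / ((length/1e3)·(library/1e6)), per gene as summed exon counts over
summed exon lengths; replicate organs are averaged; then
**log2(RPKM + 1)** (the pseudocount handles zeros; configurable) and a
per-organ **Z-score** with sample standard deviation (ddof = 1). Columns
therefore come out with mean 0 and sd 1 to machine precision, and the
transform is scale-invariant in the input units. A normalization-state tag
on the matrix prevents route mixing (e.g. Z-scoring a median-normalized
tumor matrix raises).

## Network analysis

Edge lists are ingested as undirected simple graphs: self-loops dropped,
reversed duplicates merged, scores discarded (the analysis is topological).
Degree and local clustering (0 by convention for degree < 2, so set-level
means are defined) come from networkx. The POTSF neighborhood network is
all POTSF nodes plus direct neighbors; the induced subgraph is the default
(neighbor–neighbor edges carry module structure), a star-only variant is
available.

**Dense modules** are found by a from-scratch MCODE-style procedure:
vertex weight = k × density of the highest k-core of the closed
neighborhood; complexes grow breadth-first from the highest-weight unused
seed, admitting neighbors with weight ≥ (1 − vwp) × seed weight
(defaults vwp = 0.2, haircut on, fluff off, matching the algorithm's
published defaults); haircut iteratively strips members with fewer than
two in-complex connections; complexes are ranked by density × size. All
ties — seed order, traversal order, ranking — break lexicographically on
gene id, making the output invariant to node insertion order.

**dN/dS** uses Nei–Gojobori (1986) pathway counting: synonymous site
fractions per codon position (changes to stop codons count as
nonsynonymous sites), differences averaged with equal weight over all
substitution orderings, skipping pathways through stop codons unless every
ordering is blocked, and Jukes–Cantor correction
d = −(3/4)·ln(1 − (4/3)p) with a typed saturation error at p ≥ 3/4.
ω is undefined (None) when dS = 0. This simple counting estimator was
chosen over ML codon models because the inputs are close ortholog pairs at
low divergence, where NG86 is nearly unbiased and has no optimization
failure modes; the function signature admits alternative estimators.

## Statistics

Two-sided two-sample KS and Wilcoxon rank-sum (reported statistic: rank
sum of the first sample) with exact permutation p-values when
min(n, m) ≤ 10 (Wilcoxon: and no ties), asymptotics otherwise (tie and
continuity corrections for the rank-sum normal approximation). Pearson
chi-square without continuity correction, warning on expected counts < 5.
Pairwise set comparisons report raw p-values at α = 0.05 with no
multiple-testing correction — matching the reporting convention of the
analyses this reproduces — and the significantly "higher" set is the one
with the greater mean (the underlying convention for star placement is not
otherwise defined). Benjamini–Hochberg across the pairs is available via a
flag.

The cancer-type composition contrast feeds the two printed top-10
percentage vectors directly into the chi-square as a 2 × 10 table
(percentages treated as counts, df = 9); this construction reproduces the
published P = 0.01674 exactly.

## Synthetic data

The generators' defaults encode the study conditions:

| parameter | default | rationale |
|---|---|---|
| set sizes | 83 / 1320 / 952 / 1000 | reported POTSF/ONC/TSG counts; NCRG at comparable scale |
| gene length | lognormal(ln 1500, 0.6) bp | typical coding-length distribution |
| cohorts | 11 cohorts, 129–817 cases | published per-cohort sample counts |
| base_rate | 6e-6 /bp/case | ≈ 29.5 mutations/gene ÷ 3281 cases ÷ 1.5 kb |
| rate multipliers | 3.0 / 2.5 / 1.05 / 1.0 | ratios of reported per-gene mutation means (70/58/24/23) |
| class probabilities | renormalized printed per-class counts | the printed counts oversum; only ratios are used |
| expression shift (log2) | 0.8 / 0 / 1.0 / 0 | TSG-high, POTSF≈TSG normal-organ pattern |
| expression sd | 2.0 log2 units | typical between-gene spread |
| network | growth, m = 2, POTSF attractiveness 4 | hub bias of dual-role genes |
| ω, branch length | 0.2, 0.3 proposals/codon | purifying selection at moderate divergence |

Mutation counts are Poisson(base_rate × multiplier × length × cases) per
gene/cohort; a `fixture_mode` instead emits exactly 617,354 records with
exactly 134,635 SILENT and 10,659 RNA (the non-silent remainder
apportioned from the printed class counts by largest remainder), pinning
the non-silent filter's bookkeeping at full cohort scale. The network is
grown by (degree + 1) × attractiveness preferential attachment — the +1
avoids zero-probability isolated starts — and has exactly
m(n − m) + m(m − 1)/2 edges. Codon pairs evolve an ancestor by Poisson
point-mutation proposals, accepting synonymous changes always,
nonsynonymous ones with probability ω, and stop-creating ones never; NG86
applied to such pairs recovers ω with a small downward bias (stop-blocked
proposals) well inside ±0.05 at ω = 0.2.

What the generators do **not** emulate: trinucleotide mutation signatures,
copy-number events, expression covariance between genes, sample-level
purity/batch structure, and the degree–length correlation of real
interactomes. Passing recovery tests therefore demonstrates that the
pipeline measures what it claims on data satisfying its model assumptions,
not that real pan-cancer data would show the same effect sizes.

## Numerical and scale choices

* Exact permutation enumeration for the test oracles is limited to
  min(n, m) ≤ 4 grids (C(n+m, n) splits).
* Type-I calibration uses n = m = 200 per sample and 1,000 replicates:
  both tests are then in the asymptotic regime where their size is stable
  (~0.05).
* Recovery simulations run at 200 genes/set × 100 cases (mutation rate),
  360-node networks × 100 seeds (hub bias), and 1,000 codons × 50 seeds
  (ω); these sizes give standard errors comfortably below the asserted
  bands while keeping the suite fast.
* Determinism: every generator consumes a `numpy` Generator seeded from
  (config.seed, salt) via `SeedSequence`, so outputs are byte-identical
  per seed and independent across data layers.

## Known limitations

* The mutation-rate statistic ignores sequence context and coverage; it is
  a descriptive comparison device, not a driver-detection model.
* MCODE complexes here are disjoint (a node joins at most one complex);
  the original allows overlap via fluff. Fluff is implemented but off by
  default and marks added nodes as used.
* NG86 saturates near p = 3/4 and the pathway average mis-attributes a
  small nonsynonymous fraction to multi-hit codons; the estimator is
  intended for low-divergence pairs.
* Chi-square on percentage vectors inherits the original construction's
  statistical looseness (percentages are not counts); it is reproduced for
  comparability, with the small-expected-count warning left visible.
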