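# Methods

## Annotation model

Databases are flat stores of (gene symbol, term id) associations.
Terms are treated as labels: no ontology-graph propagation (term
ancestry) is applied, so an annotation to a specific term does not imply
annotation to its parents. Gene symbols are normalized by uppercasing
and exact matching against a protein-coding universe (HGNC-style);
alias resolution is deliberately out of scope — inputs are expected to
use current approved symbols. Genes outside the universe are dropped
with a logged count rather than added, so the hypergeometric population
size GDB stays well defined.

Each standardized database carries exactly one *sentinel* term
("no annotation"), linked to every universe gene with no other
association. Sentinels make the universe exhaustive, are tested like any
other term (a gene set drawn from unannotated genes will legitimately
enrich the sentinel), but are excluded by default from similarity and
differential outputs, and from database statistics (reported
separately).

Mouse-phenotype databases are re-keyed to human symbols through a
many-to-many ortholog map: each mouse association expands to all mapped
human symbols, then the result is standardized against the human
universe. CRISPR screen hit tables are encoded as three terms per
screen — association (either hit class), positive, negative — with
empty class terms omitted, since a term with no genes can never be
tested.

## Enrichment test

For a term with `gdb` annotated genes in a database of `GDB` genes and
a query set of size `|G|` with `g` hits, the reported P value is the
exact hypergeometric upper tail P(X ≥ g) (scipy, no normal
approximation). The point probability P(X = g) is retained as
`mode="pmf"` for comparison, but it is not used as the default because
the point mass is not a valid tail probability when g is near its
expectation. Only terms with g ≥ 1 are tested; the conditioning this
induces is visible in the simulation module's `per_term_tested` metric.

Bonferroni (min(1, n·p)) and Benjamini–Hochberg step-up adjustments come
from `statsmodels.stats.multitest`. By default they are computed jointly
over all tested terms of all selected databases in one analysis
(one pooled table per analysis); per-database adjustment is available
by flag. The default "significant term" criterion downstream is raw
P < α with α = 0.05, configurable to the adjusted criteria. Ties in the
output table are broken by (database, term id), so result tables are
byte-reproducible.

## Overlap coefficients and randomization

POR is the Jaccard index or the Forbes coefficient with Alroy's
correction over the two significant-term sets; RPOR applies the same
coefficient to all annotated (g ≥ 1, non-sentinel) terms. Conventions:
both coefficients are 0 when nothing is shared (including the 0/0
case), the Forbes coefficient is 1 whenever one set is contained in the
other (b = 0 or c = 0 with a > 0), and the Jaccard index is 1 only for
equal sets.

Significance is by randomization over gene sets drawn uniformly,
without replacement, from the intersection of the selected databases'
universes. In *overlapping* mode (sets may share genes) each side is
randomized in turn while the other is held fixed, and the 2m null
values are pooled; a per-direction breakdown is also emitted. In
*conditional* mode (G′ derived from G) only G′ is randomized (m null
values). The empirical P value counts null coefficients *strictly
greater* than the observed one; ties do not count as exceeding, which
makes the estimate anti-conservative by exactly the tie mass at the
observed value — on databases where significant-term sets are small,
POR is coarsely discrete and this matters (see Calibration below). An
add-one variant (1 + #{≥})/(m + 1) is available for users who need
P > 0.

The relevance regression is an OLS of per-term gene counts in set B on
the counts in set A over the shared significant terms, reported as
adjusted R² with the model F-test P value; it is flagged undefined for
fewer than 3 shared terms or constant x, and flagged low-information
(slope 0, R² 0) for constant y.

## Synthetic databases

`generate_synthetic_db` draws per-gene annotation counts from a
gamma-Poisson mixture with target mean μ and dispersion a (variance
μ + aμ²; a = 0 gives Poisson), then samples that many distinct terms
per gene with probability proportional to rank^(−s) weights (Gumbel
top-k sampling), giving heavy-tailed term sizes. Defaults are a dense
database — 19,000 genes, 5,000 terms, μ = 17.7, a = 0.3, s = 1 —
matching the density of the larger real annotation databases; sparse
variants (μ ≈ 4.4 or 7) correspond to small disease-panel resources.
An optional disease module plants Bernoulli(p) co-associations inside a
chosen block of genes × terms, giving overlap experiments a known
signal. Requesting μ = n_terms saturates (every gene annotated to every
term); μ > n_terms is rejected as infeasible.

What the generator does *not* emulate: ontology structure and annotation
propagation, correlated gene modules outside the planted block,
database-specific curation biases, and symbol-level noise. Passing
simulation tests therefore demonstrates the statistical machinery is
correct and calibrated under exchangeable nulls, not that any particular
real database release is reproduced.

## Type-I-error experiment

For each (database, set size) cell, uniform random gene sets are drawn
and enriched. Because "ratio of significant tests" admits several
readings, three metrics are implemented:

* `per_term_all` (default): significant non-sentinel terms over *all*
  non-sentinel terms, untested terms counting as non-significant. This
  is the only reading mathematically guaranteed ≤ α in expectation for
  a valid test, and it is the one asserted quantitatively (on the dense
  default database, 1,000 random sets of size 320 give a mean FPR of
  ≈ 0.02 < 0.05).
* `per_term_tested`: denominator restricted to tested (g ≥ 1) terms.
  On sparse databases at small set sizes this metric inflates well above
  α — few terms are tested and the discrete test is coarse — which
  reproduces qualitatively the known difficulty of sparse disease-panel
  resources at small gene-set sizes.
* `any_hit_adjusted`: fraction of replicates with at least one
  Bonferroni-significant term (a family-wise reading).

The experiment reports the Pearson correlation between set size and FPR
across cells. The full grid (sizes 5–640, 1,000 replicates per cell)
runs in minutes thanks to a precomputed per-term critical count
g*(gdb) — the smallest g with P < α — so replicates need only sparse
row sums and integer compares, not per-term tail evaluations.

## Artificial-gene-set mixture experiment

Given a seed gene set (default size 261), an artificial set of the same
size is built per replicate: round(p·size) genes sampled from the seed
set; of the remainder, a 5% noise fraction sampled from genes outside
the seed set that carry at least one term enriched in the seed set;
and the rest from a filler pool matched to the seed genes'
annotation-count deciles. "Similar phenotypic connectivity" is
operationalized as that decile matching, since no sharper definition is
available; the noise definition (raw P < 0.05 terms of the seed set) is
likewise a design choice. POR between seed and artificial set is then
recorded over an 11-point grid of p with 100 replicates per point, an
OLS of POR on p is fitted over all points, and Welch t-tests compare
adjacent p levels. On the planted-module database shipped as the
default (4,000 genes, 600 terms, μ = 12, module 400 genes × 80 terms at
p = 0.25) the dose–response is monotone with R² > 0.9 and p = 0.94
vs 1.00 separate at Welch P < 0.01 — the desk-scale analogue of
detecting a ~1% composition change (3 genes in 261).

## Calibration of the empirical P

Under the null (G′ uniform at random, conditional mode), the empirical
P should be uniform on [0, 1]. This holds to the granularity of the
m + 1 lattice *provided the null POR distribution is effectively
continuous*. The calibration check therefore uses a deliberately dense
database (2,000 genes, 4,000 terms, μ = 100, mild skew) and sets of
300 genes, under which significant-term sets hold ~160 terms, the tie
mass at any single POR value is < 1%, and 200 trials at m = 200 give a
Kolmogorov–Smirnov distance from uniform of ≈ 0.07. On sparse databases
the strictly-greater counting plus the point mass of POR at 0 visibly
distorts the distribution — the documented cost of the strict counting
rule, not an implementation artifact.

## Numerical and design notes

* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; no global state. Identical inputs and
  seeds give byte-identical outputs.
* Significance thresholds are strict (<) everywhere, matching the
  "P < 0.05" convention.
* Critical-count tables are cached per (database, set size, α);
  caches are attached to database objects and never mutated.
* Problem sizes in the shipped experiments (database scale, replicate
  counts, grid sizes) are chosen so the full suite runs comfortably on
  one CPU; they are stated alongside each experiment above.
* TSV is the canonical table format and JSON the machine-readable
  summary; no plotting in the core.

## Known limitations

* No gene-symbol alias resolution; inputs using outdated symbols will
  silently lose genes (counted in the log).
* Flat-label treatment of ontology terms understates similarity between
  sets annotated to nearby but distinct terms; semantic-similarity
  approaches are a different method family.
* The strictly-greater empirical P can be exactly 0; use the add-one
  variant when downstream tools require positive P values.
* Randomization draws are uniform over genes; no matching on gene
  length, annotation density or other covariates in the null.
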