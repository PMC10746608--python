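# Methods

## Model and procedure

The pipeline operationalizes a dual-evidence screen for "core" TFs behind
a selected-gene program, followed by pathway profiling and network hub
ranking. All data are at the gene-symbol level; symbols are normalized by
stripping whitespace and uppercasing, with no automatic alias resolution
(published candidate tables mix naming dialects — "OCT4" vs "POU5F1",
"P300" vs "EP300" — and silent renaming would manufacture or destroy
overlaps; an explicit alias map on the TF catalog is the only renaming
mechanism).

**Over-representation.** The overlap *k* between a query list (effective
size *n*) and a gene set (size *K*) in a universe of *N* genes is tested
with the one-sided upper-tail hypergeometric probability
P(X ≥ k), X ~ Hypergeom(N, K, n) — identical to the one-sided "greater"
Fisher exact *p* of the 2×2 table [[k, n−k], [K−k, N−K−n+k]]. When a
library carries an explicit universe, query genes outside it are excluded
from *n* (and set members outside it are dropped at read time, since
public libraries routinely contain retired symbols); when only the
universe *size* is declared, *n* is the full query size — a standard
approximation, noted in the log. The default background size is 22,000,
the usual protein-coding gene count for human or mouse; it is overridable
per library.

**Multiplicity.** Benjamini–Hochberg step-up adjustment is applied within
one library at a time, across *all* of its sets (significant or not).
Combining libraries concatenates records, preserving provenance and
re-sorting by (adjusted *p* ascending, odds ratio descending, set name) —
it never re-adjusts, mirroring a survey that queries each library
separately and then pools the hits. Significance is strict inequality at
the threshold (default 0.01); as a deliberate convention a threshold of
exactly 1 disables filtering (every tested record passes), which keeps the
degenerate no-filter case expressible.

**TF-target collapsing.** ChIP-seq libraries carry several experiment
sets per TF. Testing and adjustment happen at the experiment level;
records then collapse to one per TF by minimal adjusted *p* (tie-break:
larger overlap, then set name) — the value a reader takes from a
multi-row query result. A conservative alternative (multiplying the best
adjusted *p* by the TF's experiment count, Bonferroni-style) is available
as `collapse="bonferroni"` but is off by default.

**Core calling.** List 1 (census TFs inside the selected-gene list) and
list 2 (TFs with collapsed adjusted *p* below threshold) are intersected
on normalized symbols. An empty intersection warns rather than errors.

**Shared pathways.** Each core TF's known target list (union of its
experiment sets) is profiled against every pathway library; the pooled
per-TF hits are intersected across TFs on set *names*, case-insensitively
across libraries — the granularity at which pathway names are reported.
TFs without target data are excluded from the intersection and listed
(mirroring the published analysis, where one of the five core TFs had no
ChIP-seq data and the shared-pathway table covers the other four).

**Network.** Regulatory edges are directed regulator → target and exist
when the target belongs to one of the regulator's experiment sets, with
experiment multiplicity retained; protein-interaction edges are
undirected, canonicalized as sorted pairs with self-pairs permitted, and
restricted to pairs touching the node set. Hub ranking is by total count
of distinct interaction partners across the named reference lists
(descending), tie-broken by regulatory out-degree then name. The
composite rank is a documented choice — the underlying counts are always
reported so users can re-rank; partner counting is per distinct symbol,
never per interaction record.

## Synthetic scenarios

The generator emulates the statistical structure the analysis assumes: a
universe of synthetic symbols (`TF0001…`, `G000001…`, so no collision with
real gene semantics), a TF catalog, a TF-target library, pathway
libraries, a selected list, and an interaction table, with ground truth
returned for every planted feature. Sampling order is fixed (universe,
TF target sets in TF order, pathways, selected list, interactions) so one
seed yields byte-identical artifacts.

The **strong preset** (the defaults) represents a clearly detectable
regime: universe 22,000; 60 catalog TFs of which 5 are planted core TFs;
1–3 experiment sets per TF (decoy sets 200–400 genes, planted sets 300 —
typical ChIP-seq target-list scales); 50 pathways of 50–300 genes, 3 of
them planted; a 200-gene selected list containing the planted TFs and
over-representing their pooled targets ten-fold relative to the uniform
base rate; Erdős–Rényi interactions at density 0.05 among catalog TFs
with the planted hub wired to 80% of the others. Planted *shared*
pathways draw an equal share of their members from every planted TF's
target set — a draw from the pooled target union alone would not
guarantee enrichment for a TF holding a small share of that union, i.e.
the plant would not actually be planted. At `enrichment_strength = 1`
the non-planted part of the selected list is drawn uniformly from the
universe, giving an exact null.

The **null preset** is a reduced no-signal scenario for type-I
calibration: universe 2,000; 50 decoy TFs with one 50-gene set each; a
uniform 100-gene selected list; nothing planted. Under it each TF's
overlap is exactly Hypergeom(2000, 50, 100), independently across TFs.

What the generator does *not* emulate: real ChEA set-size and overlap
heavy tails, inter-set correlation (real TF target sets share targets),
alias noise, and annotation bias. Passing recovery tests therefore shows
the machinery is correct and calibrated under its stated model, not that
any particular biological list will behave as cleanly.

## Numerical choices

* Tail probabilities come from `scipy.stats.hypergeom.sf`; the test suite
  checks them against two independent brute-force summations (exact
  rational arithmetic at small sizes; a log-gamma summation accumulated
  from the smallest terms on an exhaustive grid of every feasible
  (k, K, n, N) with N ≤ 200), agreeing to ≤ 1e-12 relative error.
* BH adjustment is `statsmodels` `multipletests(method="fdr_bh")`,
  cross-checked against a hand-rolled step-up oracle; adjusted values are
  clamped to `[p_raw, 1]` to absorb float round-off.
* Odds ratios add 0.5 to all four cells when any cell is zero
  (Haldane–Anscombe), keeping reports finite; they are used for
  reporting and tie-breaking only.
* All rankings are total orders: (p_adj, −odds ratio, set name) for
  enrichment tables, (−partners, −out-degree, name) for hubs, so outputs
  are byte-reproducible.
* Degenerate inputs: empty query or library is an error; an empty core
  intersection, an empty interaction table, or a TF without target data
  degrade gracefully with logged warnings.

## Calibration and recovery experiments

`coretf.validation` measures, at run time:

* **Oracle agreement** — maximal relative error of the tail probability
  over the exhaustive grid (see above).
* **Null calibration** — the per-TF rate of *raw* p < 0.01 over 500 null
  replicates (25,000 TF tests). Because the hypergeometric test is
  discrete, its attainable size at α = 0.01 is below nominal: for the
  null-preset geometry the rejection region starts at k = 8 and the exact
  size is P(X ≥ 8) ≈ 0.00276. The test checks the empirical rate against
  that exact size (99% binomial band), plus conservatism (rate ≤ α).
  Calibration is measured on raw p-values deliberately: after BH
  adjustment the per-TF null rate is far below α by construction (that is
  what FDR control means), so α-calibration is only meaningful for the
  unadjusted test.
* **Planted recovery** — over 100 strong-preset replicates, the fraction
  in which all five planted core TFs are called, the planted hub ranks
  first, and the planted pathways appear in the shared set. The test
  asserts ≥ 95%; observed rates in the reproduction script are at or
  near 100%.

Replicate counts (500 null / 100 recovery) and the grid bound (N ≤ 200 in
tests, N ≤ 100 in the quick reproduction script) are the package's chosen
experiment sizes; all are re-derived from the command-line seed.

## Expectations on the original published data (not unit-tested)

With the *original* external libraries (the 2022 ChIP-seq target-set
release, the four pathway libraries, the human TF census and the BioGRID
interaction tables), the published analysis reports: 53 selected TFs and
66 target-enriched TFs from the 764-gene selected list; their five-TF
intersection (KLF4, MITF, NR3C1, NR3C2, SOX2); pathway hits such as
"neural crest differentiation" (adjusted p 1.60e−5) for list 1; shared
pathways across four core TFs' target lists including axon guidance and
BDNF signaling; and SOX2 as the dominant hub. Those adjusted p-values
depend on the exact library versions and the enrichment service's
background handling, so they are treated as provenance, not as
recomputable targets: this package bundles the resulting candidate lists
and partner tables as fixtures (`coretf.datasets`) and reproduces the
downstream funnel (53/66/5, SOX2 hub) exactly, while the upstream numbers
are validated on synthetic data instead. The published shared-pathway
table prints seven rows but its accompanying text counts six; one row
("Signal transduction") may be a super-heading, and fixtures accept both
readings.

## Known limitations

* Symbol-level only: no coordinate, sequence or isoform awareness.
* No GSEA-style rank statistics and no replication of the Enrichr web
  service's z-score/combined-score correction — "adjusted Fisher exact"
  is read as BH-adjusted one-sided Fisher/hypergeometric.
* No cross-library multiplicity correction (by design, matching the
  survey-then-pool workflow).
* Alias handling is opt-in and catalog-scoped; orthology is out of scope.
* XLSX supplements must be exported to text (TSV/GMT) before use.
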