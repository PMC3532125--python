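# Methods

## The model

`crgnet` treats chemosensitivity-gene discovery as seed-guided network
pruning.  The data are a complete log-scale expression matrix *G* (genes ×
cell lines), a gappy drug-activity matrix *D* (drugs × cell lines, lgGI50),
an undirected protein-interaction network over gene symbols, an ontology
annotation (term → genes, plus the term DAG), and a curated compendium of
documented drug–gene pairs.  The working assumptions, each of which is a
measurable property of the seed set rather than an article of faith:

1. documented chemosensitivity genes concentrate in a small number of
   ontology terms (functional coherence);
2. they occupy structurally central network positions — high degree and
   high betweenness;
3. their expression–activity correlations are real but mostly weak, so a
   pure |PCC| cut removes most of them.

The pipeline turns each property into a filter and applies them in order:
annotation membership (gene level), centrality top-fraction (gene level),
|PCC| threshold (edge level), then ranks surviving genes with the Q
order-statistic over their degree and betweenness ranks.

## Statistics and conventions

**Pearson correlation.** Computed per (drug, gene) over the cell lines
where the drug's activity is observed; expression is required complete.
A correlation is *undefined* (recorded with its reason, never silently
zero) when fewer than `min_complete` (default 10) complete pairs remain or
either sub-series is constant.  The default stabilizes estimates on gappy
drugs; the theoretical minimum of 3 is accepted.

**Missingness filter.** A drug is dropped when its activity is missing in
*strictly more than* `max_missing_fraction` (default 0.8) of cell lines —
a drug exactly at the threshold stays.

**Seed |PCC| threshold (Filter C).** τ is the nearest-rank percentile
(rank ⌈p/100·N⌉ of the ascending sort) of the seed pairs' |PCC|, default
p = 5.  Nearest-rank rather than interpolation keeps τ equal to an
observed value, so "at least (100−p)% of seed pairs pass" holds exactly.
One global τ pools all seed pairs across drugs.  p ≤ 0 disables the cut.

**Per-drug correlation null.** A seed pair's PCC x is classified against
its drug's all-gene PCC distribution by z = |x − μ|/δ with δ the
*population* standard deviation (ddof = 0, configurable); z below the
threshold (default 0.8) is "random", otherwise the sign of x − μ gives
"larger"/"smaller".

**Fisher enrichment (Filter A).** The 2×2 table is the standard disjoint
layout: a = seed genes in term, b = other background genes in term, c/d
the complements.  Background defaults to measured genes with at least one
annotation.  The reported test statistic is the upper hypergeometric tail
(Σ over a′ ≥ a); the point probability of the observed table — the
classical factorial formula — is exposed alongside.  No multiple-testing
correction by default (raw p ≤ 0.01 per term); Benjamini–Hochberg is
available as an option.  Term depth is the shortest child→parent distance
to the namespace root; the default rule keeps terms at depth exactly 5
(mirroring DAVID-style level files), with "at most 5" and "any"
alternatives.

**Term-set similarity.** The coherence score of an enriched-term list is
the mean pairwise Jaccard index of the terms' annotated gene sets; the
null re-draws same-size gene sets from the background and re-runs the
enrichment.  Jaccard is a deliberate, stated choice — simple and
assumption-free; information-content semantic similarities are out of
scope.  Draws with fewer than two enriched terms have undefined
similarity and count as non-exceeding in the empirical p.

**Centrality (Filter B).** Degree is the neighbor count.  Betweenness is
unnormalized, over unordered node pairs with endpoints excluded;
disconnected pairs contribute zero.  Conventions only rescale the values
by constants — downstream steps use ranks, which all conventions share.
The top-fraction cut uses nearest-rank quantiles of the full network
distributions and admits ties at the cut weakly, which makes the filter
monotone in both fractions.  The two criteria combine with AND.  The
seed-vs-random comparison draws size-matched gene sets without
replacement and reports fold (observed mean / null mean) and the
one-sided empirical p with the +1 correction, so p is never zero.

**Q statistic.** V_k = Σ_{i=1..k} (−1)^{i−1} V_{k−i} r_{N−k+1}^i / i!,
Q = N!·V_N, with the rank ratios sorted ascending first — the recursion
presumes order statistics, and without sorting Q can exceed 1.  Rank
ratios are rank/n with mean ranks for ties (competition ranking is
available); with one source Q reduces to the ratio itself, and
Q(r,…,r) = r^N.  The implementation is validated against a Monte-Carlo
order-statistics oracle and the N ≤ 2 closed forms.  The pipeline fuses
N = 2 sources (degree, betweenness) over the genes that survive all three
filters; the gene-level ROC instead fuses over every measured network
gene, so the two methods rank the same universe.

**Evaluation.** Over-representation of seed pairs among predictions uses
the upper-tail hypergeometric sum with the full defined-edge table as the
universe.  The baseline is matched-count: the K = #predictions edges with
largest |PCC|, ties broken deterministically (|PCC| desc, drug, gene).
ROC/AUC is computed at the gene level — positives are genes appearing in
any seed pair, the universe is all genes entering rank fusion — with the
combined method scored by −Q and the baseline by the gene's best |PCC|;
AUC equals the Mann–Whitney statistic with half-credit ties, so any
monotone rescoring gives the same value.  A threshold sweep repeats the
matched-count comparison for q = 0.01 … 0.20.

## Synthetic studies

The generator emulates the joint structure the method exploits, at the
scale of the emulated screen (defaults: 2000 genes, 50 drugs, 60 cell
lines, 40 seed genes in 60 curated pairs):

* **Network** — preferential-attachment growth in random node order; seed
  genes receive an attachment-weight bonus (`hub_bias`, default 30) that
  makes them hubs and bottlenecks.  With `hub_bias = 0` they are
  exchangeable with other genes (fold ≈ 1), and the degree fold grows
  monotonically with the bonus.
* **Ontology/annotation** — a layered DAG of depth 7 whose parents sit
  exactly one level up, so depth equals layer; annotated terms live at
  depths 4–6 (120 at depth 5 by default) with sizes uniform in 10–40.
  Seed genes are planted into 5 depth-5 terms with probability
  `seed_concentration` (default 1).
* **Screen** — expression is iid standard normal per gene.  Each planted
  pair gets a signed target correlation; a drug's activity is
  Σ ρ_g·z_g + √(1 − Σρ²)·ε over its planted genes, which yields each
  pair's population correlation exactly (genes are independent), with the
  per-drug Σρ² capped below 1.  Planted magnitudes span 0.1–0.6 with
  80.6 % below 0.3, reproducing the weak-correlation regime in which the
  correlation-only screen fails.  Activity entries are masked completely
  at random (`missing_rate`, default 0.05).
* **Compendium** — exactly the planted pairs.  A separate deterministic
  generator emits a synthetic stand-in curated table with 150 distinct
  pairs over 64 drugs and 94 genes for loader-accounting checks.

What the generator does **not** emulate: microarray noise structure and
batch effects, correlated expression between genes (co-expression
modules), drug-class structure, informative missingness, and annotation
evidence codes.  Passing tests therefore demonstrate that the
implementation recovers planted structure of the stated kind — not that
the biological assumptions hold in any particular real screen.

## Numerical choices and degenerate inputs

Fisher/hypergeometric tails are computed in log space (scipy); exact
enumeration oracles in the test suite bound the error at 1e−10 on small
tables.  PCC is clipped to [−1, 1] against rounding.  Q is clamped to
(0, 1] against float residue of the alternating recursion.  Rank and
output tie-breaks are deterministic everywhere (gene id, then drug id),
so identical configuration and seed reproduce outputs byte-for-byte.
Empty stages raise a named error rather than returning an empty table;
all-missing drugs are kept at load and removed only by the explicit
filter; duplicate expression rows (multiple probes per symbol) collapse
by mean at load.  Gene identity is case-insensitive symbol equality after
trimming, with no alias resolution — a documented limitation.

## Design choices

* Betweenness is computed with igraph's exact Brandes algorithm for speed;
  the graph container and everything else stays networkx.  An independent
  brute-force enumeration oracle guards the agreement.
* Filters A and B act on genes, Filter C on edges; A and B commute (both
  are set intersections on the gene side), which the tests assert.
* Rank fusion happens after Filter C, over the surviving genes, so the
  reported q_score reflects the prediction set actually emitted.
* Default centrality fraction q = 0.01 for both metrics; the evaluation
  sweep covers 0.01–0.20.  Defaults live in one frozen `PipelineConfig`
  that is serialized into the run manifest with the package version and
  seed.
* Permutation nulls default to 999 draws; empirical p-values use the +1
  correction and are therefore bounded below by 1/(n_perm+1).

## Problem sizes

Tests run the full method on studies of 300–2000 genes and 8–50 drugs;
the end-to-end recovery property uses 20 seeded replicates at the default
2000-gene scale, and the acceptance script one such run.  These sizes
were chosen so the planted effects are comfortably detectable (seed
centrality folds of 3–10, enrichment p ≪ 0.01) while a complete run of
suite plus script stays in the minutes range on one CPU.

## Known limitations

No identifier harmonization (symbols must already match across matrices,
network and annotation); one global |PCC| threshold rather than per-drug
thresholds; the annotation filter inherits whatever bias the annotation
corpus has; empirical p-values are resolution-limited by the permutation
count; and the method's premise — that seed genes are central and
functionally coherent — must actually hold in the data for the filters to
help, as the zero-`hub_bias` and zero-concentration generator settings
demonstrate by construction.
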