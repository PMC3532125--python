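# crgnet

Network- and annotation-aware prioritization of **chemosensitivity-related
genes (CRGs)** — genes whose expression predicts how strongly a cancer cell
line responds to a drug.

Screens in the NCI-60 style profile each cell line twice: a gene-expression
matrix *G* (genes × cell lines, log-scale intensities) and a drug-activity
matrix *D* (drugs × cell lines, lgGI50 = log₁₀ of the concentration
inhibiting growth by 50%, with missing entries).  The classical approach
scores each (drug, gene) pair by the Pearson correlation of the gene's
expression with the drug's activity and keeps the strongest |PCC|.  That
approach misses most *documented* chemosensitivity genes, whose
correlations are predominantly weak.  `crgnet` instead starts from a
curated compendium of literature-documented drug–gene pairs (the seed set)
and prunes the full drug–gene correlation network with three filters
derived from the seed genes' measurable properties:

* **Filter A (annotation)** — seed genes are tested for over-representation
  in every ontology term at depth 5 with a one-sided Fisher exact test on
  the 2×2 table (seed vs background × in-term vs not); all genes annotated
  to terms with p ≤ 0.01 become candidates.
* **Filter B (network)** — in a protein-interaction network, candidates
  must lie in the top fraction *q* of **both** the degree distribution
  (hubs) and the unnormalized betweenness distribution
  Bᵢ = Σ_{s≠i≠t} δ_st(i)/d_st (bottlenecks).
* **Filter C (expression)** — a (drug, gene) edge survives only if
  |PCC| ≥ τ, where τ is the 5th percentile of the seed pairs' own |PCC|
  values, so 95 % of documented pairs would pass their own bar.

Surviving genes are ranked by the **Q order-statistic**, which fuses the
degree rank ratio r₁ and betweenness rank ratio r₂ into the joint tail
probability

    Q(r₁,…,r_N) = N!·V_N,   V₀ = 1,
    V_k = Σ_{i=1}^{k} (−1)^{i−1} V_{k−i} r_{N−k+1}^i / i!

(ratios sorted ascending; N = 2 here).  Q is exactly
P(U₍₁₎ ≤ r₁, …, U₍N₎ ≤ r_N) for iid uniforms, so a small Q marks a gene
that is near the top of *every* ranking simultaneously.

The package also ships the evaluation protocol (matched-count baseline,
hypergeometric over-representation, gene-level ROC/AUC), a permutation
characterization of the seed set, and a seeded synthetic-data generator
that plants all the structure above so the full method is testable without
any external download.

## Worked example

`examples/04_evaluate_vs_baseline.py` generates the default synthetic
study (2000 genes × 60 cell lines, 50 drugs, 40 seed genes planted as
hubs with clustered annotations and weak-to-moderate correlations), runs
the pipeline, and compares it with the correlation-only baseline at a
matched prediction count:

```
matched prediction count K = 281
combined filters : 13/60 seed pairs, p = 2.36e-21
|PCC| baseline   : 18/60 seed pairs, p = 5.71e-32
gene-level AUC   : combined 84.1%  vs baseline 74.1%
```

Reading: both methods recover seed pairs far above chance (hypergeometric
p), but at the **gene** level — the question "does the method rank
documented chemosensitivity genes above the rest?" — the fused centrality
score (AUC 84.1 %) clearly beats best-per-gene |PCC| (74.1 %), because
most planted correlations are below the 0.3 a correlation screen needs.
The other examples show the pipeline stages (`01`), the seed-set
characterization with permutation folds and p-values (`02`), and the Q
statistic on a toy barbell network (`03`).

A thin CLI mirrors the library:

```bash
crgnet simulate --out-dir sim --rng-seed 1
crgnet prioritize --expression sim/expression.tsv --activity sim/activity.tsv \
    --network sim/network.tsv --annotation sim/annotation.gmt \
    --ontology sim/ontology.tsv --compendium sim/compendium.tsv --out pred.tsv
```

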